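# DCMut empirical amino-acid replacement model
# lower-triangular exchangeabilities (row order ARNDCQEGHILKMFPSTWYV), then stationary frequencies
0.267828
0.984474 1.199805
0.360016 0.887753 1.961167
2.386111 0.228116 0.653416 0.406431
0.258635 0.717840 0.183641 2.485920 4.051870
3.680365 0.000000 0.244139 2.059564 0.327059 0.000000
0.232374 2.439939 0.000000 0.087791 2.383148 0.632629 0.154924
4.610124 0.896321 0.136906 1.028313 1.531590 0.265745 2.001375 0.078012
0.240368 8.931515 0.000000 1.028509 1.493409 1.385352 5.290024 0.768024 0.341113
3.148371 0.000000 0.138503 0.419244 4.885892 2.271697 0.224968 0.946940 0.158067 0.000000
1.348551 11.388659 1.240981 0.868241 0.239248 0.000000 0.716913 0.000000 0.000000 0.133940 0.956097
0.660930 0.000000 0.000000 0.178316 0.000000 0.000000 0.107278 0.282729 0.438074 0.000000 0.000000 0.000000
0.000000 0.187550 1.598356 0.162366 0.000000 0.953164 0.484678 7.086022 0.281581 6.011613 0.180393 0.730772 1.519078
1.127499 0.000000 1.526188 0.561828 0.525651 0.000000 0.000000 0.346983 0.811907 0.439469 0.609526 0.112880 0.830078 0.304803
0.000000 0.507003 0.793999 0.340156 0.000000 0.214717 0.367250 0.106802 0.000000 0.071514 0.267683 0.170372 0.153478 0.347153 2.322243
0.306662 0.000000 0.000000 0.538165 0.076981 0.443504 0.270475 0.000000 0.475927 0.933709 0.353643 0.226333 0.270564 1.265400 0.438715 2.556685
0.460857 3.332732 1.951951 0.119152 0.247955 1.900739 0.000000 0.374834 8.810038 0.180629 5.230115 1.565160 0.316258 0.171432 0.331090 0.461776 0.286572
1.745156 2.411739 0.000000 0.335419 0.954557 1.350599 0.000000 0.132142 0.103850 0.921860 0.170205 0.619951 1.031534 0.000000 0.000000 2.565955 0.110506 0.459901
0.136655 0.762354 6.952629 0.123606 2.427202 0.782857 0.000000 0.000000 0.485026 5.436674 0.740819 0.336289 0.303836 0.000000 0.417839 1.561997 0.608070 0.000000 0.279379
0.08712691287 0.04090395910 0.04043195957 0.04687195313 0.03347396653 0.03825496175 0.04952995047 0.08861191139 0.03361896638 0.03688596311 0.08535691464 0.08048091952 0.01475298525 0.03977196023 0.05067994932 0.06957693042 0.05854194146 0.01049398951 0.02991597008 0.06471793528
ARNDCQEGHILKMFPSTWYV
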