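"""FASTA / relaxed-PHYLIP alignment I/O and amino-acid encoding."""

from __future__ import annotations

from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MISSING_CODE = 20  # gap or ambiguity: no information


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered name -> sequence dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(aln: Mapping[str, str], path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in aln.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_phylip(aln: Mapping[str, str], path) -> None:
    """Relaxed PHYLIP: name, whitespace, full sequence on one line."""
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("alignment is ragged")
    (ncol,) = lengths
    with open(path, "w") as fh:
        fh.write(f" {len(aln)} {ncol}\n")
        for name, seq in aln.items():
            fh.write(f"{name}  {seq}\n")


def check_rectangular(aln: Mapping[str, str]) -> int:
    """Return the column count; raise on ragged alignments."""
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError(f"alignment is ragged: lengths {sorted(lengths)}")
    return lengths.pop() if lengths else 0


def encode_alignment(aln: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode to integer codes 0..19, with gaps/ambiguities as 20 (missing).

    Returns (names, array of shape (n_seqs, n_cols)).
    """
    ncol = check_rectangular(aln)
    names = list(aln)
    codes = np.full((len(names), ncol), MISSING_CODE, dtype=np.int8)
    for i, name in enumerate(names):
        for j, ch in enumerate(aln[name]):
            codes[i, j] = AA_INDEX.get(ch, MISSING_CODE)
    return names, codes


def decode_row(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[c] if c < 20 else "-" for c in codes)
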