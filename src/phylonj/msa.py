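"""Alignment container, FASTA / relaxed-PHYLIP I/O, and integer encoding.

The working alphabet is DNA plus gap: ``A C G T -`` coded as ``0..4``.
IUPAC ambiguity codes, ``N`` and ``?`` are mapped to the gap/missing code on
input; input case is ignored and the canonical form is uppercase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "EncodedAlignment",
    "read_alignment",
    "write_alignment",
    "encode_alignment",
    "decode_alignment",
    "GAP_CODE",
]

ALPHABET = "ACGT-"
GAP_CODE = 4
_AMBIGUOUS = set("RYSWKMBDHVN?")

_CODE = {c: i for i, c in enumerate(ALPHABET)}


@dataclass
class Alignment:
    """N equal-length DNA sequences over {A,C,G,T,-} with unique labels."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in count")
        if len(self.labels) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            detail = {lab: len(s) for lab, s in zip(self.labels, self.sequences)}
            raise ValueError(f"ragged alignment, per-sequence lengths: {detail}")
        if next(iter(lengths)) < 1:
            raise ValueError("zero-length alignment")
        self.sequences = [_canonicalize(s) for s in self.sequences]

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def gap_ratio(self) -> float:
        gaps = sum(s.count("-") for s in self.sequences)
        return gaps / (self.n_taxa * self.length)

    def subset(self, labels: list[str]) -> "Alignment":
        idx = {lab: i for i, lab in enumerate(self.labels)}
        return Alignment(list(labels), [self.sequences[idx[l]] for l in labels])


def _canonicalize(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in _CODE:
            out.append(ch)
        elif ch in _AMBIGUOUS:
            out.append("-")
        else:
            raise ValueError(f"unsupported symbol {ch!r} in sequence")
    return "".join(out)


@dataclass
class EncodedAlignment:
    """Integer-coded alignment: N x L array over {0..4}, A=0 C=1 G=2 T=3 gap=4."""

    labels: list[str]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.labels):
            raise ValueError("codes shape does not match labels")
        if self.codes.min() < 0 or self.codes.max() > 4:
            raise ValueError("codes outside {0..4}")


def encode_alignment(a: Alignment) -> EncodedAlignment:
    codes = np.array([[_CODE[c] for c in s] for s in a.sequences], dtype=np.int64)
    return EncodedAlignment(list(a.labels), codes)


def decode_alignment(e: EncodedAlignment) -> Alignment:
    seqs = ["".join(ALPHABET[c] for c in row) for row in e.codes]
    return Alignment(list(e.labels), seqs)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment from disk."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty alignment file: {path}")
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return Alignment([r.id for r in records], [str(r.seq) for r in records])
    if format == "phylip":
        return _parse_relaxed_phylip(text)
    raise ValueError(f"unknown alignment format: {format!r}")


def _parse_relaxed_phylip(text: str) -> Alignment:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    try:
        n, length = int(header[0]), int(header[1])
    except (IndexError, ValueError) as exc:
        raise ValueError("relaxed PHYLIP must start with '<ntaxa> <length>'") from exc
    labels, seqs = [], []
    for ln in lines[1:]:
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"bad PHYLIP line: {ln!r}")
        labels.append(parts[0])
        seqs.append(parts[1].replace(" ", ""))
    if len(labels) != n:
        raise ValueError(f"header declares {n} taxa, found {len(labels)}")
    if any(len(s) != length for s in seqs):
        raise ValueError("sequence lengths disagree with PHYLIP header")
    return Alignment(labels, seqs)


def write_alignment(a: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write FASTA or relaxed-PHYLIP (whitespace-delimited, full labels)."""
    path = Path(path)
    if format == "fasta":
        records = [SeqRecord(Seq(s), id=lab, description="")
                   for lab, s in zip(a.labels, a.sequences)]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{a.n_taxa} {a.length}\n")
            for lab, s in zip(a.labels, a.sequences):
                fh.write(f"{lab} {s}\n")
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
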