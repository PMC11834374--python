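"""OTU clustering of marker sequences and MLST strain assignment.

Sequences sharing more than a similarity threshold (default 99%) are
collapsed into one operational taxonomic unit by deterministic greedy
centroid clustering.  Symbiont strains are stricter: each distinct
concatenated multilocus haplotype is its own strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN-")


@dataclass
class SequenceSet:
    """Named nucleotide sequences, optionally aligned (equal length)."""

    ids: list[str]
    sequences: list[str]
    aligned: bool = True

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        self.sequences = [s.upper() for s in self.sequences]
        for i, s in enumerate(self.sequences):
            bad = set(s) - _VALID
            if bad:
                raise ValueError(f"invalid characters {bad} in sequence {self.ids[i]}")
        if self.aligned and len({len(s) for s in self.sequences} or {0}) > 1:
            raise ValueError("aligned SequenceSet requires equal-length sequences")

    def __len__(self) -> int:
        return len(self.ids)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.ids, self.sequences))

    @classmethod
    def from_fasta(cls, path: str | Path, aligned: bool = True) -> "SequenceSet":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(ids, seqs, aligned=aligned)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(s), id=i, description="")
            for i, s in zip(self.ids, self.sequences)
        ]
        SeqIO.write(recs, str(path), "fasta")


@dataclass
class OtuAssignment:
    """Result of clustering: id -> OTU label, with per-OTU representatives."""

    labels: dict[str, str]
    threshold: float
    representatives: dict[str, str] = field(default_factory=dict)

    def n_otus(self) -> int:
        return len(set(self.labels.values()))

    def to_table(self, path: str | Path) -> None:
        lines = [f"{i}\t{o}" for i, o in self.labels.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def pairwise_identity(a: str, b: str, gap_mode: str = "pairwise_deletion") -> float:
    """Fraction of matching positions between two aligned sequences.

    With ``pairwise_deletion`` (default) any position where either
    sequence has a gap or N is excluded from both numerator and
    denominator; with ``count_gaps`` such positions count as mismatches.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    aa = np.frombuffer(a.upper().encode(), dtype="S1")
    bb = np.frombuffer(b.upper().encode(), dtype="S1")
    if gap_mode == "pairwise_deletion":
        ok = ~np.isin(aa, [b"-", b"N"]) & ~np.isin(bb, [b"-", b"N"])
        if not ok.any():
            raise ValueError("no comparable positions after pairwise deletion")
        return float((aa[ok] == bb[ok]).mean())
    elif gap_mode == "count_gaps":
        if len(aa) == 0:
            raise ValueError("no comparable positions")
        return float((aa == bb).mean())
    raise ValueError(f"unknown gap_mode {gap_mode!r}")


def cluster_otus(
    seqs: SequenceSet,
    threshold: float = 0.99,
    abundance: Mapping[str, int] | None = None,
    gap_mode: str = "pairwise_deletion",
) -> OtuAssignment:
    """Greedy centroid clustering at a strict identity threshold.

    Sequences are processed in order of descending abundance then
    ascending id; each joins the first existing OTU whose representative
    exceeds ``threshold`` identity, otherwise it founds a new OTU with
    itself as representative.  Deterministic for a given input.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if len(seqs) == 0:
        return OtuAssignment({}, threshold)
    abundance = abundance or {}
    order = sorted(seqs.ids, key=lambda i: (-abundance.get(i, 1), i))
    lookup = seqs.as_dict()
    labels: dict[str, str] = {}
    reps: list[tuple[str, str]] = []  # (otu label, representative id)
    for sid in order:
        placed = False
        for otu, rep in reps:
            if pairwise_identity(lookup[sid], lookup[rep], gap_mode) > threshold:
                labels[sid] = otu
                placed = True
                break
        if not placed:
            otu = f"OTU{len(reps) + 1}"
            reps.append((otu, sid))
            labels[sid] = otu
    return OtuAssignment(labels, threshold, {o: r for o, r in reps})


def assign_strains(mlst: SequenceSet) -> dict[str, str]:
    """Assign strain labels: one strain per distinct concatenated haplotype.

    Exact-sequence equivalence (identity 1.0); labels are numbered by
    first occurrence in id-sorted order, so output is deterministic.
    """
    if len({len(s) for s in mlst.sequences} or {0}) > 1:
        raise ValueError("concatenated haplotypes differ in length")
    strain_of_seq: dict[str, str] = {}
    labels: dict[str, str] = {}
    for sid in sorted(mlst.ids):
        seq = mlst.as_dict()[sid]
        if seq not in strain_of_seq:
            strain_of_seq[seq] = f"strain_{len(strain_of_seq) + 1}"
        labels[sid] = strain_of_seq[seq]
    return labels
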