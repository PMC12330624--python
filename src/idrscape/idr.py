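"""Disordered-region extraction, functional classification and dataset filters.

Disordered regions (IDRs) are maximal runs of residues with AlphaFold pLDDT
≤ 70.  Each IDR is classified against experimentally verified
phase-separation (PS) segments — intervals whose deletion or mutation
impairs phase separation — by the fraction of the segment it covers:

* ``driving``          — covers > 50% of some PS segment
* ``participating``    — overlaps a PS segment but covers ≤ 50% of every one
* ``non_participating``— no overlap with any PS segment

Two dataset-construction filters are provided: a minimum disordered fraction
(≥ 10% of residues disordered) and a greedy redundancy filter removing
proteins over 50% pairwise sequence identity to an already-retained one.

All intervals are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .llr import PLDDT_DISORDER_THRESHOLD

FUNCTIONAL_CLASSES = ("driving", "participating", "non_participating", "unassigned")


@dataclass(frozen=True)
class IDRRegion:
    protein_id: str
    start: int
    end: int
    functional_class: str = "unassigned"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PSSegment:
    """Experimentally verified phase-separation segment."""

    protein_id: str
    start: int
    end: int
    source_note: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def extract_idrs(plddt, protein_id: str = "",
                 threshold: float = PLDDT_DISORDER_THRESHOLD) -> list[IDRRegion]:
    """Maximal runs of residues with pLDDT ≤ threshold, 1-based inclusive."""
    p = np.asarray(plddt, dtype=float)
    missing = np.flatnonzero(~np.isfinite(p))
    if missing.size:
        raise InvalidInputError(
            f"{protein_id}: missing pLDDT at positions {[int(i) + 1 for i in missing]}"
        )
    disordered = p <= threshold
    regions = []
    start = None
    for i, d in enumerate(disordered):
        if d and start is None:
            start = i
        elif not d and start is not None:
            regions.append(IDRRegion(protein_id, start + 1, i))
            start = None
    if start is not None:
        regions.append(IDRRegion(protein_id, start + 1, len(p)))
    return regions


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def classify_idr(idr: IDRRegion, segments) -> str:
    """Functional class of one IDR against the protein's PS segments.

    Coverage of a segment = overlap length / segment length; the IDR takes
    the class of its maximum coverage.  Coverage exactly 0.5 is
    participating ("over 50%" is strict for driving).  No segments at all →
    non_participating.
    """
    max_cov = 0.0
    for seg in segments:
        cov = _overlap(idr.start, idr.end, seg.start, seg.end) / seg.length
        max_cov = max(max_cov, cov)
    if max_cov > 0.5:
        return "driving"
    if max_cov > 0.0:
        return "participating"
    return "non_participating"


def classify_idrs(idrs, segments) -> list[IDRRegion]:
    """Classify every IDR of one protein; returns new records."""
    return [replace(idr, functional_class=classify_idr(idr, segments)) for idr in idrs]


def disorder_fraction_filter(plddt, min_fraction: float = 0.10,
                             threshold: float = PLDDT_DISORDER_THRESHOLD) -> bool:
    """True iff at least ``min_fraction`` of residues are disordered."""
    p = np.asarray(plddt, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty pLDDT track")
    return bool((p <= threshold).sum() / p.size >= min_fraction)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity: matches / alignment length.

    Needleman–Wunsch with unit match score, zero mismatch and linear gap
    penalty −1 (Bio.Align.PairwiseAligner).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a, seq_b)[0]
    identities = aln.counts().identities
    return identities / aln.length


def redundancy_filter(proteins, max_identity: float = 0.50) -> list[str]:
    """Greedy non-redundant subset in input order.

    A protein is retained unless its pairwise identity with an
    already-retained protein exceeds ``max_identity`` (strict: identity
    exactly at the cutoff is kept).
    """
    proteins = list(proteins)
    if not proteins:
        raise InvalidInputError("redundancy_filter requires at least one protein")
    retained: list[tuple[str, str]] = []
    for pid, seq in proteins:
        if all(pairwise_identity(seq, kept_seq) <= max_identity
               for _, kept_seq in retained):
            retained.append((pid, seq))
    return [pid for pid, _ in retained]


# ---------------------------------------------------------------------------
# I/O  (intervals on disk are 1-based inclusive)


def read_ps_segments(path) -> dict[str, list[PSSegment]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[PSSegment]] = {}
    for row in df.itertuples(index=False):
        seg = PSSegment(str(row.protein_id), int(row.start), int(row.end),
                        str(getattr(row, "note", "")))
        out.setdefault(seg.protein_id, []).append(seg)
    return out


def write_ps_segments(segments, path) -> None:
    pd.DataFrame(
        [(s.protein_id, s.start, s.end, s.source_note) for s in segments],
        columns=["protein_id", "start", "end", "note"],
    ).to_csv(path, sep="\t", index=False)


def write_idrs(idrs, path) -> None:
    pd.DataFrame(
        [(r.protein_id, r.start, r.end, r.functional_class) for r in idrs],
        columns=["protein_id", "start", "end", "functional_class"],
    ).to_csv(path, sep="\t", index=False)


def read_idrs(path) -> list[IDRRegion]:
    df = pd.read_csv(path, sep="\t")
    return [
        IDRRegion(str(r.protein_id), int(r.start), int(r.end), str(r.functional_class))
        for r in df.itertuples(index=False)
    ]
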