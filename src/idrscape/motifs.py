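"""Greedy bidirectional discovery of conserved motifs in score profiles.

A motif is a contiguous stretch of residues whose average entropy score is at
most a threshold (default 0.5 nats).  The extraction procedure:

1. **Directional scan** (run once from each terminus): find the next anchor
   residue with score ≤ threshold, then append residues toward the opposite
   terminus while the running segment mean stays ≤ threshold; the first
   residue whose inclusion pushes the mean above the threshold closes the
   segment, and the scan resumes there.
2. **Intersection**: keep only residues belonging to candidates of *both*
   directions, trimming terminal residues that qualify only by leaning on an
   adjacent low-score region.  Contiguous runs of the intersection are
   re-extracted as intervals; a run whose own mean exceeds the threshold
   (possible, since a subsegment carries no mean guarantee) is discarded.
3. **Proximity merge**: adjacent motifs whose gap is within 8 residues are
   merged when the spanning segment's mean is strictly below the threshold;
   merging cascades left to right.
4. **Length filter**: motifs shorter than ``min_len`` (default 4) are dropped.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import IntervalError, InvalidInputError

#: Residues driving strong, specific condensate interactions.
STICKER_RESIDUES = frozenset("YFWRKQ")

DEFAULT_THRESHOLD = 0.5
DEFAULT_MERGE_GAP = 8
DEFAULT_MIN_LEN = 4


@dataclass(frozen=True)
class Motif:
    """A contiguous low-entropy stretch (1-based inclusive coordinates)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    mean_esm2: float
    sticker_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


def _check_scores(scores) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1:
        raise InvalidInputError("scores must be a 1-D sequence")
    if s.size and not np.isfinite(s).all():
        raise InvalidInputError("scores contain non-finite values")
    return s


def scan_directional(scores, threshold: float = DEFAULT_THRESHOLD,
                     direction: str = "forward") -> list[frozenset[int]]:
    """Greedy one-direction candidate scan; returns 1-based position sets.

    Starting at the given terminus, anchors at the next residue with score
    ≤ threshold and extends toward the opposite terminus while the running
    mean stays ≤ threshold.  A segment that reaches the far terminus without
    breaching is emitted open.
    """
    s = _check_scores(scores)
    if direction not in ("forward", "backward"):
        raise InvalidInputError(f"direction must be forward/backward, got {direction!r}")
    if s.size == 0:
        return []
    if direction == "backward":
        rev = scan_directional(s[::-1], threshold, "forward")
        L = s.size
        return [frozenset(L + 1 - p for p in seg) for seg in rev]

    segments: list[frozenset[int]] = []
    L = s.size
    i = 0
    while i < L:
        if s[i] > threshold:
            i += 1
            continue
        total = 0.0
        j = i
        while j < L and (total + s[j]) / (j - i + 1) <= threshold:
            total += s[j]
            j += 1
        segments.append(frozenset(range(i + 1, j + 1)))  # 1-based [i, j-1]
        # the breaching residue (if any) has score > threshold, so restarting
        # the anchor search there is safe
        i = j if j > i else i + 1
    return segments


def intersect_candidates(fwd, bwd, scores=None,
                         threshold: float = DEFAULT_THRESHOLD) -> list[tuple[int, int]]:
    """Residue-level intersection of the two directional candidate sets.

    Contiguous runs of the intersection become intervals; when ``scores`` is
    provided, runs whose mean exceeds the threshold are discarded so every
    output satisfies the motif definition.
    """
    fset = set().union(*fwd) if fwd else set()
    bset = set().union(*bwd) if bwd else set()
    common = sorted(fset & bset)
    intervals: list[tuple[int, int]] = []
    for p in common:
        if intervals and p == intervals[-1][1] + 1:
            intervals[-1] = (intervals[-1][0], p)
        else:
            intervals.append((p, p))
    if scores is not None:
        s = _check_scores(scores)
        intervals = [
            (a, b) for a, b in intervals if s[a - 1:b].mean() <= threshold
        ]
    return intervals


def merge_motifs(motifs, scores, gap: int = DEFAULT_MERGE_GAP,
                 threshold: float = DEFAULT_THRESHOLD) -> list[tuple[int, int]]:
    """Proximity merging of disjoint, sorted motif intervals.

    Adjacent motifs A, B are mergeable when start(B) − end(A) ≤ gap and the
    mean score of the spanning segment is strictly below the threshold.
    Merging runs to a fixpoint, at each step replacing the mergeable
    adjacent pair with the lowest span mean (ties broken leftmost); a merged
    interval may merge again with its neighbours.  Best-first selection
    keeps the result invariant under sequence reversal whenever span means
    are tie-free.
    """
    s = _check_scores(scores)
    motifs = list(motifs)
    for (a1, b1), (a2, b2) in zip(motifs, motifs[1:]):
        if a2 <= b1:
            raise InvalidInputError(
                f"input intervals overlap or are unsorted: ({a1},{b1}) vs ({a2},{b2})"
            )
    merged = motifs
    while len(merged) > 1:
        best = None
        best_mean = None
        for k, (cur, nxt) in enumerate(zip(merged, merged[1:])):
            if nxt[0] - cur[1] > gap:
                continue
            span_mean = s[cur[0] - 1:nxt[1]].mean()
            if span_mean < threshold and (best is None or span_mean < best_mean):
                best, best_mean = k, span_mean
        if best is None:
            break
        merged = (merged[:best]
                  + [(merged[best][0], merged[best + 1][1])]
                  + merged[best + 2:])
    return merged


def sticker_fraction(motif_sequence: str) -> float:
    """Fraction of sticker residues (Y, F, W, R, K, Q) in a motif sequence."""
    if not motif_sequence:
        raise InvalidInputError("empty motif sequence")
    return sum(c in STICKER_RESIDUES for c in motif_sequence.upper()) / len(motif_sequence)


def find_motifs(track, threshold: float = DEFAULT_THRESHOLD,
                gap: int = DEFAULT_MERGE_GAP, min_len: int = DEFAULT_MIN_LEN,
                region: tuple[int, int] | None = None) -> list[Motif]:
    """End-to-end motif extraction from a residue track or raw score array.

    Parameters
    ----------
    track : pandas.DataFrame with columns esm2_score (and optionally
        protein_id, wt_aa) or a plain 1-D score sequence.
    region : optional 1-based inclusive interval restricting the scan to one
        disordered region; reported coordinates stay in protein coordinates.
    """
    if isinstance(track, pd.DataFrame):
        scores = track["esm2_score"].to_numpy(dtype=float)
        sequence = "".join(track["wt_aa"]) if "wt_aa" in track else "X" * len(scores)
        protein_id = str(track["protein_id"].iloc[0]) if "protein_id" in track and len(track) else ""
    else:
        scores = _check_scores(track)
        sequence = "X" * scores.size
        protein_id = ""

    offset = 0
    if region is not None:
        a, b = region
        if not (1 <= a <= b <= scores.size):
            raise IntervalError(
                f"region ({a},{b}) out of bounds for length {scores.size}"
            )
        offset = a - 1
        scores_scan = scores[a - 1:b]
    else:
        scores_scan = scores

    fwd = scan_directional(scores_scan, threshold, "forward")
    bwd = scan_directional(scores_scan, threshold, "backward")
    intervals = intersect_candidates(fwd, bwd, scores_scan, threshold)
    intervals = merge_motifs(intervals, scores_scan, gap, threshold)
    out = []
    for a, b in intervals:
        if b - a + 1 < min_len:
            continue
        ga, gb = a + offset, b + offset  # back to protein coordinates
        seq = sequence[ga - 1:gb]
        out.append(
            Motif(
                protein_id=protein_id,
                start=ga,
                end=gb,
                sequence=seq,
                mean_esm2=float(scores[ga - 1:gb].mean()),
                sticker_fraction=sticker_fraction(seq) if seq else 0.0,
            )
        )
    return out


def find_motifs_in_regions(track, regions,
                           threshold: float = DEFAULT_THRESHOLD,
                           gap: int = DEFAULT_MERGE_GAP,
                           min_len: int = DEFAULT_MIN_LEN) -> list[Motif]:
    """Run region-restricted motif extraction over a list of (start, end)
    intervals (e.g. the protein's disordered regions) and concatenate."""
    out: list[Motif] = []
    for a, b in regions:
        out.extend(find_motifs(track, threshold, gap, min_len, region=(int(a), int(b))))
    return sorted(out, key=lambda m: m.start)


def motif_membership(track: pd.DataFrame, motifs,
                     threshold: float = DEFAULT_THRESHOLD) -> pd.Series:
    """Per-amino-acid fraction of conserved residues lying inside motifs.

    Among residues with score ≤ threshold, for each wild-type letter, the
    fraction covered by any motif interval.  Letters with no conserved
    residues are absent from the result (no evidence, not zero).
    """
    covered: set[int] = set()
    for m in motifs:
        covered.update(m.positions())
    conserved = track[track["esm2_score"] <= threshold]
    result = {}
    for aa, sub in conserved.groupby("wt_aa"):
        inside = sub["position"].isin(covered).sum()
        result[aa] = inside / len(sub)
    return pd.Series(result, dtype=float).sort_index()


def motifs_to_frame(motifs) -> pd.DataFrame:
    """Motif list as the canonical CSV table."""
    return pd.DataFrame(
        [
            (m.protein_id, m.start, m.end, m.length, m.sequence,
             m.mean_esm2, m.sticker_fraction)
            for m in motifs
        ],
        columns=["protein_id", "start", "end", "length", "sequence",
                 "mean_esm2", "sticker_fraction"],
    )
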