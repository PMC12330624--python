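"""Per-residue mutational-tolerance scoring from language-model LLR matrices.

A protein language model queried at every position of a sequence yields, for
each of the 20 canonical amino acids, a log-likelihood ratio (LLR) of the
substitution relative to the wild-type residue (the wild-type entry is 0 by
construction: the ratio of a residue to itself).  The per-residue tolerance
score used throughout this package is the Shannon entropy, in nats, of the
softmax distribution over that 20-element LLR vector:

    score_i = -sum_k p_k log p_k,   p_k = exp(LLR_ik) / sum_j exp(LLR_ij)

A low score means the model concentrates probability on few residues —
mutations are predicted deleterious, the position is constrained.  The score
ranges from 0 (one residue tolerated) to ln 20 ≈ 2.996 (all equally
tolerated).  Residues are binned as conserved (score ≤ 0.5), flexible
(score ≥ 2.0) or intermediate, and as ordered/disordered by an AlphaFold
pLDDT ≤ 70 cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import log_softmax

from .exceptions import (
    AlignmentMismatchError,
    FormatError,
    InvalidInputError,
    ShapeError,
)

#: Canonical alphabet; fixed column order of every LLR table.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Maximum attainable entropy score (uniform tolerance), in nats.
MAX_SCORE: float = math.log(20.0)

#: pLDDT at or below which a residue is called disordered.
PLDDT_DISORDER_THRESHOLD: float = 70.0

#: Entropy-score cutoffs for the tolerance classes.
CONSERVED_MAX: float = 0.5
FLEXIBLE_MIN: float = 2.0

#: Numerical tolerance for the wild-type LLR entry, which must be 0.
WT_ZERO_TOL: float = 1e-9


@dataclass
class LLRMatrix:
    """Length-L matrix of per-residue substitution log-likelihood ratios.

    ``llr[i, k]`` is the LLR of mutating position ``i`` (0-based row,
    1-based residue ``i+1``) to ``AA_ALPHABET[k]``.  The wild-type entry of
    every row is exactly 0.
    """

    protein_id: str
    sequence: str
    llr: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.llr = np.asarray(self.llr, dtype=float)
        if self.llr.ndim != 2 or self.llr.shape[1] != len(AA_ALPHABET):
            raise ShapeError(
                f"{self.protein_id}: LLR matrix must be (L, 20), got {self.llr.shape}"
            )
        if len(self.sequence) != self.llr.shape[0]:
            raise ShapeError(
                f"{self.protein_id}: sequence length {len(self.sequence)} "
                f"!= LLR rows {self.llr.shape[0]}"
            )
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise InvalidInputError(
                f"{self.protein_id}: nonstandard residues {sorted(bad)}; "
                f"only the 20 canonical letters are supported"
            )
        if not np.isfinite(self.llr).all():
            raise InvalidInputError(f"{self.protein_id}: non-finite LLR values")
        wt_cols = np.fromiter(
            (AA_INDEX[aa] for aa in self.sequence), dtype=int, count=len(self.sequence)
        )
        wt_vals = self.llr[np.arange(len(self.sequence)), wt_cols]
        off = np.flatnonzero(np.abs(wt_vals) > WT_ZERO_TOL)
        if off.size:
            pos = int(off[0]) + 1
            raise FormatError(
                f"{self.protein_id}: wild-type LLR entry at position {pos} is "
                f"{wt_vals[off[0]]:.3g}, expected 0 (different WT convention?)"
            )

    def __len__(self) -> int:
        return self.llr.shape[0]


def esm2_score(llr_vector) -> float:
    """Entropy score (nats) of the softmax over a 20-element LLR vector.

    Invariant under adding a constant to all entries and under permutation;
    bounded by [0, ln 20].
    """
    v = np.asarray(llr_vector, dtype=float)
    if v.shape != (len(AA_ALPHABET),):
        raise ShapeError(f"LLR vector must have 20 entries, got shape {v.shape}")
    if not np.isfinite(v).all():
        raise InvalidInputError("LLR vector contains non-finite entries")
    logp = log_softmax(v)
    # -sum p log p with p = exp(logp); exp(logp)*logp -> 0 for logp -> -inf
    h = float(-np.sum(np.exp(logp) * logp))
    return min(max(h, 0.0), MAX_SCORE)


def score_matrix(llr: np.ndarray) -> np.ndarray:
    """Vectorised entropy score for every row of an (L, 20) LLR matrix."""
    logp = log_softmax(np.asarray(llr, dtype=float), axis=1)
    h = -np.sum(np.exp(logp) * logp, axis=1)
    return np.clip(h, 0.0, MAX_SCORE)


def classify_order(plddt: float) -> str:
    if plddt is None or (isinstance(plddt, float) and math.isnan(plddt)):
        return "unavailable"
    return "disordered" if plddt <= PLDDT_DISORDER_THRESHOLD else "ordered"


def classify_tolerance(score: float) -> str:
    if score <= CONSERVED_MAX:
        return "conserved"
    if score >= FLEXIBLE_MIN:
        return "flexible"
    return "intermediate"


def score_protein(m: LLRMatrix, plddt=None) -> pd.DataFrame:
    """Compute the per-residue track for one protein.

    Parameters
    ----------
    m : LLRMatrix
    plddt : array-like of length L, optional
        Per-residue AlphaFold confidence in [0, 100].  When absent the
        order class is marked ``unavailable`` and order-dependent stages
        must reject the protein.

    Returns
    -------
    pandas.DataFrame with columns protein_id, position (1-based), wt_aa,
    esm2_score, plddt, order_class, tolerance_class.
    """
    L = len(m)
    if plddt is not None:
        plddt = np.asarray(plddt, dtype=float)
        if plddt.shape != (L,):
            raise AlignmentMismatchError(
                f"{m.protein_id}: pLDDT track length {plddt.shape[0] if plddt.ndim == 1 else plddt.shape} "
                f"does not match LLR matrix length {L}"
            )
    scores = score_matrix(m.llr)
    track = pd.DataFrame(
        {
            "protein_id": m.protein_id,
            "position": np.arange(1, L + 1),
            "wt_aa": list(m.sequence),
            "esm2_score": scores,
            "plddt": plddt if plddt is not None else np.nan,
        }
    )
    track["order_class"] = [classify_order(p) for p in track["plddt"]]
    track["tolerance_class"] = [classify_tolerance(s) for s in scores]
    return track


# ---------------------------------------------------------------------------
# I/O


def _llr_columns() -> list[str]:
    return ["protein_id", "position", "wt_aa", *AA_ALPHABET]


def read_llr_tables(path) -> dict[str, LLRMatrix]:
    """Read a TSV of LLR rows (possibly several proteins) into matrices.

    Columns: protein_id, position (1-based, contiguous per protein), wt_aa,
    then the 20 alphabet columns A..Y in fixed order.
    """
    df = pd.read_csv(path, sep="\t")
    expected = _llr_columns()
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    out: dict[str, LLRMatrix] = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        positions = sub["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, len(sub) + 1)):
            raise FormatError(
                f"{path}: positions for {pid} not contiguous from 1"
            )
        seq = "".join(sub["wt_aa"])
        out[str(pid)] = LLRMatrix(
            protein_id=str(pid), sequence=seq,
            llr=sub[list(AA_ALPHABET)].to_numpy(dtype=float),
        )
    if not out:
        raise FormatError(f"{path}: empty LLR table")
    return out


def read_llr_table(path, protein_id: str | None = None) -> LLRMatrix:
    """Read one protein's LLR matrix; error if the file holds several and no
    protein_id is given."""
    tables = read_llr_tables(path)
    if protein_id is not None:
        if protein_id not in tables:
            raise FormatError(f"{path}: protein {protein_id!r} not present")
        return tables[protein_id]
    if len(tables) != 1:
        raise FormatError(
            f"{path}: holds {len(tables)} proteins; pass protein_id"
        )
    return next(iter(tables.values()))


def write_llr_table(matrices, path) -> None:
    """Write one or more LLRMatrix objects as the canonical TSV."""
    if isinstance(matrices, LLRMatrix):
        matrices = [matrices]
    frames = []
    for m in matrices:
        df = pd.DataFrame(m.llr, columns=list(AA_ALPHABET))
        df.insert(0, "wt_aa", list(m.sequence))
        df.insert(0, "position", np.arange(1, len(m) + 1))
        df.insert(0, "protein_id", m.protein_id)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.10g")


TRACK_COLUMNS = [
    "protein_id", "position", "wt_aa", "esm2_score", "plddt",
    "order_class", "tolerance_class",
]


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.10g",
                 columns=[c for c in TRACK_COLUMNS if c in track.columns]
                 + [c for c in track.columns if c not in TRACK_COLUMNS])


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_plddt_table(path) -> dict[str, np.ndarray]:
    """Read a per-residue pLDDT TSV (protein_id, position, plddt)."""
    df = pd.read_csv(path, sep="\t")
    need = {"protein_id", "position", "plddt"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    out = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        sub = sub.sort_values("position")
        if not np.array_equal(sub["position"].to_numpy(), np.arange(1, len(sub) + 1)):
            raise FormatError(f"{path}: positions for {pid} not contiguous from 1")
        out[str(pid)] = sub["plddt"].to_numpy(dtype=float)
    return out


def read_plddt_pdb(path) -> np.ndarray:
    """Read per-residue pLDDT from an AlphaFold-convention coordinate file.

    AlphaFold deposits the per-residue confidence in the B-factor column;
    the first atom of each residue is read.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    values: list[float] = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":  # skip heteroatoms/waters
                continue
            first_atom = next(iter(residue))
            values.append(float(first_atom.get_bfactor()))
    if not values:
        raise FormatError(f"{path}: no polymer residues found")
    return np.asarray(values, dtype=float)
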