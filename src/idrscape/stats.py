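"""Group-level statistics: distribution comparisons, conserved fractions,
per-amino-acid substitution profiles, clustering and correlations.

Distribution comparisons use the two-sided Mann–Whitney U test with the
significance tiers

    ***  p < 0.001      **  p < 0.01      *  p < 0.05
    †    p < 0.10 (marginal)              n.s.  p ≥ 0.10

For small samples (combined n ≤ 12) the p-value comes from full enumeration
of label assignments with midrank tie handling; larger samples use the
tie-corrected normal approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .exceptions import InvalidInputError
from .llr import AA_ALPHABET, CONSERVED_MAX

EXACT_MAX_N = 12  # combined sample size up to which U is enumerated exactly

SIGNIFICANCE_TIERS = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
    (0.10, "†"),
)


def significance_tier(p_value: float) -> str:
    for cutoff, tier in SIGNIFICANCE_TIERS:
        if p_value < cutoff:
            return tier
    return "n.s."


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    significance: str


def _u_statistic(pooled_ranks: np.ndarray, idx_a) -> float:
    n_a = len(idx_a)
    r_a = pooled_ranks[list(idx_a)].sum()
    return r_a - n_a * (n_a + 1) / 2


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Enumerate all C(n_a+n_b, n_a) assignments of the pooled values.

    Returns (U_observed, p) with p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))
    under the permutation null, midranks for ties.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    n = pooled.size
    n_a = a.size
    u_obs = _u_statistic(ranks, range(n_a))
    total = 0
    le = 0
    ge = 0
    eps = 1e-9
    for idx in itertools.combinations(range(n), n_a):
        u = _u_statistic(ranks, idx)
        total += 1
        if u <= u_obs + eps:
            le += 1
        if u >= u_obs - eps:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return u_obs, p


def mann_whitney(a, b, group_a: str = "a", group_b: str = "b") -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of two score samples.

    The U statistic reported is that of the first group.  Exact enumeration
    is used when n_a + n_b ≤ 12, the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be nonempty")
    if a.size + b.size <= EXACT_MAX_N:
        u, p = _exact_two_sided_p(a, b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(group_a, group_b, a.size, b.size, float(u), p,
                           significance_tier(p))


def fraction_by_class(track: pd.DataFrame, order_class: str | None,
                      tolerance_class: str) -> float:
    """Fraction of residues (optionally restricted to one order class) with
    the given tolerance class; NaN when the filter selects no residues."""
    sub = track if order_class is None else track[track["order_class"] == order_class]
    if len(sub) == 0:
        return float("nan")
    return (sub["tolerance_class"] == tolerance_class).sum() / len(sub)


def ps_localization_probability(track: pd.DataFrame, idrs,
                                conserved_max: float = CONSERVED_MAX) -> float:
    """Per-protein probability p of finding conserved residues inside IDRs
    that drive or participate in phase separation.

    p = (# conserved residues in driving/participating IDRs) /
        (# conserved residues in the protein); NaN when the protein has no
    conserved residues.  The complement 1 − p is the probability of finding
    them outside phase-separating regions.
    """
    conserved = track[track["esm2_score"] <= conserved_max]
    if len(conserved) == 0:
        return float("nan")
    inside: set[int] = set()
    for r in idrs:
        if r.functional_class in ("driving", "participating"):
            inside.update(range(r.start, r.end + 1))
    return conserved["position"].isin(inside).sum() / len(conserved)


def aa_mean_llr(tracks: pd.DataFrame, matrices: dict,
                residue_filter=None) -> pd.DataFrame:
    """Per-amino-acid mean substitution profile over a residue population.

    Parameters
    ----------
    tracks : concatenated residue tracks (columns protein_id, position,
        wt_aa, esm2_score, optionally cs).
    matrices : mapping protein_id → LLRMatrix.
    residue_filter : optional callable(tracks) → boolean mask selecting the
        residue population (e.g. residues of driving IDRs).

    Returns
    -------
    DataFrame indexed by amino-acid letter with columns mean_llr_<AA> (20),
    mean_esm2, mean_cs (NaN when no conservation data), n_residues and
    cluster_id ("unassigned" until clustering).  Letters absent from the
    population have n_residues 0 and NaN means.
    """
    sub = tracks if residue_filter is None else tracks[residue_filter(tracks)]
    rows = {}
    for aa in AA_ALPHABET:
        aa_res = sub[sub["wt_aa"] == aa]
        n = len(aa_res)
        if n == 0:
            rows[aa] = {f"mean_llr_{c}": np.nan for c in AA_ALPHABET} | {
                "mean_esm2": np.nan, "mean_cs": np.nan, "n_residues": 0}
            continue
        vecs = np.stack([
            matrices[r.protein_id].llr[r.position - 1]
            for r in aa_res.itertuples(index=False)
        ])
        mean_vec = vecs.mean(axis=0)
        rows[aa] = {f"mean_llr_{c}": mean_vec[k] for k, c in enumerate(AA_ALPHABET)}
        rows[aa]["mean_esm2"] = aa_res["esm2_score"].mean()
        rows[aa]["mean_cs"] = (
            aa_res["cs"].mean() if "cs" in aa_res else np.nan
        )
        rows[aa]["n_residues"] = n
    profiles = pd.DataFrame.from_dict(rows, orient="index")
    profiles.index.name = "aa"
    profiles["cluster_id"] = "unassigned"
    return profiles


def esm2_cs_correlation(profiles: pd.DataFrame, exclude=frozenset("M")) -> float:
    """Pearson r between per-amino-acid mean entropy score and mean
    conservation, excluding the given letters (methionine by default — its
    frequent initiator position confounds substitution predictions)."""
    pts = profiles.loc[[aa for aa in profiles.index if aa not in exclude]]
    pts = pts.dropna(subset=["mean_esm2", "mean_cs"])
    if len(pts) < 3:
        raise InvalidInputError(
            f"need ≥ 3 amino acids with defined means, have {len(pts)}"
        )
    x = pts["mean_esm2"].to_numpy()
    y = pts["mean_cs"].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise InvalidInputError("zero variance; correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def embed_profiles(profiles: pd.DataFrame, method: str = "pca",
                   random_state: int = 0) -> np.ndarray:
    """2-D embedding of the 20 mean-LLR vectors.

    ``pca`` (default) is deterministic; ``umap`` uses the seeded nonlinear
    neighbour-graph embedding and requires the optional umap-learn extra.
    """
    cols = [f"mean_llr_{c}" for c in AA_ALPHABET]
    X = profiles[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        missing = [str(aa) for aa, row in zip(profiles.index, X) if np.isnan(row).any()]
        raise InvalidInputError(f"profiles missing mean LLR vectors for {missing}")
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, svd_solver="full").fit_transform(X)
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=2, random_state=random_state,
                            n_neighbors=5, min_dist=0.1)
        return reducer.fit_transform(X)
    raise InvalidInputError(f"unknown embedding method {method!r}")


def cluster_aa_profiles(profiles: pd.DataFrame, n_clusters: int = 5,
                        method: str = "pca", random_state: int = 0) -> pd.Series:
    """Hierarchically cluster the 20 amino acids on a 2-D embedding of their
    mean substitution profiles.

    Average-linkage clustering of the embedding, cut at ``n_clusters``;
    cluster labels 1..n are assigned by ascending cluster-mean entropy score
    (group 1 = most conserved).
    """
    emb = embed_profiles(profiles, method=method, random_state=random_state)
    Z = linkage(emb, method="average")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    mean_scores = {
        c: profiles["mean_esm2"].to_numpy()[raw == c].mean()
        for c in np.unique(raw)
    }
    order = sorted(mean_scores, key=mean_scores.get)
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([relabel[c] for c in raw], index=profiles.index, name="cluster_id")


def compare_groups(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise Mann–Whitney comparisons over labelled score samples."""
    labels = list(samples)
    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        c = mann_whitney(samples[ga], samples[gb], ga, gb)
        rows.append((c.group_a, c.group_b, c.n_a, c.n_b, c.u_statistic,
                     c.p_value, c.significance))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "U", "p", "tier"]
    )


def histogram2d_export(x, y, bins: int = 50, range_=None) -> pd.DataFrame:
    """Plain 2-D histogram of two per-residue score tracks, as a tidy table
    (x_mid, y_mid, count) for downstream plotting scripts."""
    H, xe, ye = np.histogram2d(np.asarray(x, float), np.asarray(y, float),
                               bins=bins, range=range_)
    xm = (xe[:-1] + xe[1:]) / 2
    ym = (ye[:-1] + ye[1:]) / 2
    rows = [(xm[i], ym[j], H[i, j]) for i in range(len(xm)) for j in range(len(ym))]
    return pd.DataFrame(rows, columns=["x_mid", "y_mid", "count"])
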