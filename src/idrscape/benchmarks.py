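"""Synthetic-study benchmarks: planted-truth recovery and trend statistics.

These routines run the full analysis on generated data and measure how well
each stage recovers the planted ground truth: residue-level Jaccard overlap
of recovered vs planted motifs, the coupling between entropy scores and
alignment conservation, the group-level disorder-score gradient, and the
fraction of conserved residues captured by motifs.  They are the package's
own evaluation surface — everything here is recomputed from scratch at call
time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conservation import conservation_scores
from .idr import extract_idrs
from .llr import score_protein
from .motifs import find_motifs_in_regions
from .stats import aa_mean_llr, esm2_cs_correlation, mann_whitney
from .synthetic import SimConfig, simulate_dataset

_MOD = 2**31


def _derive_seed(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % _MOD


def _driver_proteins(seed: int, n_proteins: int, n_homologs: int):
    from .synthetic import GROUP_MULTIPLIERS

    cfg = SimConfig(seed=seed, n_proteins=n_proteins, n_homologs=n_homologs)
    proteins, _ = simulate_dataset(
        cfg, {"driver": GROUP_MULTIPLIERS["driver"]})
    return proteins


def motif_recovery_jaccard(seed: int, n_seeds: int = 20,
                           min_len: int = 4) -> float:
    """Mean residue-level Jaccard similarity between recovered and planted
    motifs over driver-like proteins, one protein per seed."""
    scores = []
    for i in range(n_seeds):
        (prot,) = _driver_proteins(_derive_seed(seed, i), 1, n_homologs=2)
        track = score_protein(prot.llr, prot.plddt)
        regions = [(r.start, r.end) for r in extract_idrs(prot.plddt, prot.id)]
        found = find_motifs_in_regions(track, regions, min_len=min_len)
        recovered = {p for m in found for p in m.positions()}
        planted = {p for a, b in prot.truth["motifs"]
                   for p in range(a, b + 1)}
        union = recovered | planted
        scores.append(len(recovered & planted) / len(union) if union else 1.0)
    return float(np.mean(scores))


def coupling_statistics(seed: int, n_proteins: int = 3,
                        n_homologs: int = 200) -> dict:
    """Entropy-score ↔ conservation coupling on softmax-sampled MSAs.

    Returns the mean conserved-site homolog WT frequency together with its
    closed-form expectation and standard error, the per-site Spearman
    correlation between entropy score and conservation, and the
    per-amino-acid Pearson r (methionine excluded).
    """
    proteins = _driver_proteins(_derive_seed(seed, 101), n_proteins, n_homologs)
    tracks = []
    matrices = {}
    conserved_cs = []
    conserved_expected = []
    conserved_var = []
    for prot in proteins:
        track = score_protein(prot.llr, prot.plddt)
        cs = conservation_scores(prot.msa)
        track = track.merge(cs[["protein_id", "position", "cs", "n_nongap"]],
                            on=["protein_id", "position"])
        tracks.append(track)
        matrices[prot.id] = prot.llr
        in_motif = np.zeros(len(prot.sequence), dtype=bool)
        for a, b in prot.truth["motifs"]:
            in_motif[a - 1:b] = True
        p_site = prot.truth["wt_softmax"][in_motif]
        n_site = track["n_nongap"].to_numpy()[in_motif]
        conserved_cs.extend(track["cs"].to_numpy()[in_motif])
        conserved_expected.extend(p_site)
        conserved_var.extend(p_site * (1 - p_site) / np.maximum(n_site, 1))

    track = pd.concat(tracks, ignore_index=True)
    ok = track["cs"].notna()
    spearman = float(sps.spearmanr(track.loc[ok, "esm2_score"],
                                   track.loc[ok, "cs"]).statistic)
    dis = track[(track["order_class"] == "disordered") & ok]
    spearman_dis = float(sps.spearmanr(dis["esm2_score"], dis["cs"]).statistic)
    site_pearson = float(sps.pearsonr(track.loc[ok, "esm2_score"],
                                      track.loc[ok, "cs"]).statistic)
    profiles = aa_mean_llr(track, matrices)
    pearson = esm2_cs_correlation(profiles, exclude=frozenset("M"))

    n_sites = len(conserved_cs)
    return {
        "conserved_wt_freq": float(np.mean(conserved_cs)),
        "conserved_wt_freq_expected": float(np.mean(conserved_expected)),
        "conserved_wt_freq_se": float(np.sqrt(np.sum(conserved_var)) / n_sites),
        "closed_form_wt_weight": float(1 / (1 + 19 * np.exp(-8.0))),
        "site_spearman": spearman,
        "site_spearman_disordered": spearman_dis,
        "site_pearson": site_pearson,
        "aa_pearson": float(pearson),
        "n_conserved_sites": n_sites,
    }


def group_trend(seed: int, n_seeds: int = 10, n_residues: int = 500,
                n_proteins: int = 16) -> list[dict]:
    """Disordered-residue score gradient across the three synthetic groups.

    For each seed, draws ``n_residues`` disordered-residue scores per group
    by systematic (evenly spaced) sampling of the pooled group residues, so
    the sample's conserved fraction reflects the group's planted motif
    density rather than any single protein's draw, and runs the
    adjacent-group Mann–Whitney comparisons.
    """
    results = []
    for i in range(n_seeds):
        run_seed = _derive_seed(seed, 200 + i)
        cfg = SimConfig(seed=run_seed, n_proteins=n_proteins, n_homologs=2)
        proteins, _ = simulate_dataset(cfg)
        samples = {}
        for group in ("background", "client", "driver"):
            pooled = []
            for prot in proteins:
                if prot.truth["group"] != group:
                    continue
                track = score_protein(prot.llr, prot.plddt)
                pooled.extend(
                    track.loc[track["order_class"] == "disordered",
                              "esm2_score"])
            pooled = np.asarray(pooled)
            if pooled.size > n_residues:
                idx = (np.arange(n_residues) * pooled.size) // n_residues
                pooled = pooled[idx]
            samples[group] = pooled
        results.append({
            "means": {g: float(s.mean()) for g, s in samples.items()},
            "n": {g: int(s.size) for g, s in samples.items()},
            "background_vs_client": mann_whitney(
                samples["background"], samples["client"],
                "background", "client"),
            "client_vs_driver": mann_whitney(
                samples["client"], samples["driver"], "client", "driver"),
        })
    return results


def conserved_motif_membership(seed: int, n_seeds: int = 10,
                               min_len: int = 4) -> float:
    """Fraction of conserved residues (score ≤ 0.5) of driver-like proteins
    that lie inside reported motifs, averaged over seeds."""
    fractions = []
    for i in range(n_seeds):
        proteins = _driver_proteins(_derive_seed(seed, 300 + i), 2,
                                    n_homologs=2)
        inside = 0
        total = 0
        for prot in proteins:
            track = score_protein(prot.llr, prot.plddt)
            regions = [(r.start, r.end)
                       for r in extract_idrs(prot.plddt, prot.id)]
            found = find_motifs_in_regions(track, regions, min_len=min_len)
            covered = {p for m in found for p in m.positions()}
            conserved = track.loc[track["esm2_score"] <= 0.5, "position"]
            total += len(conserved)
            inside += conserved.isin(covered).sum()
        fractions.append(inside / total if total else float("nan"))
    return float(np.nanmean(fractions))


def pipeline_determinism(seed: int, workdir) -> tuple[dict, dict]:
    """Run generate→write→analyse twice with one seed; returns the two
    output-checksum dictionaries (byte-identical outputs ⇒ equal dicts)."""
    from pathlib import Path

    from .pipeline import RunConfig, run_pipeline
    from .synthetic import write_dataset

    workdir = Path(workdir)
    sums = []
    for label in ("first", "second"):
        data_dir = workdir / f"data_{label}"
        out_dir = workdir / f"out_{label}"
        cfg = SimConfig(seed=_derive_seed(seed, 400), n_proteins=2,
                        n_homologs=30)
        proteins, manifest = simulate_dataset(cfg)
        write_dataset(proteins, manifest, data_dir)
        report = run_pipeline(RunConfig(
            llr_table=str(data_dir / "llr.tsv"),
            plddt_table=str(data_dir / "plddt.tsv"),
            msa_dir=str(data_dir / "msa"),
            ps_segments=str(data_dir / "ps_segments.tsv"),
            group_labels=str(data_dir / "groups.tsv"),
            output_dir=str(out_dir),
            seed=seed,
        ))
        sums.append(report["output_checksums"])
    return sums[0], sums[1]
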