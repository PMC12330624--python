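"""Seed-reproducible synthetic proteins with planted ground truth.

Each generated protein bundles every input the analysis pipeline consumes —
sequence, per-residue LLR matrix, pLDDT trace, homolog MSA and
phase-separation segments — together with the planted truth (motif
intervals, per-site conservation probabilities, group label).

The construction couples mutational tolerance to conservation by design:
homolog residues are sampled i.i.d. from the softmax of each site's LLR
vector, so a site whose non-wild-type LLRs centre on −8 has wild-type
softmax weight 1/(1+19·e⁻⁸) ≈ 0.9937 (entropy ≈ 0.03 nats, far below the
conserved cutoff 0.5) while a background site with LLRs near 0 is close to
uniform (entropy ≈ ln 20, conservation ≈ 1/20).  Planted motifs therefore
stand out sharply in both the entropy track and the alignment, giving every
downstream stage a recoverable ground truth.

Three group labels emulate a phase-separation gradient: ``background``
(non-MLO-like, sparse motifs), ``client`` (intermediate) and ``driver``
(dense motifs whose disordered regions cover > 50% of a planted PS
segment).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .conservation import AlignmentSet
from .exceptions import GenerationError
from .idr import PSSegment
from .llr import AA_ALPHABET, LLRMatrix

#: Disorder-typical letters enriched in disordered runs.  The enrichment
#: table is a fixed modelling choice of this generator, not an empirical
#: composition.
DISORDER_ENRICHED = "GSPQKRE"
_DISORDER_WEIGHT = 3.0
FOLDED_ENRICHED = "AVLIFWYM"
_FOLDED_WEIGHT = 1.5

#: Minimum background residues kept between planted motifs so that the
#: proximity-merge step cannot bridge two distinct planted motifs: a merge
#: needs the spanning mean below 0.5, i.e. 3·s < 0.5·(m+s) for motif
#: residues near 0 and background near ln 20 ≈ 3, which is unreachable for
#: s = 7 with combined motif lengths ≤ 30.
MOTIF_SPACING = 7

#: Motif-count multipliers of the three planted groups.  Chosen by power
#: analysis of the two-level score mixture: the rank-test effect between
#: groups differing only in motif density is θ = ½ + Δf/2, so adjacent
#: density gaps of ≈ 0.2 (conserved fractions ≈ 0.05/0.25/0.47 of
#: disordered residues) are needed for the group contrast to be detectable
#: at 500 residues per group essentially always.  The driver density is
#: capped near 0.45 by motif spacing, so the client multiplier balances the
#: two adjacent gaps.
GROUP_MULTIPLIERS = {"background": 0.25, "client": 1.5, "driver": 2.7}


def _composition(enriched: str, weight: float) -> np.ndarray:
    w = np.ones(len(AA_ALPHABET))
    for aa in enriched:
        w[AA_ALPHABET.index(aa)] = weight
    return w / w.sum()


DISORDERED_COMPOSITION = _composition(DISORDER_ENRICHED, _DISORDER_WEIGHT)
FOLDED_COMPOSITION = _composition(FOLDED_ENRICHED, _FOLDED_WEIGHT)


@dataclass
class SimConfig:
    """Generator configuration; the seed fully determines every output."""

    n_proteins: int = 10
    length_range: tuple[int, int] = (250, 450)
    folded_run_length: tuple[int, int] = (30, 80)
    disordered_run_length: tuple[int, int] = (50, 130)
    folded_run_plddt: tuple[float, float] = (80.0, 98.0)
    disordered_run_plddt: tuple[float, float] = (35.0, 68.0)
    n_motifs_per_protein: tuple[int, int] = (3, 4)
    motif_density: float | None = 0.16
    motif_length: tuple[int, int] = (4, 15)
    motif_nonwt_llr_mean: float = -8.0
    motif_nonwt_llr_sd: float = 0.5
    background_nonwt_llr_mean: float = 0.0
    background_nonwt_llr_sd: float = 0.3
    n_homologs: int = 200
    indel_rate: float = 0.02
    ps_segment_policy: str = "by_group"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.indel_rate <= 1.0:
            raise GenerationError("indel_rate must lie in [0, 1]")
        if self.motif_length[0] < 1:
            raise GenerationError("motif lengths must be ≥ 1")


@dataclass
class SyntheticProtein:
    id: str
    sequence: str
    llr: LLRMatrix
    plddt: np.ndarray
    msa: AlignmentSet
    ps_segments: list[PSSegment]
    truth: dict = field(default_factory=dict)


def _draw_runs(cfg: SimConfig, rng, L: int) -> list[tuple[str, int, int]]:
    """Alternating folded/disordered runs covering [1, L], 1-based inclusive."""
    runs = []
    state = "folded" if rng.random() < 0.5 else "disordered"
    pos = 1
    while pos <= L:
        lo, hi = (cfg.folded_run_length if state == "folded"
                  else cfg.disordered_run_length)
        n = int(rng.integers(lo, hi + 1))
        end = min(pos + n - 1, L)
        runs.append((state, pos, end))
        pos = end + 1
        state = "disordered" if state == "folded" else "folded"
    if all(s != "disordered" for s, _, _ in runs):
        # force at least one disordered run so the protein passes the
        # 10%-disorder dataset filter with high probability
        s, a, b = runs[-1]
        runs[-1] = ("disordered", a, b)
    return runs


def _place_motifs(rng, runs, n_motifs: int, motif_lengths) -> list[tuple[int, int]]:
    """Plant disjoint motifs inside disordered runs, ≥ MOTIF_SPACING apart."""
    if n_motifs == 0:
        return []
    dis_runs = [(a, b) for s, a, b in runs if s == "disordered"]
    order = rng.permutation(len(dis_runs))
    placed: list[tuple[int, int]] = []
    remaining = list(motif_lengths)
    for k in order:
        a, b = dis_runs[k]
        pos = a + int(rng.integers(0, 4))
        while remaining:
            mlen = remaining[0]
            if pos + mlen - 1 > b:
                break
            placed.append((pos, pos + mlen - 1))
            remaining.pop(0)
            pos += mlen + MOTIF_SPACING + int(rng.integers(0, 3))
        if not remaining:
            break
    if remaining:
        raise GenerationError(
            f"cannot place {len(motif_lengths)} motifs: disordered capacity "
            f"exhausted with {len(remaining)} left"
        )
    return sorted(placed)


def _place_ps_segments(rng, runs, motifs, group: str, L: int) -> list[PSSegment]:
    """Plant a phase-separation segment according to the group label.

    driver: segment ⊂ slightly-extended motif-bearing disordered run, so the
    run covers > 50% of it.  client: segment mostly outside a disordered
    run, overlap ≈ 20% of its length.  background: no segment.
    """
    if group == "background":
        return []
    dis_runs = [(a, b) for s, a, b in runs if s == "disordered"]
    motif_runs = [
        (a, b) for a, b in dis_runs
        if any(a <= ms and me <= b for ms, me in motifs)
    ]
    candidates = motif_runs or dis_runs
    a, b = candidates[int(rng.integers(0, len(candidates)))]
    if group == "driver":
        li = b - a + 1
        ext_a = int(rng.integers(0, max(1, int(0.3 * li)) + 1))
        ext_b = int(rng.integers(0, max(1, int(0.3 * li)) + 1))
        seg = PSSegment("", max(1, a - ext_a), min(L, b + ext_b), "planted:driver")
        return [seg]
    # client: anchor a small overlap at one run boundary
    seg_len = int(rng.integers(20, 61))
    overlap = max(1, int(0.2 * seg_len))
    start, end = b - overlap + 1, b - overlap + seg_len
    if end > L:  # fall back to the left boundary
        start, end = a + overlap - seg_len, a + overlap - 1
        if start < 1:
            start = 1
            end = min(L, seg_len)
    run_cov = (min(end, b) - max(start, a) + 1) / (end - start + 1)
    if run_cov > 0.5:  # clipping at the termini inflated the overlap
        end = min(L, b + (b - a + 1))  # widen outside; keep coverage ≤ 0.5
    return [PSSegment("", start, end, "planted:client")]


def simulate_protein(cfg: SimConfig, rng=None, protein_id: str = "synth0001",
                     group: str = "driver",
                     motif_multiplier: float | None = None) -> SyntheticProtein:
    """Generate one synthetic protein with planted ground truth.

    Raises :class:`GenerationError` when the requested motif count cannot be
    placed inside the drawn disordered runs.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if motif_multiplier is None:
        motif_multiplier = GROUP_MULTIPLIERS.get(group, 1.0)

    L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    runs = _draw_runs(cfg, rng, L)

    plddt = np.empty(L)
    for state, a, b in runs:
        lo, hi = (cfg.folded_run_plddt if state == "folded"
                  else cfg.disordered_run_plddt)
        plddt[a - 1:b] = rng.uniform(lo, hi, size=b - a + 1)

    seq_idx = np.empty(L, dtype=int)
    for state, a, b in runs:
        comp = FOLDED_COMPOSITION if state == "folded" else DISORDERED_COMPOSITION
        seq_idx[a - 1:b] = rng.choice(len(AA_ALPHABET), size=b - a + 1, p=comp)
    sequence = "".join(AA_ALPHABET[k] for k in seq_idx)

    # density-controlled planting: the motif count targets a fixed fraction
    # of the disordered capacity, so group densities do not drift with the
    # drawn geometry; count-distribution planting is the fallback
    if cfg.motif_density is not None:
        capacity = sum(b - a + 1 for s, a, b in runs if s == "disordered")
        mean_len = (cfg.motif_length[0] + cfg.motif_length[1]) / 2
        target = cfg.motif_density * motif_multiplier * capacity
        n_motifs = int(round(target / mean_len))
    else:
        base = int(rng.integers(cfg.n_motifs_per_protein[0],
                                cfg.n_motifs_per_protein[1] + 1))
        n_motifs = int(round(base * motif_multiplier))
    motif_lengths = [int(rng.integers(cfg.motif_length[0], cfg.motif_length[1] + 1))
                     for _ in range(n_motifs)]
    motifs = _place_motifs(rng, runs, n_motifs, motif_lengths)

    llr = rng.normal(cfg.background_nonwt_llr_mean, cfg.background_nonwt_llr_sd,
                     size=(L, len(AA_ALPHABET)))
    in_motif = np.zeros(L, dtype=bool)
    for ms, me in motifs:
        in_motif[ms - 1:me] = True
    llr[in_motif] = rng.normal(cfg.motif_nonwt_llr_mean, cfg.motif_nonwt_llr_sd,
                               size=(int(in_motif.sum()), len(AA_ALPHABET)))
    llr[np.arange(L), seq_idx] = 0.0
    matrix = LLRMatrix(protein_id, sequence, llr)

    # homologs sampled per site from softmax(LLR) via the Gumbel-max trick
    logits = llr[None, :, :]
    gumbel = rng.gumbel(size=(cfg.n_homologs, L, len(AA_ALPHABET)))
    hom_idx = np.argmax(logits + gumbel, axis=2)
    gaps = rng.random((cfg.n_homologs, L)) < cfg.indel_rate
    homologs = []
    for h in range(cfg.n_homologs):
        chars = [AA_ALPHABET[k] for k in hom_idx[h]]
        for i in np.flatnonzero(gaps[h]):
            chars[i] = "-"
        homologs.append((f"hom{h + 1:04d}", "".join(chars)))
    msa = AlignmentSet(protein_id, sequence, homologs)

    segments = [
        PSSegment(protein_id, s.start, s.end, s.source_note)
        for s in _place_ps_segments(rng, runs, motifs, group, L)
    ]

    # planted per-site conservation probability: softmax weight of WT (= 0 LLR)
    expv = np.exp(llr - llr.max(axis=1, keepdims=True))
    wt_softmax = expv[np.arange(L), seq_idx] / expv.sum(axis=1)

    truth = {
        "group": group,
        "motifs": [[int(a), int(b)] for a, b in motifs],
        "wt_softmax": wt_softmax,
        "disordered_runs": [[int(a), int(b)] for s, a, b in runs if s == "disordered"],
    }
    return SyntheticProtein(protein_id, sequence, matrix, plddt, msa,
                            segments, truth)


def simulate_dataset(cfg: SimConfig, group_spec: dict | None = None):
    """Generate a labelled dataset of synthetic proteins.

    Parameters
    ----------
    group_spec : mapping group label → motif-density multiplier; defaults to
        the background/client/driver gradient.  Each group receives
        ``cfg.n_proteins`` proteins.

    Returns
    -------
    (proteins, manifest) where the manifest records the seed, group spec and
    every planted truth item.

    A protein whose drawn geometry cannot host the requested motif count is
    redrawn from a fresh deterministic substream (≤ 20 attempts).
    """
    if group_spec is None:
        group_spec = dict(GROUP_MULTIPLIERS)
    proteins: list[SyntheticProtein] = []
    manifest_rows = []
    k = 0
    for group, multiplier in group_spec.items():
        for _ in range(cfg.n_proteins):
            k += 1
            pid = f"synth{k:04d}"
            prot = None
            for attempt in range(20):
                rng = np.random.default_rng([cfg.seed % (2**31), k, attempt])
                try:
                    prot = simulate_protein(cfg, rng, pid, group, multiplier)
                    break
                except GenerationError:
                    continue
            if prot is None:
                raise GenerationError(
                    f"{pid}: could not place motifs in 20 geometry draws"
                )
            proteins.append(prot)
            manifest_rows.append({
                "protein_id": pid,
                "group": group,
                "length": len(prot.sequence),
                "n_motifs": len(prot.truth["motifs"]),
                "motifs": prot.truth["motifs"],
                "disordered_runs": prot.truth["disordered_runs"],
                "ps_segments": [[s.start, s.end] for s in prot.ps_segments],
            })
    manifest = {
        "seed": cfg.seed,
        "group_spec": {g: float(m) for g, m in group_spec.items()},
        "n_proteins_per_group": cfg.n_proteins,
        "proteins": manifest_rows,
    }
    return proteins, manifest


# ---------------------------------------------------------------------------
# On-disk export in the formats the analysis modules consume


def write_dataset(proteins, manifest, outdir) -> None:
    """Write FASTA, LLR/pLDDT/PS-segment TSVs, per-protein A3M MSAs, group
    labels and the truth manifest under ``outdir``."""
    from pathlib import Path

    import pandas as pd

    from .idr import write_ps_segments
    from .llr import write_llr_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "msa").mkdir(exist_ok=True)

    with open(outdir / "sequences.fasta", "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.sequence}\n")

    write_llr_table([p.llr for p in proteins], outdir / "llr.tsv")

    plddt_rows = []
    for p in proteins:
        for i, v in enumerate(p.plddt, start=1):
            plddt_rows.append((p.id, i, v))
    pd.DataFrame(plddt_rows, columns=["protein_id", "position", "plddt"]).to_csv(
        outdir / "plddt.tsv", sep="\t", index=False, float_format="%.4f")

    for p in proteins:
        with open(outdir / "msa" / f"{p.id}.a3m", "w") as fh:
            fh.write(f">{p.msa.reference_id}\n{p.msa.reference_aligned}\n")
            for hid, seq in p.msa.homologs:
                fh.write(f">{hid}\n{seq}\n")

    segments = [s for p in proteins for s in p.ps_segments]
    write_ps_segments(segments, outdir / "ps_segments.tsv")

    pd.DataFrame(
        [(p.id, p.truth["group"]) for p in proteins],
        columns=["protein_id", "group"],
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)

    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
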