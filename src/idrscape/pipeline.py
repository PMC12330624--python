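"""End-to-end orchestration: score → conserve → annotate → motifs → compare.

The pipeline consumes a directory of tabular inputs (LLR tables, pLDDT
tracks, optional per-protein MSAs, optional phase-separation segments and
group labels), runs every analysis stage whose inputs are present, and
writes deterministic tabular outputs plus a machine-readable JSON report.
Re-running with the same configuration and inputs reproduces byte-identical
tables; the configuration is serialised into the output directory for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation as cons
from . import idr as idrmod
from . import llr as llrmod
from . import motifs as motifmod
from . import stats as statsmod
from .exceptions import ReconciliationError

logger = logging.getLogger("idrscape.pipeline")


@dataclass
class RunConfig:
    """Inputs, thresholds and outputs of one pipeline run.

    Every threshold default is the published analysis constant: disorder at
    pLDDT ≤ 70, conserved at score ≤ 0.5, flexible at ≥ 2.0, motif threshold
    0.5 with merge gap 8 and minimum length 4, homolog identity floor 0.20,
    driving coverage 0.5, redundancy ceiling 0.50.
    """

    llr_table: str = ""
    plddt_table: str = ""
    msa_dir: str = ""
    ps_segments: str = ""
    group_labels: str = ""
    output_dir: str = "idrscape_out"
    plddt_disorder: float = 70.0
    conserved_max: float = 0.5
    flexible_min: float = 2.0
    motif_threshold: float = 0.5
    merge_gap: int = 8
    min_len: int = 4
    min_identity: float = 0.20
    driving_coverage: float = 0.5
    redundancy_max_identity: float = 0.50
    min_disorder_fraction: float = 0.10
    apply_dataset_filters: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat key=value (or JSON) config file."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in fields:
                raise ReconciliationError(f"unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                value = str(value).lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                value = int(value)
            elif isinstance(default, float):
                value = float(value)
            kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t" if path.suffix == ".tsv" else ",",
              index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages whose inputs are configured; returns the report.

    Stages lacking their inputs are skipped with a logged warning (e.g. no
    MSA directory → no conservation track).  A protein present in the LLR
    table but missing from the pLDDT table (or vice versa) is a
    reconciliation error.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}, "counts": {}}

    if not cfg.llr_table:
        raise ReconciliationError("no LLR table configured; nothing to score")
    matrices = llrmod.read_llr_tables(cfg.llr_table)
    plddt = llrmod.read_plddt_table(cfg.plddt_table) if cfg.plddt_table else {}
    if plddt:
        missing = sorted(set(matrices) ^ set(plddt))
        if missing:
            raise ReconciliationError(
                f"protein IDs not shared by LLR and pLDDT inputs: {missing}"
            )
    report["counts"]["proteins_in"] = len(matrices)

    # dataset-construction filters (disorder fraction, redundancy)
    ids = list(matrices)
    if cfg.apply_dataset_filters and plddt:
        ids = [pid for pid in ids
               if idrmod.disorder_fraction_filter(
                   plddt[pid], cfg.min_disorder_fraction, cfg.plddt_disorder)]
        logger.info("disorder-fraction filter: %d -> %d proteins",
                    len(matrices), len(ids))
        ids = idrmod.redundancy_filter(
            [(pid, matrices[pid].sequence) for pid in ids],
            cfg.redundancy_max_identity)
        logger.info("redundancy filter: -> %d proteins", len(ids))
    report["counts"]["proteins_retained"] = len(ids)

    # stage: score
    tracks = []
    for pid in ids:
        tracks.append(llrmod.score_protein(matrices[pid], plddt.get(pid)))
    track = pd.concat(tracks, ignore_index=True)
    report["stages"]["score"] = {"n_residues": int(len(track))}

    # stage: conservation
    if cfg.msa_dir:
        cs_frames = []
        for pid in ids:
            hits = sorted(Path(cfg.msa_dir).glob(f"{pid}.*"))
            if not hits:
                logger.warning("no MSA for %s; conservation skipped", pid)
                continue
            aln = cons.parse_alignment(hits[0])
            aln = cons.filter_homologs(aln, cfg.min_identity)
            cs_frames.append(cons.conservation_scores(aln))
        if cs_frames:
            cs = pd.concat(cs_frames, ignore_index=True)
            track = track.merge(
                cs[["protein_id", "position", "cs", "n_match", "n_nongap"]],
                on=["protein_id", "position"], how="left")
            _write_csv(cs, out / "conservation.tsv")
            report["stages"]["conserve"] = {"n_proteins": len(cs_frames)}
    else:
        logger.warning("no MSA directory configured; conservation stage skipped")

    llrmod.write_track(track, out / "tracks.tsv")

    # stage: IDR annotation
    idrs_by_protein: dict[str, list] = {}
    if plddt:
        segments = (idrmod.read_ps_segments(cfg.ps_segments)
                    if cfg.ps_segments else {})
        all_idrs = []
        for pid in ids:
            regions = idrmod.extract_idrs(plddt[pid], pid, cfg.plddt_disorder)
            regions = idrmod.classify_idrs(regions, segments.get(pid, []))
            idrs_by_protein[pid] = regions
            all_idrs.extend(regions)
        idrmod.write_idrs(all_idrs, out / "idrs.tsv")
        report["stages"]["annotate"] = {"n_idrs": len(all_idrs)}
    else:
        logger.warning("no pLDDT input; IDR annotation skipped")

    # stage: motifs (region-restricted to each IDR)
    all_motifs = []
    for pid in ids:
        ptrack = track[track["protein_id"] == pid]
        regions = [(r.start, r.end) for r in idrs_by_protein.get(pid, [])]
        if not regions:
            continue
        all_motifs.extend(
            motifmod.find_motifs_in_regions(
                ptrack.reset_index(drop=True), regions,
                cfg.motif_threshold, cfg.merge_gap, cfg.min_len))
    motif_table = motifmod.motifs_to_frame(all_motifs)
    _write_csv(motif_table, out / "motifs.csv")
    report["stages"]["motifs"] = {"n_motifs": len(all_motifs)}

    # stage: group comparison of disordered-residue scores
    if cfg.group_labels:
        labels = pd.read_csv(cfg.group_labels, sep="\t")
        track_g = track.merge(labels, on="protein_id", how="left")
        disordered = track_g[track_g["order_class"] == "disordered"]
        samples = {
            str(g): sub["esm2_score"].to_numpy()
            for g, sub in disordered.groupby("group")
            if len(sub)
        }
        if len(samples) >= 2:
            comparisons = statsmod.compare_groups(samples)
            _write_csv(comparisons, out / "comparisons.tsv")
            report["stages"]["compare"] = {
                "groups": {g: int(v.size) for g, v in samples.items()}
            }

    # stage: per-amino-acid profiles over disordered residues
    if plddt:
        profiles = statsmod.aa_mean_llr(
            track, {pid: matrices[pid] for pid in ids},
            residue_filter=lambda t: t["order_class"] == "disordered")
        profiles_out = profiles.reset_index()
        _write_csv(profiles_out, out / "aa_profiles.csv")
        report["stages"]["profiles"] = {
            "n_letters": int((profiles["n_residues"] > 0).sum())
        }

    # per-protein phase-separation localisation probability p
    if idrs_by_protein and cfg.ps_segments:
        rows = []
        for pid in ids:
            p = statsmod.ps_localization_probability(
                track[track["protein_id"] == pid], idrs_by_protein[pid],
                cfg.conserved_max)
            rows.append((pid, p))
        _write_csv(pd.DataFrame(rows, columns=["protein_id", "p_ps"]),
                   out / "ps_localization.tsv")

    cfg.to_file(out / "run_config.json")
    report["output_checksums"] = output_checksums(out)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def output_checksums(outdir) -> dict[str, str]:
    """SHA-256 of every tabular output, for determinism audits."""
    sums = {}
    for path in sorted(Path(outdir).glob("*.*")):
        if path.suffix in (".tsv", ".csv"):
            sums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return sums
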