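"""End-to-end synthetic study: generate, analyse, compare groups.

Generates a labelled dataset (background / client / driver groups with
increasing planted motif density), writes it in the formats the pipeline
consumes, runs every stage, and prints the group comparison table: the
mean disordered-residue entropy score falls from background to driver, the
synthetic analogue of phase-separation drivers carrying more conserved
disordered residues.
"""

import tempfile
from pathlib import Path

import pandas as pd

from idrscape import RunConfig, SimConfig, run_pipeline, simulate_dataset
from idrscape.synthetic import write_dataset

cfg = SimConfig(seed=11, n_proteins=4, n_homologs=50)
proteins, manifest = simulate_dataset(cfg)
print(f"generated {len(proteins)} proteins "
      f"({cfg.n_proteins} per group), seed {cfg.seed}")

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    out = Path(tmp) / "out"
    write_dataset(proteins, manifest, data)
    report = run_pipeline(RunConfig(
        llr_table=str(data / "llr.tsv"),
        plddt_table=str(data / "plddt.tsv"),
        msa_dir=str(data / "msa"),
        ps_segments=str(data / "ps_segments.tsv"),
        group_labels=str(data / "groups.tsv"),
        output_dir=str(out),
        seed=cfg.seed,
    ))
    print(f"stages run: {sorted(report['stages'])}")
    print(f"motifs found: {report['stages']['motifs']['n_motifs']}")

    comparisons = pd.read_csv(out / "comparisons.tsv", sep="\t")
    track = pd.read_csv(out / "tracks.tsv", sep="\t")
    labels = pd.read_csv(data / "groups.tsv", sep="\t")

print()
disordered = track.merge(labels, on="protein_id")
disordered = disordered[disordered["order_class"] == "disordered"]
print("mean disordered-residue entropy score by group:")
print(disordered.groupby("group")["esm2_score"].mean().round(3).to_string())
print()
print(comparisons.to_string(index=False))
print()
print("Lower mean score = more mutation-constrained disordered residues;")
print("the Mann-Whitney tiers show the planted density gradient is")
print("recovered as a significant group effect.")
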