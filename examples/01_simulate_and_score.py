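"""Simulate a small cfDNA cohort and score regional end-motif diversity.

Builds a toy reference genome, simulates a longitudinal two-group cohort
in which non-responders have less diverse fragment 5' end motifs at a few
genomic bins, then recomputes per-bin rMDS from the fragment files by
reading the reference — exactly as one would for real BED fragment data.
"""

import tempfile
from pathlib import Path

from rmdskit import SimConfig, load_layout, make_toy_reference, simulate_cohort
from rmdskit.pipeline import drop_incomplete_bins, zrmds_matrix

workdir = Path(tempfile.mkdtemp(prefix="rmds_example_"))
ref = make_toy_reference(n_chromosomes=2, chrom_length=1_000_000, seed=1, outdir=workdir)
layout = load_layout(ref.chrom_sizes, bin_size=100_000)

effect_bins = (0, 3, 7, 12, 16)
cfg = SimConfig(
    n_chromosomes=2, chrom_length=1_000_000, bin_size=100_000,
    n_patients_per_group=5, coverage=400,
    effect_bins=effect_bins, effect_delta=0.2,
    trajectory_pattern={b: "cluster2" for b in effect_bins},
    seed=2,
)
sim = simulate_cohort(cfg, layout, ref.fasta, workdir / "fragments")
print(f"simulated {len(sim.fragment_files)} samples "
      f"({cfg.n_patients_per_group} patients/group x {len(cfg.timepoints)} timepoints)")

matrix = drop_incomplete_bins(
    zrmds_matrix(sim.fragment_files, str(ref.fasta), layout, min_ends=50)
)
print(f"z-rMDS matrix: {matrix.shape[0]} samples x {matrix.shape[1]} bins")

meta = sim.metadata.set_index("sample_id")
resp = meta.loc[matrix.index, "response"] == "Responder"
effect_ids = [layout.bin_ids[b] for b in effect_bins]
r_mean = matrix.loc[resp.to_numpy(), effect_ids].mean().mean()
n_mean = matrix.loc[(~resp).to_numpy(), effect_ids].mean().mean()
print(f"mean z-rMDS at effect bins   responders: {r_mean:+.2f}   "
      f"non-responders: {n_mean:+.2f}")
print("A negative gap for non-responders reflects the planted drop in "
      "end-motif diversity (lower normalized entropy) at those bins.")
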