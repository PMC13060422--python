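"""Classify treatment response from reduced rMDS features.

Simulates a planted-effect cohort end to end (fragments -> z-rMDS matrix),
reduces it with truncated SVD and evaluates a logistic classifier under
patient-level repeated cross-validation and leave-one-institute-out
(LOIO) — no patient ever appears in both train and test, and the patient
prediction uses the most recent available timepoint.
"""

import tempfile
from pathlib import Path

from rmdskit import (
    EvalScheme,
    SimConfig,
    load_layout,
    make_toy_reference,
    run_evaluation,
    simulate_cohort,
)
from rmdskit.pipeline import drop_incomplete_bins, zrmds_matrix

workdir = Path(tempfile.mkdtemp(prefix="rmds_classify_"))
ref = make_toy_reference(2, 2_000_000, seed=10, outdir=workdir)
layout = load_layout(ref.chrom_sizes, bin_size=100_000)
effect = tuple(range(0, 40, 2))
cfg = SimConfig(
    n_chromosomes=2, chrom_length=2_000_000, bin_size=100_000,
    n_patients_per_group=8, coverage=300,
    effect_bins=effect, effect_delta=0.25,
    trajectory_pattern={b: "cluster2" for b in effect},
    seed=11,
)
sim = simulate_cohort(cfg, layout, ref.fasta, workdir / "frags")
matrix = drop_incomplete_bins(
    zrmds_matrix(sim.fragment_files, str(ref.fasta), layout, min_ends=50)
)

for label, scheme in (
    ("repeated 5-fold CV", EvalScheme(kind="repeated_kfold", n_folds=5, n_repeats=4, seed=0)),
    ("leave-one-institute-out", EvalScheme(kind="leave_one_institute_out")),
):
    report = run_evaluation(matrix, sim.metadata, scheme,
                            correction_policy="none", n_components=6)
    agg = report.aggregate
    print(f"{label}: patient-level AUC = {agg['roc_auc_mean']:.2f} "
          f"± {agg['roc_auc_sd']:.2f}, accuracy = {agg['accuracy_mean']:.2f}, "
          f"sens@95%spec = {agg['sens_at_95spec_mean']:.2f} "
          f"({report.n_splits} splits, {report.n_skipped} skipped)")
print("AUC near 1 under CV reflects the strong planted entropy difference; "
      "LOIO is the harder, cross-site generalization setting.")
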