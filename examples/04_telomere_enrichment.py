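"""Test whether a bin set is enriched near chromosome ends.

Compares a telomere-adjacent cluster and a random cluster against a null
of 100,000 uniformly placed same-width bins, using a one-sided
Mann-Whitney U test and a permutation test on the mean distance.
"""

import numpy as np

from rmdskit import telomere_enrichment
from rmdskit.fragio import GenomeLayout

layout = GenomeLayout.from_sizes({f"chr{i}": 25_000_000 for i in range(1, 9)},
                                 bin_size=500_000)
bins_per_chrom = 50

telomeric = []
for c in range(8):
    telomeric += [c * bins_per_chrom + j for j in range(3)]
    telomeric += [(c + 1) * bins_per_chrom - 1 - j for j in range(3)]

rng = np.random.default_rng(1)
random_bins = rng.choice(layout.n_bins, size=48, replace=False)

for name, bins in (("telomere-adjacent", telomeric), ("random", random_bins)):
    res = telomere_enrichment(bins, layout, n_null=100_000, n_perm=100_000, seed=0)
    print(f"{name:18s} cluster ({len(bins)} bins): "
          f"mean distance {res.observed_distances.mean()/1e6:.2f} Mb "
          f"vs null {res.null_mean/1e6:.2f} Mb | "
          f"Mann-Whitney p = {res.mannwhitney_p:.2e}, "
          f"permutation p = {res.permutation_p:.2e}")
print("Small p-values for the first cluster only: its bins sit closer to "
      "chromosome ends than uniformly placed bins of the same width.")
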