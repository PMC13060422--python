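# rmdskit

Regional motif diversity score (rMDS) analysis of cell-free DNA fragment
end motifs.

Plasma cfDNA is cut by nucleases whose sequence preferences depend on the
chromatin state of the contributing cells, so the k-mer at a fragment's 5′
terminus is an epigenetic readout. Genome-wide summaries of end-motif
diversity compress this into one number per sample; `rmdskit` instead
scores it **per genomic bin**, as the normalized Shannon entropy of 5′ end
4-mer motifs:

    rMDS_j = Σ_i −P_ij · log P_ij / log 4^k,        Z_j = (rMDS_j − μ)/σ

where P_ij is the relative frequency of motif *i* in bin *j*; rMDS ranges
from 0 (one motif carries every end) to 1 (uniform usage over all 4^k
motifs), and Z_rMDS is the per-sample z-transform across bins. The package
is aimed at cfDNA fragmentomics analyses of longitudinal, multi-site
cohorts — e.g. monitoring immunotherapy response from low-coverage WGS —
and covers the full path from fragment intervals to patient-level
classification:

- **fragio** — fragment QC (mapq ≥ 30, 50–350 bp, blacklist exclusion),
  genome binning with blacklist/mappability masks, and end-motif counting
  against an indexed reference (5′ side, plus a composition-matched 3′
  control).
- **rmds_core** — per-bin rMDS and Z_rMDS, sliding-window locus tracks,
  fragment downsampling and depth-stability analysis.
- **harmonize** — batch correction by sum-contrast regression with the
  response label as a *preserved* covariate, standardization, truncated
  SVD, silhouette scores.
- **differential** — per-bin GLS with patient blocking (duplicate-
  correlation), empirical-Bayes moderated t statistics, Storey/BH
  q-values.
- **regions** — Ward clustering of differential bins by longitudinal
  pattern, trajectory summaries, telomere-proximity enrichment against a
  random-bin null (Mann–Whitney + permutation).
- **respond** — response classifiers on SVD-reduced features under three
  patient-level validation schemes, with most-recent-timepoint patient
  predictions and sensitivity-at-95%-specificity.
- **synthdata** — a cohort simulator that writes fragment files whose
  reference-context end motifs realize planted Dirichlet-multinomial
  distributions, with batch tilts and timepoint trajectory archetypes.

## Worked example

`examples/` contains one narrative script per capability. For instance,
simulating a cohort in which non-responders have less diverse end motifs
at five bins, then recomputing the score from the fragment files:

```bash
$ python examples/01_simulate_and_score.py
simulated 30 samples (5 patients/group x 3 timepoints)
z-rMDS matrix: 30 samples x 20 bins
mean z-rMDS at effect bins   responders: -0.09   non-responders: -1.70
```

The gap of ~1.6 z-units at the planted bins is the regional entropy
deficit the simulator injected for non-responders. Downstream, the
batch-correction and classification stages behave the same way on this
matrix as on real Z_rMDS profiles:

```bash
$ python examples/02_batch_correction.py
institute silhouette: +0.576 -> -0.013
response  silhouette: +0.125 -> +0.359

$ python examples/05_response_classification.py
repeated 5-fold CV: patient-level AUC = 1.00 ± 0.00, accuracy = 1.00, ...
leave-one-institute-out: patient-level AUC = 1.00 ± 0.00, accuracy = 1.00, ...

$ python examples/06_depth_stability.py
full depth: 5.5x over the toy genome
  kept fraction  0.500 (~ 2.74x): Pearson r vs full depth = 0.918
  kept fraction  0.100 (~ 0.55x): Pearson r vs full depth = 0.627
  ...
```

After correction the institute separation collapses to ~0 while the
response separation survives (it is a preserved covariate); the classifier
recovers the planted effect perfectly at this effect size; and profile
correlation decays monotonically as depth falls.

A thin CLI wraps the same library calls (`rmdskit simulate | motifs |
rmds | sliding | downsample | stability | correct | embed | silhouette |
diff | cluster | enrich-telomere | classify | run`); `rmdskit run
--config cfg.txt` executes the whole pipeline from a flat key=value file
and writes per-stage TSV/JSON artifacts with content hashes into a
provenance record.

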