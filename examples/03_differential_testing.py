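"""Moderated differential testing with repeated measures per patient.

Simulates a longitudinal matrix (three timepoints per patient, intra-
patient correlation 0.4) with 60 of 800 bins carrying a true response
difference, estimates the consensus within-patient correlation, fits the
block-equicorrelated GLS with empirical-Bayes variance moderation, and
calls bins at q < 0.1.
"""

import numpy as np
import pandas as pd

from rmdskit import estimate_block_correlation, fit_differential

rng = np.random.default_rng(4)
n_patients, n_bins, n_effect = 40, 800, 60
rows, meta = [], []
for p in range(n_patients):
    resp = "Responder" if p < n_patients // 2 else "Non-Responder"
    intercept = rng.normal(0, np.sqrt(0.4), n_bins)
    for t, tp in enumerate(("Screen", "Day0", "AdjWk1")):
        y = intercept + rng.normal(0, np.sqrt(0.6), n_bins)
        if resp == "Responder":
            y[:n_effect] += 0.8
        sid = f"P{p:02d}_{tp}"
        rows.append(y)
        meta.append({"sample_id": sid, "patient_id": f"P{p:02d}",
                     "response": resp, "timepoint": tp,
                     "age": int(rng.integers(30, 80))})
meta = pd.DataFrame(meta)
matrix = pd.DataFrame(rows, index=meta["sample_id"],
                      columns=[f"bin{j}" for j in range(n_bins)])

rho = estimate_block_correlation(matrix, meta, covariates=["age"])
result = fit_differential(matrix, meta, covariates=["age"], rho=rho)
sig = result.significant(0.1)
true_hits = sig["bin_id"].str.replace("bin", "").astype(int) < n_effect

print(f"consensus intra-patient correlation rho = {rho:.3f} (planted 0.4)")
print(f"EB prior: d0 = {result.d0:.1f}, s0^2 = {result.s0sq:.3f}")
print(f"{len(sig)} bins at q < 0.1; {true_hits.sum()} of the {n_effect} "
      f"planted bins recovered, {(~true_hits).sum()} false positives")
print("Moderated t-tests borrow variance strength across bins, keeping the "
      "false-discovery rate controlled at this modest cohort size.")
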