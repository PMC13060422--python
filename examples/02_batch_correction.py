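"""Remove a technical batch effect while preserving the response signal.

Plants additive per-institute offsets plus a genuine response difference
in a z-rMDS-like matrix, fits the sum-contrast regression with response as
a preserved covariate, and shows that correction collapses the institute
separation while the response separation survives.
"""

import numpy as np
import pandas as pd

from rmdskit import apply_correction, fit_correction, silhouette_separation

rng = np.random.default_rng(0)
rows, meta = [], []
for inst, offset in (("UC", 0.6), ("OSU", -0.6)):
    for s in range(40):
        resp = "Responder" if s % 2 == 0 else "Non-Responder"
        y = rng.normal(0, 0.3, 80) + offset
        if resp == "Responder":
            y[:30] += 0.8  # the biology we must not remove
        sid = f"{inst}_{s:02d}"
        rows.append(y)
        meta.append({"sample_id": sid, "patient_id": sid, "institute": inst,
                     "response": resp})
meta = pd.DataFrame(meta)
matrix = pd.DataFrame(rows, index=meta["sample_id"],
                      columns=[f"bin{j}" for j in range(80)])

resp = meta.set_index("sample_id")["response"]
inst = meta.set_index("sample_id")["institute"]
_, sil_resp0 = silhouette_separation(matrix, resp)
_, sil_inst0 = silhouette_separation(matrix, inst)

model = fit_correction(matrix, meta, batch_factors=["institute"])
corrected = apply_correction(matrix, meta, model)
_, sil_resp1 = silhouette_separation(corrected, resp)
_, sil_inst1 = silhouette_separation(corrected, inst)

print(f"institute silhouette: {sil_inst0:+.3f} -> {sil_inst1:+.3f}")
print(f"response  silhouette: {sil_resp0:+.3f} -> {sil_resp1:+.3f}")
print("The institute separation collapses toward 0 after correction; the "
      "response separation is retained (it was a preserved covariate, so "
      "its term was never subtracted).")
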