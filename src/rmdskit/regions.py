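"""Longitudinal clustering of differential bins and telomere enrichment.

Significant bins are clustered by their value pattern across all samples
(ordered by response group, patient, timepoint) with Ward linkage on
Euclidean distance, cut to a fixed number of clusters; labels are
renumbered by descending cluster size for determinism. Telomere proximity
of a bin is the distance from its midpoint to the nearest chromosome end,
compared against a null of randomly placed same-width bins by a one-sided
Mann-Whitney U test and a permutation test on the mean distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .fragio import GenomeLayout

__all__ = [
    "ClusterAssignment",
    "enrichment_from_distances",
    "EnrichmentResult",
    "cluster_bins",
    "trajectory_summary",
    "telomere_distance",
    "telomere_enrichment",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # bin_id -> cluster label (1..n_clusters)
    n_clusters: int
    linkage: str = "ward"
    feature_order: list[str] = field(default_factory=list)

    def bins_in(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def cluster_bins(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    n_clusters: int = 3,
) -> ClusterAssignment:
    """Ward-cluster significant bins by their cross-sample value pattern.

    ``matrix`` is samples x (significant) bins. Each bin's feature vector
    is its column ordered by (response, patient, timepoint); duplicated
    bins are at zero distance and always co-cluster. Labels are renumbered
    by descending cluster size (ties broken by first occurrence).
    """
    if matrix.shape[1] < n_clusters:
        raise ValueError("fewer bins than clusters")
    meta = metadata.set_index("sample_id").loc[matrix.index].rename_axis("sample_id").reset_index()
    if "timepoint" not in meta:
        raise ValueError("metadata must carry a timepoint column")
    order = meta.sort_values(
        ["response", "patient_id", "timepoint"], kind="stable"
    )["sample_id"].tolist()
    feats = matrix.loc[order].to_numpy().T  # bins x samples
    Z = hierarchy.linkage(feats, method="ward")
    raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    # renumber by descending size, ties by first appearance
    uniq = pd.Series(raw).value_counts(sort=False)
    ranked = sorted(
        uniq.index, key=lambda c: (-uniq[c], int(np.argmax(raw == c)))
    )
    remap = {old: i + 1 for i, old in enumerate(ranked)}
    labels = pd.Series([remap[c] for c in raw], index=matrix.columns, name="cluster")
    return ClusterAssignment(
        labels=labels, n_clusters=n_clusters, feature_order=order
    )


def trajectory_summary(
    matrix: pd.DataFrame,
    assignment: ClusterAssignment,
    metadata: pd.DataFrame,
    timepoint_order: list[str] | None = None,
) -> pd.DataFrame:
    """Mean rMDS trajectory per (cluster, response group, timepoint).

    Per sample, bin values are averaged within each cluster; per stratum
    the mean is taken over patients (one value per patient and timepoint)
    with a 95% t-interval across patients. Strata missing for a patient
    are computed from the remaining patients.
    """
    meta = metadata.set_index("sample_id").loc[matrix.index].rename_axis("sample_id").reset_index()
    rows = []
    for cluster in sorted(assignment.labels.unique()):
        bins = assignment.bins_in(cluster)
        per_sample = matrix[bins].mean(axis=1)
        df = meta.assign(value=per_sample.to_numpy())
        for (resp, tp), sub in df.groupby(["response", "timepoint"], sort=False):
            pat_means = sub.groupby("patient_id")["value"].mean().to_numpy()
            m = float(pat_means.mean())
            n = len(pat_means)
            if n > 1 and pat_means.std(ddof=1) > 0:
                half = float(
                    stats.t.ppf(0.975, n - 1) * pat_means.std(ddof=1) / np.sqrt(n)
                )
            else:
                half = 0.0
            rows.append(
                {
                    "cluster": cluster,
                    "response": resp,
                    "timepoint": tp,
                    "mean": m,
                    "ci_low": m - half,
                    "ci_high": m + half,
                    "n_patients": n,
                }
            )
    out = pd.DataFrame(rows)
    if timepoint_order is not None:
        out["timepoint"] = pd.Categorical(out["timepoint"], timepoint_order, ordered=True)
        out = out.sort_values(["cluster", "response", "timepoint"]).reset_index(drop=True)
    return out


def telomere_distance(bin_index: int, layout: GenomeLayout) -> int:
    """Distance (bp) from the bin midpoint to the nearest chromosome end."""
    row = layout.bins.iloc[bin_index]
    L = layout.lengths[row["chrom"]]
    mid = (int(row["start"]) + int(row["end"])) // 2
    return min(mid, L - mid)


@dataclass
class EnrichmentResult:
    cluster: int | str
    observed_distances: np.ndarray
    null_mean: float
    null_median: float
    mannwhitney_u: float
    mannwhitney_p: float
    permutation_p: float
    n_null: int
    n_perm: int
    direction: str = "closer_to_telomere"

    def to_json_obj(self) -> dict:
        return {
            "cluster": self.cluster,
            "n_bins": int(len(self.observed_distances)),
            "observed_mean": float(self.observed_distances.mean()),
            "null_mean": self.null_mean,
            "null_median": self.null_median,
            "mannwhitney_u": self.mannwhitney_u,
            "mannwhitney_p": self.mannwhitney_p,
            "permutation_p": self.permutation_p,
            "n_null": self.n_null,
            "n_perm": self.n_perm,
            "direction": self.direction,
        }


def _null_distances(
    layout: GenomeLayout, width: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    lengths = np.array([layout.lengths[c] for c in layout.chroms], dtype=float)
    probs = lengths / lengths.sum()
    cidx = rng.choice(len(lengths), size=n, p=probs)
    starts = (rng.random(n) * np.maximum(lengths[cidx] - width, 1)).astype(np.int64)
    mids = starts + width // 2
    return np.minimum(mids, lengths[cidx].astype(np.int64) - mids)


def telomere_enrichment(
    bin_indices,
    layout: GenomeLayout,
    n_null: int = 100_000,
    n_perm: int = 100_000,
    seed: int = 0,
    statistic: str = "mean",
    cluster: int | str = "",
) -> EnrichmentResult:
    """Test whether a bin set lies closer to chromosome ends than random bins.

    The null places ``n_null`` bins of the layout's bin width uniformly on
    the genome with chromosome probability proportional to length (null
    bins may overlap each other or real bins). One-sided Mann-Whitney U
    tests whether observed distances are stochastically smaller; the
    permutation test redraws |cluster|-sized sets from the null pool and
    compares the chosen statistic (mean by default, median optional), with
    the add-one correction p >= 1/(n_perm + 1).
    """
    bin_indices = list(bin_indices)
    if len(bin_indices) < 2:
        raise ValueError("need at least 2 bins for enrichment testing")
    if (layout.bins["chrom"].value_counts() <= 1).any():
        warnings.warn("a chromosome has a single bin; distances are degenerate there")
    observed = np.array([telomere_distance(i, layout) for i in bin_indices], dtype=np.int64)
    return enrichment_from_distances(
        observed, layout, n_null=n_null, n_perm=n_perm, seed=seed,
        statistic=statistic, cluster=cluster,
    )


def enrichment_from_distances(
    observed: np.ndarray,
    layout: GenomeLayout,
    n_null: int = 100_000,
    n_perm: int = 100_000,
    seed: int = 0,
    statistic: str = "mean",
    cluster: int | str = "",
) -> EnrichmentResult:
    """Telomere-enrichment test for an already-computed distance set.

    Used by :func:`telomere_enrichment` and directly in calibration
    studies where the observed set is itself drawn from the null
    placement process.
    """
    observed = np.asarray(observed, dtype=np.int64)
    stat_fn = {"mean": np.mean, "median": np.median}[statistic]
    rng = np.random.default_rng(seed)
    null = _null_distances(layout, layout.bin_size, n_null, rng)

    u, p_mwu = stats.mannwhitneyu(observed, null, alternative="less")
    m = len(observed)
    obs_stat = stat_fn(observed)
    draws = null[rng.integers(0, n_null, size=(n_perm, m))]
    perm_stats = stat_fn(draws, axis=1)
    p_perm = (1 + int((perm_stats <= obs_stat).sum())) / (n_perm + 1)
    return EnrichmentResult(
        cluster=cluster,
        observed_distances=observed,
        null_mean=float(null.mean()),
        null_median=float(np.median(null)),
        mannwhitney_u=float(u),
        mannwhitney_p=float(p_mwu),
        permutation_p=float(p_perm),
        n_null=n_null,
        n_perm=n_perm,
    )
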