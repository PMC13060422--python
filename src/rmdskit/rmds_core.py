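"""Regional motif diversity score (rMDS) and depth-stability analysis.

For bin j with motif counts c_ij, let P_ij = c_ij / sum_i c_ij. The raw
score is the normalized Shannon entropy of the end-motif distribution,

    rMDS_j = sum_i -P_ij * log(P_ij) / log(4**k),

with 0*log(0) := 0, so rMDS ranges from 0 (all ends share one motif) to 1
(uniform usage over all 4**k motifs). Within each sample the scores are
z-transformed across defined bins, Z_j = (rMDS_j - mu) / sigma, using the
population standard deviation. Bins with fewer than ``min_ends`` ends are
left undefined rather than scored from unstable counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .fragio import FragmentSet, GenomeLayout, MotifCountMatrix, end_motif_events, extract_end_motifs

DEFAULT_MIN_ENDS = 100

__all__ = [
    "RMDSProfile",
    "StabilityReport",
    "rmds_from_counts",
    "zscore_transform",
    "sliding_rmds",
    "downsample_fragments",
    "stability_analysis",
    "normalized_entropy",
]


def normalized_entropy(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy of each row, normalized by log of the column count.

    Zero-count cells contribute nothing; rows must have positive totals.
    The log base cancels in the ratio.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    totals = counts.sum(axis=1, keepdims=True)
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1) / np.log(counts.shape[1])


@dataclass
class RMDSProfile:
    """Per-bin rMDS (and optionally Z_rMDS) for one sample."""

    sample_id: str
    k: int
    end_side: str
    table: pd.DataFrame  # bin_id, chrom, start, end, n_ends, rmds[, z_rmds]
    min_ends: int = DEFAULT_MIN_ENDS
    metadata: dict = field(default_factory=dict)

    @property
    def rmds(self) -> pd.Series:
        return self.table["rmds"]

    @property
    def z_rmds(self) -> pd.Series:
        if "z_rmds" not in self.table:
            raise AttributeError("profile has no z-scores; run zscore_transform first")
        return self.table["z_rmds"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def rmds_from_counts(
    counts: MotifCountMatrix,
    min_ends: int = DEFAULT_MIN_ENDS,
) -> RMDSProfile:
    """Compute per-bin rMDS from an end-motif count matrix.

    Bins with fewer than ``min_ends`` ends (including masked bins, which
    carry no counts) are set to NaN. Raises if no bin is usable.
    """
    if min_ends < 1:
        raise ValueError("min_ends must be >= 1")
    totals = counts.n_ends
    defined = totals >= min_ends
    if not defined.any():
        raise ValueError("no usable bins: all bins below min_ends")
    rmds = np.full(counts.layout.n_bins, np.nan)
    rmds[defined] = normalized_entropy(counts.counts[defined])
    b = counts.layout.bins
    table = pd.DataFrame(
        {
            "bin_id": counts.layout.bin_ids,
            "chrom": b["chrom"].to_numpy(),
            "start": b["start"].to_numpy(),
            "end": b["end"].to_numpy(),
            "n_ends": totals,
            "rmds": rmds,
        }
    )
    return RMDSProfile(
        sample_id=counts.sample_id,
        k=counts.k,
        end_side=counts.end_side,
        table=table,
        min_ends=min_ends,
    )


def zscore_transform(profile: RMDSProfile) -> RMDSProfile:
    """Z-score rMDS across the defined bins of the sample (population SD)."""
    vals = profile.table["rmds"].to_numpy()
    defined = ~np.isnan(vals)
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined bins to z-transform")
    mu = vals[defined].mean()
    sigma = vals[defined].std(ddof=0)
    if sigma == 0:
        raise ValueError("degenerate profile: zero variance across bins")
    table = profile.table.copy()
    table["z_rmds"] = (vals - mu) / sigma
    return RMDSProfile(
        sample_id=profile.sample_id,
        k=profile.k,
        end_side=profile.end_side,
        table=table,
        min_ends=profile.min_ends,
        metadata=dict(profile.metadata),
    )


def sliding_rmds(
    fragments: FragmentSet,
    reference,
    layout: GenomeLayout,
    step: int = 10_000,
    flank: int = 250_000,
    k: int = 4,
    min_ends: int = DEFAULT_MIN_ENDS,
    end_side: str = "five_prime",
) -> pd.DataFrame:
    """Locus-level rMDS track over sliding windows.

    Windows of width ``step`` are tiled along each chromosome; the value of
    a window is the rMDS of all fragment ends within ``flank`` bp of its
    center (a 2*flank window, the locus-visualization convention). Windows
    with fewer than ``min_ends`` ends are omitted. Raw (not z-scored) rMDS
    is reported; cross-sample normalization happens downstream.
    """
    if flank < step:
        raise ValueError("flank must be >= step")
    events, _ = end_motif_events(fragments, reference, k=k, end_side=end_side)
    rows = []
    for chrom in layout.chroms:
        L = layout.lengths[chrom]
        if step > L:
            warnings.warn(f"step {step} exceeds length of {chrom}; empty track")
            continue
        sub = events[events["chrom"] == chrom]
        pos = np.sort(sub["pos"].to_numpy())
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        codes = sub["code"].to_numpy()[order]
        n_motifs = 4**k
        for w in range(0, L - step + 1, step):
            center = w + step // 2
            lo = np.searchsorted(pos, center - flank, side="left")
            hi = np.searchsorted(pos, center + flank, side="left")
            if hi - lo < min_ends:
                continue
            c = np.bincount(codes[lo:hi], minlength=n_motifs)
            rows.append((chrom, w, min(w + step, L), float(normalized_entropy(c)[0])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "rmds"])


def track_to_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def downsample_fragments(
    fragments: FragmentSet,
    fraction: float | None = None,
    target_coverage: float | None = None,
    seed: int = 0,
    layout: GenomeLayout | None = None,
) -> FragmentSet:
    """Keep each fragment independently with probability ``fraction``.

    Alternatively give ``target_coverage`` (mean depth over the usable
    genome, estimated as total fragment bases / usable genome length; needs
    ``layout``) and the matching fraction is derived. Deterministic for a
    fixed seed.
    """
    if (fraction is None) == (target_coverage is None):
        raise ValueError("give exactly one of fraction or target_coverage")
    if fraction is None:
        if layout is None:
            raise ValueError("target_coverage requires a layout")
        current = estimate_coverage(fragments, layout)
        if target_coverage > current:
            raise ValueError(
                f"target coverage {target_coverage} exceeds available {current:.3g}"
            )
        fraction = target_coverage / current
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return FragmentSet(
            records=fragments.records.copy(),
            source=fragments.source,
            filter_log=dict(fragments.filter_log),
        )
    rng = np.random.default_rng(seed)
    keep = rng.random(len(fragments)) < fraction
    return FragmentSet(
        records=fragments.records.loc[keep].reset_index(drop=True),
        source=fragments.source,
        filter_log={"downsampled_from": len(fragments), "fraction": float(fraction)},
    )


def estimate_coverage(fragments: FragmentSet, layout: GenomeLayout) -> float:
    """Mean depth: summed fragment length over usable genome length."""
    lengths = (fragments.records["end"] - fragments.records["start"]).to_numpy()
    return float(lengths.sum()) / layout.usable_genome_length()


@dataclass
class StabilityReport:
    """Pearson correlation of downsampled rMDS profiles vs full depth."""

    levels: list[float]  # kept fractions, strictly decreasing
    pearson_r: list[float | None]
    n_bins: list[int]
    full_coverage: float
    silhouette: list[float | None] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"fraction": self.levels, "pearson_r": self.pearson_r, "n_bins": self.n_bins})
        if self.silhouette is not None:
            df["silhouette"] = self.silhouette
        return df


def stability_analysis(
    fragments: FragmentSet | dict[str, FragmentSet],
    reference,
    layout: GenomeLayout,
    levels: Sequence[float],
    seed: int = 0,
    labels: dict[str, str] | None = None,
    k: int = 4,
    min_ends: int = DEFAULT_MIN_ENDS,
    end_side: str = "five_prime",
) -> StabilityReport:
    """Recompute rMDS at reduced depths and correlate with full depth.

    ``levels`` are kept fractions in (0, 1], sorted strictly descending.
    For each level the Pearson r against the full-depth profile is taken
    over bins defined at both depths (needs >= 3 such bins, else reported
    missing). With multiple samples and ``labels``, a silhouette score of
    the label separation on the per-level z-rMDS matrix is also reported.
    """
    levels = [float(x) for x in levels]
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly decreasing")
    if any(not 0 < x <= 1 for x in levels):
        raise ValueError("levels must be fractions in (0, 1]")
    samples = fragments if isinstance(fragments, dict) else {"sample": fragments}

    full = {}
    for name, fs in samples.items():
        counts = extract_end_motifs(fs, reference, layout, k=k, end_side=end_side, sample_id=name)
        full[name] = rmds_from_counts(counts, min_ends=min_ends).rmds.to_numpy()
    full_cov = float(
        np.mean([estimate_coverage(fs, layout) for fs in samples.values()])
    )

    rs: list[float | None] = []
    nb: list[int] = []
    sils: list[float | None] = []
    for i, frac in enumerate(levels):
        per_sample_r = []
        zmat = {}
        n_common = 0
        for j, (name, fs) in enumerate(samples.items()):
            sub = downsample_fragments(fs, fraction=frac, seed=seed + 1000 * i + j)
            counts = extract_end_motifs(sub, reference, layout, k=k, end_side=end_side, sample_id=name)
            try:
                prof = rmds_from_counts(counts, min_ends=min_ends)
            except ValueError:
                continue
            vals = prof.rmds.to_numpy()
            both = ~np.isnan(vals) & ~np.isnan(full[name])
            n_common = max(n_common, int(both.sum()))
            if both.sum() >= 3:
                per_sample_r.append(float(np.corrcoef(vals[both], full[name][both])[0, 1]))
            zmat[name] = vals
        rs.append(float(np.mean(per_sample_r)) if per_sample_r else None)
        nb.append(n_common)
        if labels is not None and len(samples) > 1:
            sils.append(_matrix_silhouette(zmat, labels))
        else:
            sils.append(None)
    return StabilityReport(
        levels=levels,
        pearson_r=rs,
        n_bins=nb,
        full_coverage=full_cov,
        silhouette=sils if labels is not None else None,
    )


def _matrix_silhouette(zmat: dict[str, np.ndarray], labels: dict[str, str]) -> float | None:
    from .harmonize import silhouette_separation

    names = [n for n in zmat if n in labels]
    if len({labels[n] for n in names}) < 2:
        return None
    mat = np.vstack([zmat[n] for n in names])
    keep = ~np.isnan(mat).any(axis=0)
    if keep.sum() < 2:
        return None
    mat = mat[:, keep]
    mat = (mat - mat.mean(axis=0)) / np.where(mat.std(axis=0) == 0, 1, mat.std(axis=0))
    scores, mean = silhouette_separation(mat, [labels[n] for n in names])
    return mean
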