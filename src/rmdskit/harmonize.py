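"""Batch correction with a preserved biological covariate, plus embedding.

Per genomic bin, Z_rMDS values are modeled by ordinary least squares on
sum-to-zero contrasts of the technical batch factors (institute, isolation
date, library date) together with the biological covariate to preserve
(treatment response). Only the batch terms are subtracted when correcting,
so response-associated variation survives by construction. Coefficients
are learned once on a fit set and applied frozen to held-out samples;
factor levels unseen at fit time encode to the zero vector under sum
contrasts and therefore receive the grand-mean correction only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

__all__ = [
    "CorrectionModel",
    "EmbeddingResult",
    "Standardizer",
    "fit_correction",
    "apply_correction",
    "standardize",
    "svd_reduce",
    "silhouette_separation",
    "sum_contrast",
]


def sum_contrast(values: pd.Series, levels: list[str], factor: str = "") -> np.ndarray:
    """Sum-to-zero contrast encoding: columns for levels[:-1].

    Row for level i < m-1 is e_i; the last level encodes to -1 everywhere;
    a level not in ``levels`` encodes to the zero vector (with a warning).
    """
    m = len(levels)
    enc = np.zeros((len(values), m - 1))
    index = {lv: i for i, lv in enumerate(levels)}
    unseen = set()
    for r, v in enumerate(values.astype(str)):
        i = index.get(v)
        if i is None:
            unseen.add(v)
        elif i == m - 1:
            enc[r, :] = -1.0
        else:
            enc[r, i] = 1.0
    if unseen:
        warnings.warn(
            f"levels {sorted(unseen)} of factor {factor or '?'} unseen at fit time; "
            "encoded as zero (grand-mean correction only)"
        )
    return enc


@dataclass
class CorrectionModel:
    """Frozen per-bin batch coefficients and their factor encodings."""

    batch_factors: list[str]
    preserve: str
    levels: dict[str, list[str]]  # stored level order per factor (incl. preserve)
    bin_ids: list[str]
    batch_coef: np.ndarray  # (n batch columns) x bins
    batch_columns: list[str]
    fit_samples: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "batch_factors": self.batch_factors,
            "preserve": self.preserve,
            "levels": self.levels,
            "bin_ids": self.bin_ids,
            "batch_columns": self.batch_columns,
            "batch_coef": self.batch_coef.tolist(),
            "fit_samples": self.fit_samples,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionModel":
        obj = json.loads(Path(path).read_text())
        obj["batch_coef"] = np.asarray(obj["batch_coef"])
        return cls(**obj)


def _batch_design(
    metadata: pd.DataFrame, model_levels: dict[str, list[str]], factors: list[str]
) -> tuple[np.ndarray, list[str]]:
    blocks, names = [], []
    for f in factors:
        lv = model_levels[f]
        blocks.append(sum_contrast(metadata[f], lv, factor=f))
        names.extend(f"{f}[{l}]" for l in lv[:-1])
    X = np.hstack(blocks) if blocks else np.empty((len(metadata), 0))
    return X, names


def fit_correction(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    batch_factors: list[str],
    preserve: str = "response",
) -> CorrectionModel:
    """Fit per-bin OLS of value ~ batch factors + preserved covariate.

    ``matrix`` is samples x bins (index = sample ids, aligned with
    ``metadata`` rows by sample_id). Every batch factor needs >= 2 levels
    in the fit set; a design that is rank deficient (e.g. a batch factor
    perfectly confounded with the preserved covariate) raises with the
    aliased columns named.
    """
    meta = metadata.set_index("sample_id").loc[matrix.index]
    levels: dict[str, list[str]] = {}
    for f in [*batch_factors, preserve]:
        lv = list(pd.unique(meta[f].astype(str)))
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels in the fit set")
        levels[f] = lv

    Xb, bnames = _batch_design(meta, levels, batch_factors)
    Xp, pnames = _batch_design(meta, levels, [preserve])
    X = np.hstack([np.ones((len(meta), 1)), Xb, Xp])
    names = ["intercept", *bnames, *pnames]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the null space
        _, _, vt = np.linalg.svd(X)
        null = np.abs(vt[rank:]).sum(axis=0)
        aliased = [n for n, w in zip(names, null) if w > 1e-8]
        raise ValueError(f"design matrix rank deficient; aliased columns: {aliased}")

    beta, *_ = np.linalg.lstsq(X, matrix.to_numpy(), rcond=None)
    nb = Xb.shape[1]
    return CorrectionModel(
        batch_factors=list(batch_factors),
        preserve=preserve,
        levels=levels,
        bin_ids=list(matrix.columns),
        batch_coef=beta[1 : 1 + nb],
        batch_columns=bnames,
        fit_samples=list(matrix.index),
    )


def apply_correction(
    matrix: pd.DataFrame, metadata: pd.DataFrame, model: CorrectionModel
) -> pd.DataFrame:
    """Subtract the frozen batch terms: corrected = Y - X_batch @ beta_batch."""
    if list(matrix.columns) != model.bin_ids:
        raise ValueError("bin set mismatch between matrix and correction model")
    meta = metadata.set_index("sample_id").loc[matrix.index]
    Xb, _ = _batch_design(meta, model.levels, model.batch_factors)
    corrected = matrix.to_numpy() - Xb @ model.batch_coef
    return pd.DataFrame(corrected, index=matrix.index, columns=matrix.columns)


class Standardizer:
    """Per-bin (column) z-scoring across samples; zero-variance bins dropped."""

    def __init__(self):
        self.columns_: list[str] | None = None
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, matrix: pd.DataFrame) -> "Standardizer":
        vals = matrix.to_numpy()
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=0)
        keep = sd > 0
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(f"dropping {n_drop} zero-variance bins")
        self.columns_ = list(np.asarray(matrix.columns)[keep])
        self.mean_ = mean[keep]
        self.sd_ = sd[keep]
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise ValueError("Standardizer is not fitted")
        sub = matrix[self.columns_].to_numpy()
        return pd.DataFrame(
            (sub - self.mean_) / self.sd_, index=matrix.index, columns=self.columns_
        )

    def fit_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return self.fit(matrix).transform(matrix)


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each bin across samples (population SD); drops constant bins."""
    return Standardizer().fit_transform(matrix)


@dataclass
class EmbeddingResult:
    """Truncated-SVD scores with sign-canonicalized components."""

    scores: pd.DataFrame  # samples x components (U * S)
    singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # n_components x bins (V rows)
    columns: list[str]
    n_components: int

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Project new samples onto the fitted components."""
        sub = matrix[self.columns].to_numpy()
        scores = sub @ self.components.T
        return pd.DataFrame(
            scores, index=matrix.index, columns=self.scores.columns
        )


def svd_reduce(matrix: pd.DataFrame, n_components: int = 6) -> EmbeddingResult:
    """Truncated SVD of the (already standardized) matrix; scores = U S.

    Components are sign-canonicalized so the largest-magnitude loading of
    each is positive, making embeddings reproducible across runs.
    Explained-variance fractions are squared singular values over the total
    squared Frobenius norm.
    """
    vals = matrix.to_numpy(dtype=float)
    if n_components > min(vals.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    u, s, vt = np.linalg.svd(vals, full_matrices=False)
    total = float((s**2).sum())
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign canonicalization on loadings
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = pd.DataFrame(
        u * s,
        index=matrix.index,
        columns=[f"SV{i + 1}" for i in range(n_components)],
    )
    evr = (s**2) / total if total > 0 else np.zeros_like(s)
    return EmbeddingResult(
        scores=scores,
        singular_values=s,
        explained_variance_ratio=evr,
        components=vt,
        columns=list(matrix.columns),
        n_components=n_components,
    )


def silhouette_separation(features, labels) -> tuple[pd.Series, float]:
    """Silhouette of label separation: per-sample (b-a)/max(a,b) and mean.

    Euclidean distances. Singleton clusters score 0 (with a warning), as do
    samples where a = b = 0 (identical points).
    """
    from sklearn.metrics import silhouette_samples

    if isinstance(features, pd.DataFrame):
        index = features.index
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        index = pd.RangeIndex(len(X))
    labels = np.asarray([str(l) for l in labels])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct labels")
    if (counts == 1).any():
        warnings.warn("singleton cluster(s); their silhouette is 0 by convention")
    if len(uniq) == len(labels):
        scores = np.zeros(len(labels))
    else:
        scores = silhouette_samples(X, labels)
        scores = np.nan_to_num(scores)
    s = pd.Series(scores, index=index)
    return s, float(s.mean())
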