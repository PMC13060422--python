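"""Response classification on reduced rMDS features, patient-level splits.

Three validation schemes mirror a multi-institute longitudinal design:
repeated k-fold cross-validation at the patient level, leave-one-institute
-out (LOIO), and repeated random patient holdout. Splits are always at the
patient level — no patient contributes samples to both train and test.
Patient-level predictions use the most recent available timepoint.

``correction_policy`` decides where preprocessing is learned: ``global``
uses the provided, already corrected/standardized matrix (SVD fitted once
on all samples, mirroring analysis-set evaluation), while ``refit`` learns
batch correction, standardization and SVD on the training samples of each
split and applies them frozen to the test samples (no leakage).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .differential import RESPONSE_POSITIVE
from .harmonize import Standardizer, apply_correction, fit_correction, svd_reduce

TIMEPOINT_ORDER = ("Screen", "Day0", "AdjWk1")

__all__ = [
    "EvalScheme",
    "EvalReport",
    "default_classifier",
    "patient_prediction",
    "sensitivity_at_specificity",
    "run_evaluation",
    "feature_subset_evaluation",
]


def default_classifier():
    """Ridge-regularized logistic regression: dependency-light, deterministic."""
    return LogisticRegression(C=1.0, max_iter=2000)


@dataclass
class EvalScheme:
    """Patient-level validation scheme.

    kind: 'repeated_kfold' (n_folds x n_repeats, stratified by response at
    the patient level), 'leave_one_institute_out', or
    'random_patient_holdout' (holdout_size patients per round, n_repeats
    rounds).
    """

    kind: str = "repeated_kfold"
    n_folds: int = 10
    n_repeats: int = 10
    holdout_size: int = 10
    seed: int = 0

    def splits(self, patients: pd.DataFrame):
        """Yield (train_patient_ids, test_patient_ids)."""
        pids = patients["patient_id"].to_numpy()
        labels = patients["response"].to_numpy()
        rng = np.random.default_rng(self.seed)
        if self.kind == "repeated_kfold":
            from sklearn.model_selection import StratifiedKFold

            for r in range(self.n_repeats):
                skf = StratifiedKFold(
                    n_splits=self.n_folds,
                    shuffle=True,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                for tr, te in skf.split(pids, labels):
                    yield pids[tr], pids[te]
        elif self.kind == "leave_one_institute_out":
            inst = patients["institute"].to_numpy()
            for site in pd.unique(inst):
                yield pids[inst != site], pids[inst == site]
        elif self.kind == "random_patient_holdout":
            for r in range(self.n_repeats):
                te = rng.choice(pids, size=min(self.holdout_size, len(pids) - 1), replace=False)
                yield np.setdiff1d(pids, te), te
        else:
            raise ValueError(f"unknown scheme kind {self.kind!r}")


def _timepoint_rank(tp: str) -> int:
    try:
        return TIMEPOINT_ORDER.index(tp) + 1
    except ValueError:
        return 0  # unknown timepoints sort least recent


def patient_prediction(
    sample_probabilities: pd.Series, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Patient probability = that of the latest available timepoint's sample.

    Ties at probability 0.5 predict the positive class (>= rule). Patients
    with no scored sample are excluded (count in attrs['n_excluded']).
    """
    meta = metadata.set_index("sample_id")
    rows = []
    n_excluded = 0
    for pid, sub in meta.groupby("patient_id", sort=False):
        scored = sub.index.intersection(sample_probabilities.index)
        if len(scored) == 0:
            n_excluded += 1
            continue
        sub = sub.loc[scored]
        ranks = sub["timepoint"].map(_timepoint_rank)
        best = ranks.idxmax()
        prob = float(sample_probabilities[best])
        rows.append(
            {
                "patient_id": pid,
                "probability": prob,
                "predicted": RESPONSE_POSITIVE if prob >= 0.5 else "Non-Responder",
                "timepoint_used": sub.loc[best, "timepoint"],
                "response": sub.loc[best, "response"] if "response" in sub else None,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


def sensitivity_at_specificity(scores, labels, specificity: float = 0.95) -> float:
    """Max sensitivity over thresholds whose specificity >= target; 0 if none."""
    from sklearn.metrics import roc_curve

    y = np.asarray([1 if l == RESPONSE_POSITIVE or l == 1 else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    ok = fpr <= (1 - specificity) + 1e-12
    return float(tpr[ok].max()) if ok.any() else 0.0


def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, scores))


def _split_metrics(scores: np.ndarray, y: np.ndarray) -> dict:
    from sklearn.metrics import (
        accuracy_score,
        balanced_accuracy_score,
        confusion_matrix,
        f1_score,
        precision_score,
        recall_score,
    )

    pred = (scores >= 0.5).astype(int)
    with warnings.catch_warnings():
        # single-class strata (e.g. one timepoint of a small test split)
        # make sklearn warn about confusion-matrix shape; harmless here
        warnings.simplefilter("ignore", UserWarning)
        out = {
            "accuracy": accuracy_score(y, pred),
            "f1": f1_score(y, pred, zero_division=0),
            "precision": precision_score(y, pred, zero_division=0),
            "recall": recall_score(y, pred, zero_division=0),
            "balanced_accuracy": balanced_accuracy_score(y, pred),
        }
    if y.min() != y.max():
        out["roc_auc"] = _auc(scores, y)
        out["sens_at_95spec"] = sensitivity_at_specificity(scores, y, 0.95)
    else:
        out["roc_auc"] = np.nan
        out["sens_at_95spec"] = np.nan
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    out.update({"tn": tn, "fp": fp, "fn": fn, "tp": tp})
    return out


@dataclass
class EvalReport:
    per_split: pd.DataFrame  # patient-level metrics per split
    aggregate: dict  # mean/sd per metric, patient level
    sample_by_timepoint: pd.DataFrame  # aggregated sample-level metrics per timepoint
    confusion: dict  # summed patient-level confusion counts
    n_splits: int
    n_skipped: int
    scheme: EvalScheme | None = None

    def to_json_obj(self) -> dict:
        return {
            "aggregate": {k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v))
                          for k, v in self.aggregate.items()},
            "confusion": {k: int(v) for k, v in self.confusion.items()},
            "n_splits": self.n_splits,
            "n_skipped": self.n_skipped,
        }


def _clone_classifier(classifier):
    try:
        from sklearn.base import clone

        return clone(classifier)
    except Exception:
        return copy.deepcopy(classifier)


def run_evaluation(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    scheme: EvalScheme,
    classifier=None,
    correction_policy: str = "global",
    batch_factors: list[str] | None = None,
    n_components: int = 6,
) -> EvalReport:
    """Evaluate a response classifier under a patient-level scheme.

    ``matrix`` is samples x bins: for policy 'global' it should already be
    batch-corrected and standardized; for policy 'refit' it should be raw
    Z_rMDS, and correction (on ``batch_factors``), standardization and SVD
    are learned per split on training samples only. Policy 'none' skips
    correction but refits standardization/SVD per split. Splits whose
    training set carries a single class are skipped and counted; a
    classifier failure on a split is recorded, not fatal.
    """
    if classifier is None:
        classifier = default_classifier()
    if correction_policy not in ("global", "refit", "none"):
        raise ValueError(f"unknown correction_policy {correction_policy!r}")
    meta = metadata.set_index("sample_id").loc[matrix.index].rename_axis("sample_id").reset_index()
    patients = meta.drop_duplicates("patient_id")[["patient_id", "response", "institute"]]

    global_features = None
    if correction_policy == "global":
        global_features = svd_reduce(matrix, n_components=min(n_components, min(matrix.shape)))

    split_rows = []
    sample_rows = []
    confusion = {"tn": 0, "fp": 0, "fn": 0, "tp": 0}
    n_skipped = 0
    for i, (train_p, test_p) in enumerate(scheme.splits(patients)):
        assert len(np.intersect1d(train_p, test_p)) == 0
        tr_mask = meta["patient_id"].isin(train_p).to_numpy()
        te_mask = meta["patient_id"].isin(test_p).to_numpy()
        y_tr = (meta.loc[tr_mask, "response"] == RESPONSE_POSITIVE).astype(int).to_numpy()
        if y_tr.min() == y_tr.max():
            n_skipped += 1
            continue
        tr_ids = meta.loc[tr_mask, "sample_id"]
        te_ids = meta.loc[te_mask, "sample_id"]

        if correction_policy == "global":
            X_tr = global_features.scores.loc[tr_ids].to_numpy()
            X_te = global_features.scores.loc[te_ids].to_numpy()
        else:
            train_mat = matrix.loc[tr_ids]
            test_mat = matrix.loc[te_ids]
            if correction_policy == "refit":
                model = fit_correction(
                    train_mat,
                    metadata,
                    batch_factors=batch_factors or ["institute"],
                )
                train_mat = apply_correction(train_mat, metadata, model)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    test_mat = apply_correction(test_mat, metadata, model)
            scaler = Standardizer().fit(train_mat)
            train_mat = scaler.transform(train_mat)
            test_mat = scaler.transform(test_mat)
            emb = svd_reduce(train_mat, n_components=min(n_components, min(train_mat.shape)))
            X_tr = emb.scores.to_numpy()
            X_te = emb.transform(test_mat).to_numpy()

        clf = _clone_classifier(classifier)
        try:
            clf.fit(X_tr, y_tr)
            prob = clf.predict_proba(X_te)[:, 1]
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"classifier failed on split {i}: {exc}")
            n_skipped += 1
            continue
        prob_s = pd.Series(prob, index=te_ids)

        te_meta = meta.loc[te_mask]
        y_te = (te_meta["response"] == RESPONSE_POSITIVE).astype(int).to_numpy()
        for tp, sub in te_meta.groupby("timepoint", sort=False):
            y_s = (sub["response"] == RESPONSE_POSITIVE).astype(int).to_numpy()
            sm = _split_metrics(prob_s[sub["sample_id"]].to_numpy(), y_s)
            sample_rows.append({"split": i, "timepoint": tp, **sm})

        pp = patient_prediction(prob_s, metadata)
        y_p = (pp["response"] == RESPONSE_POSITIVE).astype(int).to_numpy()
        pm = _split_metrics(pp["probability"].to_numpy(), y_p)
        for key in confusion:
            confusion[key] += int(pm[key])
        split_rows.append({"split": i, "n_test_patients": len(pp), **pm})

    per_split = pd.DataFrame(split_rows)
    metric_cols = [
        "roc_auc", "accuracy", "f1", "precision", "recall",
        "balanced_accuracy", "sens_at_95spec",
    ]
    aggregate = {}
    for m in metric_cols:
        vals = per_split[m].to_numpy(dtype=float) if len(per_split) else np.array([])
        vals = vals[~np.isnan(vals)]
        aggregate[f"{m}_mean"] = float(vals.mean()) if vals.size else None
        aggregate[f"{m}_sd"] = float(vals.std(ddof=0)) if vals.size else None

    sdf = pd.DataFrame(sample_rows)
    if len(sdf):
        by_tp = sdf.groupby("timepoint")[metric_cols].agg(["mean", "std"])
    else:
        by_tp = pd.DataFrame()
    return EvalReport(
        per_split=per_split,
        aggregate=aggregate,
        sample_by_timepoint=by_tp,
        confusion=confusion,
        n_splits=len(split_rows),
        n_skipped=n_skipped,
        scheme=scheme,
    )


def feature_subset_evaluation(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    subsets: dict[str, list[str]],
    scheme: EvalScheme,
    **kwargs,
) -> dict[str, EvalReport]:
    """Run the evaluation restricted to each named bin subset."""
    out = {}
    for name, bins in subsets.items():
        if len(bins) == 0:
            raise ValueError(f"subset {name!r} is empty")
        missing = [b for b in bins if b not in matrix.columns]
        if missing:
            raise ValueError(f"subset {name!r} has unknown bins: {missing[:5]}")
        out[name] = run_evaluation(matrix[list(bins)], metadata, scheme, **kwargs)
    return out
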