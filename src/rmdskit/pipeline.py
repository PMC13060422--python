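"""End-to-end orchestration: stage wiring, run configuration, provenance.

The pipeline runs preprocessing -> rMDS -> batch correction -> differential
testing -> clustering/telomere enrichment -> classification, writing each
stage's artifacts (TSV/JSON) into an output directory together with a
provenance record (tool version, config hash, seed, content hashes of
inputs and outputs). Deterministic stages reproduce identical hashes on
re-run with identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import estimate_block_correlation, fit_differential
from .fragio import GenomeLayout, filter_fragments, extract_end_motifs, load_layout
from .harmonize import fit_correction, apply_correction, standardize, svd_reduce, silhouette_separation
from .rmds_core import rmds_from_counts, zscore_transform
from .regions import cluster_bins, telomere_enrichment, trajectory_summary
from .respond import EvalScheme, run_evaluation

__all__ = ["RunConfig", "run_pipeline", "zrmds_matrix", "drop_incomplete_bins"]


def zrmds_matrix(
    fragment_files: dict[str, str | Path],
    reference,
    layout: GenomeLayout,
    k: int = 4,
    min_ends: int = 100,
    end_side: str = "five_prime",
    blacklist=None,
) -> pd.DataFrame:
    """Filter, count and score each sample; return samples x bins Z_rMDS."""
    rows = {}
    for sid, path in fragment_files.items():
        frags = filter_fragments(path, layout, blacklist=blacklist)
        counts = extract_end_motifs(frags, reference, layout, k=k, end_side=end_side, sample_id=sid)
        prof = zscore_transform(rmds_from_counts(counts, min_ends=min_ends))
        rows[sid] = prof.z_rmds.to_numpy()
    return pd.DataFrame.from_dict(rows, orient="index", columns=layout.bin_ids)


def drop_incomplete_bins(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep only bins defined (non-NaN) in every sample."""
    return matrix.loc[:, ~matrix.isna().any(axis=0)]


@dataclass
class RunConfig:
    """Validated run configuration; serialized next to the outputs.

    The on-disk format is a flat ``key = value`` text file (diff-able,
    language-agnostic). Paths must exist at validation time.
    """

    reference: str = ""
    chrom_sizes: str = ""
    fragments_dir: str = ""
    metadata: str = ""
    output_dir: str = "rmdskit_out"
    blacklist: str = ""
    mappability: str = ""
    bin_size: int = 500_000
    k: int = 4
    end_side: str = "five_prime"
    min_ends: int = 100
    q_threshold: float = 0.1
    n_components: int = 6
    n_clusters: int = 3
    n_null: int = 100_000
    n_perm: int = 100_000
    scheme: str = "repeated_kfold"
    n_folds: int = 10
    n_repeats: int = 10
    batch_factors: tuple[str, ...] = ("institute", "isolation_date", "library_date")
    covariates: tuple[str, ...] = ("age", "gender", "smoking", "alcohol")
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kw = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("batch_factors", "covariates"):
                kw[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key in ("bin_size", "k", "min_ends", "n_components", "n_clusters",
                         "n_null", "n_perm", "n_folds", "n_repeats", "seed"):
                kw[key] = int(value)
            elif key == "q_threshold":
                kw[key] = float(value)
            else:
                kw[key] = value
        return cls(**kw)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for k, v in asdict(self).items():
            if isinstance(v, tuple):
                v = ",".join(v)
            lines.append(f"{k} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    def validate(self) -> None:
        for name in ("reference", "chrom_sizes", "fragments_dir", "metadata"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} missing or does not exist: {p}")
        for name in ("blacklist", "mappability"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        if self.k not in (3, 4, 5, 6):
            raise ValueError("k must be in 3..6")
        if self.bin_size <= 0 or self.min_ends < 1:
            raise ValueError("bin_size and min_ends must be positive")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; halt with the stage name on failure.

    Returns the output directory. Every artifact is content-hashed into
    ``provenance.json`` alongside tool version, config hash and seed.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "run_config.txt")
    provenance: dict = {
        "tool": "rmdskit",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _sha256(out / "run_config.txt"),
        "inputs": {},
        "artifacts": {},
    }

    def record(stage: str, path: Path) -> None:
        provenance["artifacts"][f"{stage}:{path.name}"] = _sha256(path)

    stage = "layout"
    try:
        layout = load_layout(
            config.chrom_sizes,
            config.bin_size,
            blacklist=config.blacklist or None,
            mappability=config.mappability or None,
        )
        frag_files = sorted(
            p for p in Path(config.fragments_dir).iterdir()
            if p.suffix in (".bed", ".gz")
        )
        files = {p.name.replace(".bed.gz", "").replace(".bed", ""): p for p in frag_files}
        for p in (config.reference, config.chrom_sizes, config.metadata):
            provenance["inputs"][Path(p).name] = _sha256(Path(p))

        stage = "rmds"
        matrix = zrmds_matrix(
            files, config.reference, layout,
            k=config.k, min_ends=config.min_ends, end_side=config.end_side,
        )
        matrix = drop_incomplete_bins(matrix)
        matrix.to_csv(out / "zrmds_matrix.tsv", sep="\t")
        record(stage, out / "zrmds_matrix.tsv")

        metadata = pd.read_csv(config.metadata, sep="\t")
        metadata = metadata[metadata["sample_id"].isin(matrix.index)]

        stage = "correct"
        model = fit_correction(matrix, metadata, batch_factors=list(config.batch_factors))
        corrected = apply_correction(matrix, metadata, model)
        model.to_json(out / "correction_model.json")
        corrected.to_csv(out / "corrected_matrix.tsv", sep="\t")
        record(stage, out / "corrected_matrix.tsv")

        stage = "embed"
        standardized = standardize(corrected)
        emb = svd_reduce(standardized, n_components=min(config.n_components, min(standardized.shape)))
        emb.scores.to_csv(out / "svd_scores.tsv", sep="\t")
        record(stage, out / "svd_scores.tsv")

        stage = "silhouette"
        _, mean_sil = silhouette_separation(
            standardized, metadata.set_index("sample_id").loc[standardized.index, "response"]
        )
        (out / "silhouette.json").write_text(json.dumps({"response_mean_silhouette": mean_sil}))
        record(stage, out / "silhouette.json")

        stage = "differential"
        rho = estimate_block_correlation(corrected, metadata, covariates=list(config.covariates))
        table = fit_differential(corrected, metadata, covariates=list(config.covariates), rho=rho)
        table.table.sort_values("q").to_csv(out / "differential.tsv", sep="\t", index=False)
        (out / "differential_model.json").write_text(json.dumps(table.summary_json()))
        record(stage, out / "differential.tsv")

        stage = "cluster"
        sig = list(table.significant(config.q_threshold)["bin_id"])
        enrich = []
        if len(sig) >= config.n_clusters:
            assignment = cluster_bins(corrected[sig], metadata, n_clusters=config.n_clusters)
            assignment.labels.rename_axis("bin_id").reset_index().to_csv(
                out / "clusters.tsv", sep="\t", index=False
            )
            record(stage, out / "clusters.tsv")
            traj = trajectory_summary(corrected, assignment, metadata)
            traj.to_csv(out / "trajectories.tsv", sep="\t", index=False)
            record(stage, out / "trajectories.tsv")

            stage = "enrich"
            bin_pos = {b: i for i, b in enumerate(layout.bin_ids)}
            for c in sorted(assignment.labels.unique()):
                bins = [bin_pos[b] for b in assignment.bins_in(c)]
                if len(bins) < 2:
                    continue
                res = telomere_enrichment(
                    bins, layout, n_null=config.n_null, n_perm=config.n_perm,
                    seed=config.seed, cluster=int(c),
                )
                enrich.append(res.to_json_obj())
        (out / "telomere_enrichment.json").write_text(json.dumps(enrich))
        record("enrich", out / "telomere_enrichment.json")

        stage = "classify"
        scheme = EvalScheme(
            kind=config.scheme, n_folds=config.n_folds,
            n_repeats=config.n_repeats, seed=config.seed,
        )
        report = run_evaluation(
            standardized, metadata, scheme,
            correction_policy="global", n_components=config.n_components,
        )
        (out / "classification_report.json").write_text(json.dumps(report.to_json_obj()))
        report.per_split.to_csv(out / "classification_splits.tsv", sep="\t", index=False)
        record(stage, out / "classification_report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return out
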