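"""Synthetic cfDNA cohorts with planted regional end-motif entropy effects.

The simulator emulates a longitudinal, multi-institute plasma cfDNA study:
two response groups, three timepoints per patient, per-(institute, date)
batch tilts, and a subset of genomic bins where the groups differ in
end-motif diversity.

Per sample and bin, the end-motif distribution p is drawn from a Dirichlet
with symmetric concentration ``base_concentration`` per motif; fragment
ends are then placed so the *reference sequence* at each end realizes
motifs drawn from p (Dirichlet-multinomial counts). Because the counting
stage re-reads the reference, nothing is taken on trust from the
simulator. The group effect multiplies the concentration by
``effect_delta`` for non-responders at ``effect_bins``: a smaller
concentration makes the Dirichlet draws more peaked, lowering expected
entropy (and vice versa), without moving the mean motif composition.

End placement: the upstream 5' end is put at a position inside the bin
whose forward k-mer equals the sampled motif (uniform over matches; if the
motif is absent from the bin, a uniform position is used as fallback). The
downstream end is put at the position matching its sampled motif nearest
to the length-sampled endpoint within the 50-350 bp window; when no match
exists in the window the length-sampled endpoint itself is used. The
fallback admixture is small and shrinks with bin size.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import kmer_codes, revcomp_codes
from .fragio import FragmentSet, GenomeLayout, _ReferenceCodes

DEFAULT_TIMEPOINTS = ("Screen", "Day0", "AdjWk1")
DEFAULT_INSTITUTES = ("UC", "UM", "OSU", "MUSC", "MDACC", "UofL")

__all__ = [
    "SimConfig",
    "SimTruth",
    "ToyReference",
    "CohortSim",
    "make_toy_reference",
    "simulate_cohort",
]


@dataclass
class ToyReference:
    fasta: Path
    chrom_sizes: Path
    names: list[str]
    lengths: dict[str, int]


def make_toy_reference(
    n_chromosomes: int,
    chrom_length: int,
    seed: int,
    outdir: str | Path,
    line_width: int = 80,
) -> ToyReference:
    """Write an i.i.d. uniform A/C/G/T reference FASTA plus a sizes table.

    Deterministic for a fixed seed; FASTA and chrom.sizes agree on names
    and lengths.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if n_chromosomes <= 0:
        raise ValueError("n_chromosomes must be positive")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    fasta = outdir / "reference.fa"
    sizes = outdir / "reference.chrom.sizes"
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(fasta, "w") as fh:
        for name in names:
            fh.write(f">{name}\n")
            seq = bases[rng.integers(0, 4, size=chrom_length)].tobytes().decode("ascii")
            for i in range(0, chrom_length, line_width):
                fh.write(seq[i : i + line_width] + "\n")
    with open(sizes, "w") as fh:
        for name in names:
            fh.write(f"{name}\t{chrom_length}\n")
    return ToyReference(
        fasta=fasta,
        chrom_sizes=sizes,
        names=names,
        lengths={n: chrom_length for n in names},
    )


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    ``coverage`` is the mean number of fragments per bin per sample.
    ``effect_delta`` multiplies the Dirichlet concentration for
    non-responders at ``effect_bins`` (< 1 lowers entropy, > 1 raises it);
    ``trajectory_pattern`` maps each effect bin to one of three timepoint
    dynamics: ``cluster1`` (effect at Screen and AdjWk1, none at Day0),
    ``cluster2`` (constant), ``cluster3`` (constant, opposite direction).
    """

    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    bin_size: int = 500_000
    k: int = 4
    n_patients_per_group: int = 10
    institutes: tuple[str, ...] = DEFAULT_INSTITUTES
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    coverage: float = 1000.0
    base_concentration: float = 2.0
    effect_bins: tuple[int, ...] = ()
    effect_delta: float = 0.2
    batch_tilt_sd: float = 0.0
    batch_bin_sd: float = 0.0
    trajectory_pattern: dict[int, str] = field(default_factory=dict)
    fraglen_mean: float = 166.0
    fraglen_sd: float = 40.0
    gzip_output: bool = False
    seed: int = 0

    def validate(self, layout: GenomeLayout) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be positive")
        if self.effect_delta <= 0:
            raise ValueError("effect_delta must be positive")
        if not self.timepoints:
            raise ValueError("timepoints must be non-empty")
        bad = [b for b in self.effect_bins if not 0 <= b < layout.n_bins]
        if bad:
            raise ValueError(f"effect bins outside layout: {bad}")
        for b, lab in self.trajectory_pattern.items():
            if lab not in ("cluster1", "cluster2", "cluster3"):
                raise ValueError(f"unknown trajectory pattern {lab!r} for bin {b}")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``group_probs[(group, timepoint)]`` holds the mean motif vector per bin
    (n_bins x 4**k); ``sample_probs[sample_id]`` the realized Dirichlet
    draw each sample's counts converge to as coverage grows.
    """

    group_probs: dict[tuple[str, str], np.ndarray]
    sample_probs: dict[str, np.ndarray]
    batch_tilts: dict[str, np.ndarray]
    sample_batch: dict[str, str]
    labels: dict[str, str]
    effect_bins: tuple[int, ...]
    trajectory_pattern: dict[int, str]
    batch_bin_tilts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for arr in self.sample_probs.values():
            s = arr.sum(axis=1)
            if not np.allclose(s, 1.0, atol=1e-9) or (arr < 0).any():
                raise ValueError("sample motif probabilities must be a simplex")

    def to_json(self, path: str | Path, include_samples: bool = False) -> None:
        obj = {
            "effect_bins": list(self.effect_bins),
            "trajectory_pattern": {str(k): v for k, v in self.trajectory_pattern.items()},
            "labels": self.labels,
            "sample_batch": self.sample_batch,
            "group_probs": {
                f"{g}|{t}": arr.tolist() for (g, t), arr in self.group_probs.items()
            },
        }
        if include_samples:
            obj["sample_probs"] = {k: v.tolist() for k, v in self.sample_probs.items()}
        Path(path).write_text(json.dumps(obj))


@dataclass
class CohortSim:
    fragment_files: dict[str, Path]
    metadata: pd.DataFrame
    metadata_path: Path
    truth: SimTruth
    layout: GenomeLayout


def _effect_multiplier(pattern: str, timepoint_idx: int, delta: float) -> float:
    if pattern == "cluster1":
        return delta if timepoint_idx != 1 else 1.0
    if pattern == "cluster2":
        return delta
    if pattern == "cluster3":
        return 1.0 / delta
    raise ValueError(pattern)


class _ChromIndex:
    """Sorted (code, position) keys for end placement on one chromosome."""

    def __init__(self, base_codes: np.ndarray, k: int):
        self.L = base_codes.size
        self.k = k
        kf = kmer_codes(base_codes, k)
        pos = np.arange(kf.size)
        ok = kf >= 0
        # upstream keys: forward k-mer code at the start position
        self.up_keys = np.sort(kf[ok] * (self.L + 1) + pos[ok])
        # downstream keys: motif observed at fragment end e is
        # revcomp(ref[e-k, e)); index by e
        dn = revcomp_codes(kf, k)
        e = pos + k
        self.dn_keys = np.sort(dn[ok] * (self.L + 1) + e[ok])

    def sample_starts(self, m1, lo, hi, rng):
        """Uniform start among positions in [lo, hi) whose k-mer == m1."""
        m1 = np.asarray(m1, dtype=np.int64)
        a = np.searchsorted(self.up_keys, m1 * (self.L + 1) + lo)
        b = np.searchsorted(self.up_keys, m1 * (self.L + 1) + hi)
        n = len(m1)
        out = np.empty(n, dtype=np.int64)
        have = b > a
        pick = a + (rng.random(n) * (b - a)).astype(np.int64)
        out[have] = self.up_keys[np.minimum(pick[have], b[have] - 1)] % (self.L + 1)
        # fallback: motif absent in window -> uniform position
        miss = ~have
        out[miss] = lo[miss] + (rng.random(miss.sum()) * (hi[miss] - lo[miss])).astype(np.int64)
        return out

    def place_ends(self, m2, e_lo, e_hi, e_target):
        """End position matching motif m2 in [e_lo, e_hi], nearest e_target.

        Falls back to e_target when no position in the window carries m2.
        """
        m2 = np.asarray(m2, dtype=np.int64)
        base = m2 * (self.L + 1)
        a = np.searchsorted(self.dn_keys, base + e_lo)
        b = np.searchsorted(self.dn_keys, base + e_hi + 1)
        out = e_target.copy()
        have = b > a
        j = np.clip(np.searchsorted(self.dn_keys, base + e_target), a, np.maximum(b - 1, a))
        cand1 = self.dn_keys[np.minimum(j, len(self.dn_keys) - 1)] % (self.L + 1)
        jm = np.maximum(j - 1, a)
        cand0 = self.dn_keys[np.minimum(jm, len(self.dn_keys) - 1)] % (self.L + 1)
        closer0 = np.abs(cand0 - e_target) < np.abs(cand1 - e_target)
        best = np.where(closer0, cand0, cand1)
        out[have] = best[have]
        return out


def simulate_cohort(
    config: SimConfig,
    layout: GenomeLayout,
    reference,
    outdir: str | Path,
) -> CohortSim:
    """Simulate fragment files, metadata and truth for a full cohort.

    One sample per (patient, timepoint); patients split evenly into
    responders and non-responders; institutes and technical batches
    assigned by random permutation of patients so that batches are not
    confounded with response by construction (confounded designs can be
    produced by editing the returned metadata).
    """
    config.validate(layout)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ref = _ReferenceCodes(reference)
    n_motifs = 4**config.k
    k = config.k

    chrom_index = {c: _ChromIndex(ref.base_codes(c), k) for c in layout.chroms}

    n_pat = 2 * config.n_patients_per_group
    groups = ["Responder"] * config.n_patients_per_group + [
        "Non-Responder"
    ] * config.n_patients_per_group
    inst_perm = rng.permutation(n_pat)
    batch_perm = rng.permutation(n_pat)
    institutes = [config.institutes[inst_perm[p] % len(config.institutes)] for p in range(n_pat)]
    # all timepoints of a patient share an isolation/library batch
    iso_batch = [int(batch_perm[p] // 6) for p in range(n_pat)]
    lib_batch = [int(batch_perm[p] // 8) for p in range(n_pat)]

    # batch tilt per (institute, library date): elementwise exp(N(0, sd)) on
    # the motif axis, plus an optional per-bin concentration multiplier
    # (batch_bin_sd) creating bin-level entropy structure that survives the
    # per-sample z-transform (motif-axis tilts alone shift all bins alike)
    tilts: dict[str, np.ndarray] = {}
    bin_tilts: dict[str, np.ndarray] = {}

    def tilt_for(inst: str, lib: int) -> tuple[str, np.ndarray, np.ndarray]:
        key = f"{inst}|lib{lib:02d}"
        if key not in tilts:
            if config.batch_tilt_sd > 0:
                tilts[key] = np.exp(rng.normal(0.0, config.batch_tilt_sd, size=n_motifs))
            else:
                tilts[key] = np.ones(n_motifs)
            if config.batch_bin_sd > 0:
                bin_tilts[key] = np.exp(rng.normal(0.0, config.batch_bin_sd, size=layout.n_bins))
            else:
                bin_tilts[key] = np.ones(layout.n_bins)
        return key, tilts[key], bin_tilts[key]

    # group/timepoint mean motif vectors (uniform base composition; effect
    # changes concentration, not the mean)
    base_alpha = np.full(n_motifs, config.base_concentration)
    group_probs = {
        (g, t): np.tile(base_alpha / base_alpha.sum(), (layout.n_bins, 1))
        for g in ("Responder", "Non-Responder")
        for t in config.timepoints
    }

    widths = (layout.bins["end"] - layout.bins["start"]).to_numpy()
    meta_rows = []
    fragment_files: dict[str, Path] = {}
    sample_probs: dict[str, np.ndarray] = {}
    sample_batch: dict[str, str] = {}
    labels: dict[str, str] = {}

    effect_bins = set(config.effect_bins)
    for p in range(n_pat):
        pid = f"P{p:03d}"
        group = groups[p]
        demo = {
            "age": int(rng.integers(30, 80)),
            "gender": str(rng.choice(["Male", "Female"])),
            "smoking": str(rng.choice(["Yes", "No"])),
            "alcohol": str(rng.choice(["Yes", "No"])),
        }
        for t_idx, tp in enumerate(config.timepoints):
            sid = f"{pid}_{tp}"
            batch_key, tilt, bin_tilt = tilt_for(institutes[p], lib_batch[p])
            labels[sid] = group
            sample_batch[sid] = batch_key

            probs = np.empty((layout.n_bins, n_motifs))
            frames = []
            for b in range(layout.n_bins):
                alpha = base_alpha * tilt * bin_tilt[b]
                if b in effect_bins and group == "Non-Responder":
                    pattern = config.trajectory_pattern.get(b, "cluster2")
                    alpha = alpha * _effect_multiplier(pattern, t_idx, config.effect_delta)
                pvec = rng.dirichlet(alpha)
                probs[b] = pvec
                n_frag = rng.poisson(config.coverage)
                if n_frag == 0:
                    continue
                row = layout.bins.iloc[b]
                chrom = row["chrom"]
                ci = chrom_index[chrom]
                bin_lo = int(row["start"])
                bin_hi = int(row["end"])
                m1 = rng.choice(n_motifs, size=n_frag, p=pvec)
                m2 = rng.choice(n_motifs, size=n_frag, p=pvec)
                lo = np.full(n_frag, bin_lo, dtype=np.int64)
                hi = np.full(n_frag, min(bin_hi, ci.L - 50), dtype=np.int64)
                starts = ci.sample_starts(m1, lo, hi, rng)
                length = rng.normal(config.fraglen_mean, config.fraglen_sd, size=n_frag)
                length = np.clip(np.round(length), 50, 350).astype(np.int64)
                e_target = np.minimum(starts + length, ci.L)
                e_lo = starts + 50
                e_hi = np.minimum(starts + 350, ci.L)
                ends = ci.place_ends(m2, e_lo, e_hi, e_target)
                frames.append(
                    pd.DataFrame(
                        {"chrom": chrom, "start": starts, "end": ends}
                    )
                )
            sample_probs[sid] = probs
            frags = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=["chrom", "start", "end"])
            )
            frags = frags.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
            frags["name"] = [f"{sid}_f{i}" for i in range(len(frags))]
            frags["mapq"] = 60
            frags["strand"] = "+"
            suffix = ".bed.gz" if config.gzip_output else ".bed"
            path = outdir / f"{sid}{suffix}"
            opener = gzip.open if config.gzip_output else open
            with opener(path, "wt") as fh:
                frags.to_csv(fh, sep="\t", header=False, index=False)
            fragment_files[sid] = path

            meta_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pid,
                    "institute": institutes[p],
                    "timepoint": tp,
                    "isolation_date": f"2023-{iso_batch[p] + 1:02d}-15",
                    "library_date": f"2023-{lib_batch[p] + 1:02d}-20",
                    "response": group,
                    **demo,
                }
            )

    metadata = pd.DataFrame(meta_rows)
    metadata_path = outdir / "metadata.tsv"
    metadata.to_csv(metadata_path, sep="\t", index=False)
    truth = SimTruth(
        group_probs=group_probs,
        sample_probs=sample_probs,
        batch_tilts=tilts,
        sample_batch=sample_batch,
        labels=labels,
        effect_bins=tuple(config.effect_bins),
        trajectory_pattern=dict(config.trajectory_pattern),
        batch_bin_tilts=bin_tilts,
    )
    return CohortSim(
        fragment_files=fragment_files,
        metadata=metadata,
        metadata_path=metadata_path,
        truth=truth,
        layout=layout,
    )
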