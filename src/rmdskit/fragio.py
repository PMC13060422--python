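"""Fragment I/O, QC filtering, genome binning and end-motif counting.

Coordinates are 0-based half-open (BED convention) throughout. Fragment QC
mirrors standard low-coverage cfDNA preprocessing: mapping quality >= 30,
fragment length 50-350 bp inclusive, chromosomes restricted to the layout,
and exclusion of fragments overlapping a blacklist.

End-motif conventions (``end_side``):

* ``five_prime`` — the informative, nuclease-cut side. The upstream 5' end
  motif is the reference k-mer ``[start, start+k)``; the downstream 5' end
  motif is the reverse complement of ``[end-k, end)`` (the 5' end of the
  bottom strand), the double-strand convention of the end-motif literature.
* ``three_prime`` — a composition-matched negative control: the reverse
  complements of the corresponding ``five_prime`` motifs, i.e. the motif
  pair read off the 3' termini.

Each end motif is tallied into the genomic bin containing its own terminal
base (``start`` for the upstream end, ``end-1`` for the downstream end).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode_bases, kmer_codes, motif_lexicon, revcomp_codes

MIN_FRAGMENT_LENGTH = 50
MAX_FRAGMENT_LENGTH = 350
MIN_MAPQ = 30

__all__ = [
    "GenomeLayout",
    "FragmentSet",
    "MotifCountMatrix",
    "load_layout",
    "read_chrom_sizes",
    "read_fragments",
    "filter_fragments",
    "extract_end_motifs",
    "end_motif_events",
]


# ---------------------------------------------------------------------------
# intervals


def _read_bed3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df.astype({"start": np.int64, "end": np.int64})


class _IntervalIndex:
    """Merged, sorted intervals per chromosome with overlap queries."""

    def __init__(self, intervals: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in intervals.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            order = np.argsort(s, kind="stable")
            s, e = s[order], e[order]
            # merge overlapping/adjacent
            ms, me = [], []
            for a, b in zip(s, e):
                if me and a <= me[-1]:
                    me[-1] = max(me[-1], b)
                else:
                    ms.append(a)
                    me.append(b)
            self._by_chrom[str(chrom)] = (np.asarray(ms), np.asarray(me))

    def overlaps(self, chrom: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Boolean mask: does [start, end) overlap any interval on chrom."""
        out = np.zeros(len(start), dtype=bool)
        chrom = np.asarray(chrom, dtype=object)
        for c, (ms, me) in self._by_chrom.items():
            sel = chrom == c
            if not sel.any():
                continue
            s, e = start[sel], end[sel]
            # first interval whose end > fragment start
            idx = np.searchsorted(me, s, side="right")
            hit = (idx < len(ms)) & (ms[np.minimum(idx, len(ms) - 1)] < e)
            out[sel] = hit
        return out

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        ms, me = self._by_chrom.get(chrom, (np.empty(0), np.empty(0)))
        if len(ms) == 0:
            return 0
        o = np.minimum(me, end) - np.maximum(ms, start)
        return int(np.clip(o, 0, None).sum())


# ---------------------------------------------------------------------------
# layout


@dataclass
class GenomeLayout:
    """Bin tiling of a genome: the coordinate authority for every stage.

    Bins tile each chromosome left to right without overlap; the terminal
    bin may be shorter than ``bin_size``. Bin identity is its index in
    ``bins``. ``mask`` marks usable bins (True = usable).
    """

    chroms: list[str]
    lengths: dict[str, int]
    bin_size: int
    bins: pd.DataFrame  # columns: chrom, start, end
    mask: np.ndarray

    def __post_init__(self):
        self._offsets = {}
        off = 0
        for c in self.chroms:
            self._offsets[c] = off
            off += -(-self.lengths[c] // self.bin_size)
        if off != len(self.bins):
            raise ValueError("bins do not tile the declared chromosomes")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def bin_ids(self) -> list[str]:
        b = self.bins
        return [f"{c}:{s}-{e}" for c, s, e in zip(b["chrom"], b["start"], b["end"])]

    def bin_index(self, chrom: str, pos: np.ndarray | int) -> np.ndarray | int:
        """Index of the bin containing base ``pos`` on ``chrom``."""
        return self._offsets[chrom] + np.asarray(pos) // self.bin_size

    def usable_genome_length(self) -> int:
        widths = (self.bins["end"] - self.bins["start"]).to_numpy()
        return int(widths[self.mask].sum())

    @classmethod
    def from_sizes(cls, sizes: Mapping[str, int], bin_size: int) -> "GenomeLayout":
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        chroms = list(sizes)
        if len(set(chroms)) != len(chroms):
            raise ValueError("duplicate chromosome names")
        rows = []
        for c in chroms:
            length = int(sizes[c])
            if length <= 0:
                raise ValueError(f"non-positive length for {c}")
            for s in range(0, length, bin_size):
                rows.append((c, s, min(s + bin_size, length)))
        bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(
            chroms=chroms,
            lengths={c: int(sizes[c]) for c in chroms},
            bin_size=bin_size,
            bins=bins,
            mask=np.ones(len(bins), dtype=bool),
        )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
    if df["chrom"].duplicated().any():
        raise ValueError("duplicate chromosome names in sizes table")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def load_layout(
    chrom_sizes: str | Path | Mapping[str, int],
    bin_size: int,
    blacklist: str | Path | None = None,
    mappability: str | Path | None = None,
    mappability_min: float = 0.9,
    blacklist_mask_frac: float = 0.5,
) -> GenomeLayout:
    """Tile chromosomes into fixed-width bins and mask unusable ones.

    A bin is masked (unusable) if blacklist intervals cover more than
    ``blacklist_mask_frac`` of it, or if its mean mappability (from a
    BED/bedGraph track; missing positions score 0) falls below
    ``mappability_min``.
    """
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    layout = GenomeLayout.from_sizes(chrom_sizes, bin_size)

    if blacklist is not None:
        idx = _IntervalIndex(_read_bed3(blacklist))
        for i, row in layout.bins.iterrows():
            width = row["end"] - row["start"]
            if idx.overlap_bp(row["chrom"], row["start"], row["end"]) > blacklist_mask_frac * width:
                layout.mask[i] = False

    if mappability is not None:
        df = pd.read_csv(mappability, sep="\t", header=None, comment="#")
        if df.shape[1] >= 4:
            df = df.iloc[:, :4]
            df.columns = ["chrom", "start", "end", "score"]
            # bedGraph score column; a plain BED 4th column that is not
            # numeric (a name) means full mappability over the interval
            df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(1.0)
        else:
            df = df.iloc[:, :3]
            df.columns = ["chrom", "start", "end"]
            df["score"] = 1.0
        for i, row in layout.bins.iterrows():
            sub = df[df["chrom"] == row["chrom"]]
            o = np.minimum(sub["end"].to_numpy(), row["end"]) - np.maximum(
                sub["start"].to_numpy(), row["start"]
            )
            weighted = float((np.clip(o, 0, None) * sub["score"].to_numpy()).sum())
            if weighted / (row["end"] - row["start"]) < mappability_min:
                layout.mask[i] = False
    return layout


# ---------------------------------------------------------------------------
# fragments


@dataclass
class FragmentSet:
    """QC-passed fragment intervals plus a per-rule rejection log."""

    records: pd.DataFrame  # columns: chrom, start, end, mapq, strand
    source: str = ""
    filter_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a BED-like fragment file (chrom, start, end[, name, mapq, strand]).

    Gzip is detected from the ``.gz`` suffix. Missing mapq is left as NaN
    (treated as pass by :func:`filter_fragments`, inputs being pre-filtered
    upstream) and missing strand as '.'.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", header=None, comment="#", dtype={0: str})
    names = ["chrom", "start", "end", "name", "mapq", "strand"]
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    for col in names[df.shape[1] :]:
        df[col] = np.nan
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["mapq"] = pd.to_numeric(df["mapq"], errors="coerce")
    df["strand"] = df["strand"].fillna(".")
    return df


def filter_fragments(
    records: pd.DataFrame | str | Path,
    layout: GenomeLayout,
    blacklist: str | Path | None = None,
    min_mapq: int = MIN_MAPQ,
    min_length: int = MIN_FRAGMENT_LENGTH,
    max_length: int = MAX_FRAGMENT_LENGTH,
) -> FragmentSet:
    """Apply fragment-level QC and return survivors with rejection counts.

    Rules, applied in order (a record is counted under the first failure):
    malformed (start >= end), unknown chromosome, mapq < min_mapq (missing
    mapq passes, flagged in the log), length outside [min_length,
    max_length] inclusive, blacklist overlap.
    """
    source = ""
    if not isinstance(records, pd.DataFrame):
        source = str(records)
        records = read_fragments(records)
    df = records.copy()
    if "mapq" not in df:
        df["mapq"] = np.nan
    if "strand" not in df:
        df["strand"] = "."

    n = len(df)
    reason = np.full(n, "", dtype=object)
    malformed = (df["start"] >= df["end"]).to_numpy()
    reason[malformed] = "malformed"

    known = df["chrom"].isin(layout.chroms).to_numpy()
    reason[(reason == "") & ~known] = "chrom"

    mapq = df["mapq"].to_numpy(dtype=float)
    mapq_fail = ~np.isnan(mapq) & (mapq < min_mapq)
    reason[(reason == "") & mapq_fail] = "mapq"

    length = (df["end"] - df["start"]).to_numpy()
    len_fail = (length < min_length) | (length > max_length)
    reason[(reason == "") & len_fail] = "length"

    if blacklist is not None:
        idx = _IntervalIndex(_read_bed3(blacklist))
        bl = idx.overlaps(
            df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
        )
        reason[(reason == "") & bl] = "blacklist"

    keep = reason == ""
    counts = pd.Series(reason[~keep]).value_counts().to_dict()
    log = {
        "n_input": int(n),
        "n_kept": int(keep.sum()),
        "rejected": {k: int(v) for k, v in counts.items()},
        "mapq_missing": int(np.isnan(mapq).sum()),
    }
    kept = df.loc[keep, ["chrom", "start", "end", "mapq", "strand"]].reset_index(drop=True)
    return FragmentSet(records=kept, source=source, filter_log=log)


# ---------------------------------------------------------------------------
# end-motif counting


@dataclass
class MotifCountMatrix:
    """Per-bin counts of fragment end motifs for one sample.

    ``counts`` is ``n_bins x 4**k``; column order is the lexicographic
    motif lexicon. Tallies record ends not counted: non-ACGT windows
    (``n_discarded``), ends within k bp of a chromosome boundary
    (``n_edge_skipped``) and ends landing in masked bins
    (``n_masked_skipped``). Conservation:
    counts.sum() + all tallies == 2 * n_fragments.
    """

    sample_id: str
    end_side: str
    k: int
    counts: np.ndarray
    layout: GenomeLayout
    n_fragments: int
    n_discarded: int = 0
    n_edge_skipped: int = 0
    n_masked_skipped: int = 0

    @property
    def lexicon(self) -> list[str]:
        return motif_lexicon(self.k)

    @property
    def n_ends(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        b = self.layout.bins
        df = pd.DataFrame(self.counts, columns=self.lexicon)
        df.insert(0, "end", b["end"].to_numpy())
        df.insert(0, "start", b["start"].to_numpy())
        df.insert(0, "chrom", b["chrom"].to_numpy())
        df.insert(0, "bin_id", self.layout.bin_ids)
        df.to_csv(path, sep="\t", index=False)


class _ReferenceCodes:
    """Lazily-encoded per-chromosome base codes from a FASTA."""

    def __init__(self, reference):
        import pyfaidx

        if isinstance(reference, (str, Path)):
            reference = pyfaidx.Fasta(str(reference))
        self._fasta = reference
        self._cache: dict[str, np.ndarray] = {}

    def base_codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._cache:
            self._cache[chrom] = encode_bases(str(self._fasta[chrom][:]))
        return self._cache[chrom]


def end_motif_events(
    fragments: FragmentSet,
    reference,
    k: int = 4,
    end_side: str = "five_prime",
) -> tuple[pd.DataFrame, dict]:
    """Per-end motif events: one row per countable fragment end.

    Returns ``(events, tallies)`` where events has columns chrom, pos
    (the end's terminal base), code (motif code) and tallies counts ends
    skipped at chromosome edges or discarded for non-ACGT windows. Used by
    both binned counting and sliding-window scoring.
    """
    if end_side not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown end_side {end_side!r}")
    if k not in (3, 4, 5, 6):
        raise ValueError("k must be in 3..6")
    ref = reference if isinstance(reference, _ReferenceCodes) else _ReferenceCodes(reference)

    chunks = []
    n_edge = 0
    n_discard = 0
    for chrom, sub in fragments.records.groupby("chrom", sort=False):
        codes = ref.base_codes(str(chrom))
        L = codes.size
        kf = kmer_codes(codes, k)
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()

        # upstream end: terminal base = start, window [start, start+k)
        up_ok = (s >= 0) & (s + k <= L)
        n_edge += int((~up_ok).sum())
        up_code = np.full(len(s), -1, dtype=np.int64)
        up_code[up_ok] = kf[s[up_ok]]
        # downstream end: terminal base = end-1, window [end-k, end)
        dn_ok = (e - k >= 0) & (e <= L)
        n_edge += int((~dn_ok).sum())
        dn_fwd = np.full(len(e), -1, dtype=np.int64)
        dn_fwd[dn_ok] = kf[e[dn_ok] - k]

        if end_side == "five_prime":
            dn_code = revcomp_codes(dn_fwd, k)
        else:
            up_code = revcomp_codes(up_code, k)
            dn_code = dn_fwd

        pos = np.concatenate([s, e - 1])
        code = np.concatenate([up_code, dn_code])
        ok = np.concatenate([up_ok, dn_ok])
        invalid = ok & (code < 0)
        n_discard += int(invalid.sum())
        sel = ok & (code >= 0)
        chunks.append(
            pd.DataFrame({"chrom": chrom, "pos": pos[sel], "code": code[sel]})
        )
    events = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=["chrom", "pos", "code"])
    )
    return events, {"n_edge_skipped": n_edge, "n_discarded": n_discard}


def extract_end_motifs(
    fragments: FragmentSet,
    reference,
    layout: GenomeLayout,
    k: int = 4,
    end_side: str = "five_prime",
    sample_id: str = "",
) -> MotifCountMatrix:
    """Tally fragment end motifs into layout bins from the reference.

    Each fragment contributes two ends; each end is assigned to the bin
    containing its own terminal base. Ends in masked bins are skipped and
    tallied separately.
    """
    events, tallies = end_motif_events(fragments, reference, k=k, end_side=end_side)
    n_motifs = 4**k
    counts = np.zeros((layout.n_bins, n_motifs), dtype=np.int64)
    n_masked = 0
    for chrom, sub in events.groupby("chrom", sort=False):
        bidx = layout.bin_index(str(chrom), sub["pos"].to_numpy())
        usable = layout.mask[bidx]
        n_masked += int((~usable).sum())
        np.add.at(counts, (bidx[usable], sub["code"].to_numpy()[usable]), 1)
    return MotifCountMatrix(
        sample_id=sample_id,
        end_side=end_side,
        k=k,
        counts=counts,
        layout=layout,
        n_fragments=len(fragments),
        n_discarded=tallies["n_discarded"],
        n_edge_skipped=tallies["n_edge_skipped"],
        n_masked_skipped=n_masked,
    )
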