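"""Layout tiling, fragment QC and end-motif counting against oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rmdskit import fragio
from rmdskit._seq import (
    code_to_motif,
    encode_bases,
    motif_lexicon,
    motif_to_code,
    revcomp_codes,
    revcomp_str,
)


# ---------------------------------------------------------------------------
# sequence codes


@pytest.mark.parametrize("k,size", [(3, 64), (4, 256), (5, 1024), (6, 4096)])
def test_motif_lexicon_cardinality_and_order(k, size):
    lex = motif_lexicon(k)
    assert len(lex) == size
    assert lex == sorted(lex)
    assert [motif_to_code(m) for m in lex] == list(range(size))


def test_revcomp_code_matches_string_revcomp():
    rng = np.random.default_rng(0)
    for k in (3, 4, 5):
        codes = rng.integers(0, 4**k, size=50)
        for c in codes:
            m = code_to_motif(int(c), k)
            assert code_to_motif(int(revcomp_codes(c, k)), k) == revcomp_str(m)


# ---------------------------------------------------------------------------
# layout


def test_layout_tiles_with_short_terminal_bin():
    layout = fragio.GenomeLayout.from_sizes({"chr1": 1_200_000}, 500_000)
    assert layout.bins[["start", "end"]].to_numpy().tolist() == [
        [0, 500_000], [500_000, 1_000_000], [1_000_000, 1_200_000]
    ]


def test_layout_bin_count_two_chromosomes():
    layout = fragio.GenomeLayout.from_sizes({"chr1": 5_000_000, "chr2": 5_000_000}, 500_000)
    assert layout.n_bins == 20
    # bins tile without overlap and end within chromosome bounds
    for chrom, sub in layout.bins.groupby("chrom"):
        assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()
        assert sub["end"].max() == layout.lengths[chrom]


def test_layout_errors():
    with pytest.raises(ValueError):
        fragio.GenomeLayout.from_sizes({"chr1": 0}, 100)
    with pytest.raises(ValueError):
        fragio.GenomeLayout.from_sizes({"chr1": 100}, 0)


def test_blacklist_masks_majority_covered_bin(tmp_path):
    bl = tmp_path / "bl.bed"
    # covers 60% of bin 2 ([200,300) of a 100bp-bin layout)
    bl.write_text("chr1\t200\t260\n")
    layout = fragio.load_layout({"chr1": 500}, 100, blacklist=bl)
    assert not layout.mask[2]
    assert layout.mask[[0, 1, 3, 4]].all()


def test_mappability_masks_low_bins(tmp_path):
    mp = tmp_path / "map.bedgraph"
    # bin 0 fully covered at 1.0; bin 1 covered at 0.5 -> masked at 0.9
    mp.write_text("chr1\t0\t100\t1.0\nchr1\t100\t200\t0.5\n")
    layout = fragio.load_layout({"chr1": 200}, 100, mappability=mp, mappability_min=0.9)
    assert layout.mask[0] and not layout.mask[1]


# ---------------------------------------------------------------------------
# fragment QC


def _records(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq", "strand"])


def test_filter_boundaries_inclusive(toy_layout):
    rows = [
        ("chr1", 1000, 1349, 30, "+"),   # length 349, mapq 30 -> kept
        ("chr1", 1000, 1050, 30, "+"),   # length 50 -> kept (inclusive)
        ("chr1", 1000, 1350, 30, "+"),   # length 350 -> kept (inclusive)
        ("chr1", 1000, 1049, 60, "+"),   # length 49 -> rejected: length
        ("chr1", 1000, 1351, 60, "+"),   # length 351 -> rejected: length
        ("chr1", 1000, 1200, 29, "+"),   # mapq 29 -> rejected: mapq
        ("chrX", 1000, 1200, 60, "+"),   # unknown chrom
        ("chr1", 1200, 1100, 60, "+"),   # malformed
    ]
    fs = fragio.filter_fragments(_records(rows), toy_layout)
    assert len(fs) == 3
    assert fs.filter_log["rejected"] == {"length": 2, "mapq": 1, "chrom": 1, "malformed": 1}


def test_filter_missing_mapq_passes_and_is_flagged(toy_layout):
    rows = [("chr1", 1000, 1200, np.nan, "+")]
    fs = fragio.filter_fragments(_records(rows), toy_layout)
    assert len(fs) == 1
    assert fs.filter_log["mapq_missing"] == 1


def test_filter_blacklist_overlap(toy_layout, tmp_path):
    bl = tmp_path / "bl.bed"
    bl.write_text("chr1\t1500\t1600\n")
    rows = [
        ("chr1", 1400, 1550, 60, "+"),  # overlaps
        ("chr1", 1600, 1800, 60, "+"),  # abuts, half-open: no overlap
    ]
    fs = fragio.filter_fragments(_records(rows), toy_layout, blacklist=bl)
    assert len(fs) == 1
    assert fs.filter_log["rejected"] == {"blacklist": 1}


def test_filter_planted_violations_accounted(toy_layout, rng):
    """1,000 records with 100 planted violations: exactly 900 survive."""
    n_good, n_bad = 900, 100
    good = pd.DataFrame({
        "chrom": "chr1",
        "start": rng.integers(0, 900_000, n_good),
        "mapq": 60, "strand": "+",
    })
    good["end"] = good["start"] + rng.integers(50, 351, n_good)
    bad_kind = rng.integers(0, 3, n_bad)
    bad = pd.DataFrame({
        "chrom": np.where(bad_kind == 0, "chrUn", "chr1"),
        "start": rng.integers(0, 900_000, n_bad),
        "mapq": np.where(bad_kind == 1, 10, 60),
        "strand": "+",
    })
    bad["end"] = bad["start"] + np.where(bad_kind == 2, 30, 100)
    fs = fragio.filter_fragments(
        pd.concat([good, bad], ignore_index=True)[["chrom", "start", "end", "mapq", "strand"]],
        toy_layout,
    )
    assert len(fs) == n_good
    assert sum(fs.filter_log["rejected"].values()) == n_bad


def test_read_fragments_gzip_roundtrip(tmp_path, toy_layout):
    import gzip

    path = tmp_path / "x.bed.gz"
    with gzip.open(path, "wt") as fh:
        fh.write("chr1\t100\t300\tf0\t60\t+\nchr2\t200\t400\tf1\t60\t-\n")
    df = fragio.read_fragments(path)
    assert len(df) == 2 and df.loc[1, "chrom"] == "chr2"


# ---------------------------------------------------------------------------
# end-motif extraction


def _write_ref(tmp_path, seqs):
    fa = tmp_path / "ref.fa"
    with open(fa, "w") as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n{s}\n")
    return fa


def test_five_prime_motifs_read_from_reference(tmp_path):
    seq = "ACGT" + "A" * 96 + "TTAA" + "A" * 50
    fa = _write_ref(tmp_path, {"chr1": seq})
    layout = fragio.GenomeLayout.from_sizes({"chr1": len(seq)}, len(seq))
    frags = fragio.FragmentSet(
        records=pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [104],
                              "mapq": [60], "strand": ["+"]})
    )
    counts = fragio.extract_end_motifs(frags, fa, layout, k=4, end_side="five_prime")
    # upstream end: ACGT; downstream end: revcomp(TTAA) = TTAA (palindrome)
    assert counts.counts[0, motif_to_code("ACGT")] == 1
    assert counts.counts[0, motif_to_code("TTAA")] == 1
    assert counts.counts.sum() == 2


def test_three_prime_is_revcomp_of_five_prime(tmp_path, rng):
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    fa = _write_ref(tmp_path, {"chr1": seq})
    layout = fragio.GenomeLayout.from_sizes({"chr1": 5000}, 5000)
    starts = rng.integers(10, 4500, size=200)
    frags = fragio.FragmentSet(records=pd.DataFrame({
        "chrom": "chr1", "start": starts,
        "end": starts + rng.integers(50, 300, size=200),
        "mapq": 60, "strand": "+",
    }))
    five = fragio.extract_end_motifs(frags, fa, layout, k=4, end_side="five_prime")
    three = fragio.extract_end_motifs(frags, fa, layout, k=4, end_side="three_prime")
    # the 3' multiset is the reverse complement of the 5' multiset per bin
    rc = revcomp_codes(np.arange(256), 4)
    assert (five.counts[0][rc] == three.counts[0]).all()


def test_n_bases_discard_only_affected_end(tmp_path):
    seq = "NNAC" + "G" * 100 + "ACGT" + "G" * 20
    fa = _write_ref(tmp_path, {"chr1": seq})
    layout = fragio.GenomeLayout.from_sizes({"chr1": len(seq)}, len(seq))
    frags = fragio.FragmentSet(records=pd.DataFrame({
        "chrom": ["chr1"], "start": [0], "end": [108], "mapq": [60], "strand": ["+"]
    }))
    counts = fragio.extract_end_motifs(frags, fa, layout, k=4)
    assert counts.n_discarded == 1
    assert counts.counts.sum() == 1  # downstream end still counted


def test_edge_skip_near_chromosome_boundary(tmp_path):
    seq = "ACGTACGTACGTACGTACGT" * 10  # 200 bp
    fa = _write_ref(tmp_path, {"chr1": seq})
    layout = fragio.GenomeLayout.from_sizes({"chr1": 200}, 200)
    frags = fragio.FragmentSet(records=pd.DataFrame({
        "chrom": ["chr1"], "start": [148], "end": [200], "mapq": [60], "strand": ["+"]
    }))
    counts = fragio.extract_end_motifs(frags, fa, layout, k=4)
    # downstream window [196,200) fits; upstream fits too -> no skip
    assert counts.n_edge_skipped == 0
    frags2 = fragio.FragmentSet(records=pd.DataFrame({
        "chrom": ["chr1"], "start": [150], "end": [201], "mapq": [60], "strand": ["+"]
    }))
    counts2 = fragio.extract_end_motifs(frags2, fa, layout, k=4)
    assert counts2.n_edge_skipped == 1  # end beyond chromosome


def _naive_counts(frags, seq_by_chrom, layout, k, end_side):
    """Brute-force per-fragment loop oracle."""
    counts = np.zeros((layout.n_bins, 4**k), dtype=int)
    edge = disc = masked = 0
    for _, r in frags.records.iterrows():
        seq = seq_by_chrom[r["chrom"]]
        L = len(seq)
        for which in ("up", "dn"):
            if which == "up":
                if r["start"] + k > L or r["start"] < 0:
                    edge += 1
                    continue
                motif = seq[r["start"] : r["start"] + k]
                if end_side == "three_prime":
                    motif = revcomp_str(motif)
                pos = r["start"]
            else:
                if r["end"] - k < 0 or r["end"] > L:
                    edge += 1
                    continue
                motif = seq[r["end"] - k : r["end"]]
                if end_side == "five_prime":
                    motif = revcomp_str(motif)
                pos = r["end"] - 1
            if any(c not in "ACGT" for c in motif):
                disc += 1
                continue
            b = layout.bin_index(r["chrom"], pos)
            if not layout.mask[b]:
                masked += 1
                continue
            counts[b, motif_to_code(motif)] += 1
    return counts, edge, disc, masked


def test_counting_matches_naive_oracle_and_conserves(cohort, toy_ref, toy_layout):
    sid = sorted(cohort.fragment_files)[0]
    frags = fragio.filter_fragments(cohort.fragment_files[sid], toy_layout)
    seqs = {}
    import pyfaidx

    fa = pyfaidx.Fasta(str(toy_ref.fasta))
    for c in toy_layout.chroms:
        seqs[c] = str(fa[c][:])
    for end_side in ("five_prime", "three_prime"):
        got = fragio.extract_end_motifs(frags, str(toy_ref.fasta), toy_layout,
                                        k=4, end_side=end_side)
        exp, edge, disc, masked = _naive_counts(frags, seqs, toy_layout, 4, end_side)
        assert (got.counts == exp).all()
        assert got.n_edge_skipped == edge
        assert got.n_discarded == disc
        assert got.n_masked_skipped == masked
        total = got.counts.sum() + got.n_discarded + got.n_edge_skipped + got.n_masked_skipped
        assert total == 2 * len(frags)


def test_strand_symmetry_under_reference_reversal(tmp_path, rng):
    """Reverse-complementing the reference and mirroring fragments leaves
    the five_prime motif multiset invariant."""
    n = 10_000
    seq = "".join(rng.choice(list("ACGT"), size=n))
    starts = rng.integers(10, n - 400, size=300)
    ends = starts + rng.integers(50, 350, size=300)

    fa1 = _write_ref(tmp_path, {"chr1": seq})
    layout = fragio.GenomeLayout.from_sizes({"chr1": n}, n)
    f1 = fragio.FragmentSet(records=pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": ends, "mapq": 60, "strand": "+"}))
    c1 = fragio.extract_end_motifs(f1, fa1, layout, k=4)

    fa2 = _write_ref(tmp_path / "..", {"chr1": revcomp_str(seq)}) if False else None
    fa2 = tmp_path / "ref2.fa"
    fa2.write_text(f">chr1\n{revcomp_str(seq)}\n")
    f2 = fragio.FragmentSet(records=pd.DataFrame(
        {"chrom": "chr1", "start": n - ends, "end": n - starts, "mapq": 60, "strand": "+"}))
    c2 = fragio.extract_end_motifs(f2, fa2, layout, k=4)
    assert (c1.counts.sum(axis=0) == c2.counts.sum(axis=0)).all()


def test_masked_bins_receive_no_counts(tmp_path, rng):
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    fa = _write_ref(tmp_path, {"chr1": seq})
    layout = fragio.GenomeLayout.from_sizes({"chr1": 2000}, 1000)
    layout.mask[1] = False
    starts = rng.integers(0, 1500, size=100)
    frags = fragio.FragmentSet(records=pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 100, "mapq": 60, "strand": "+"}))
    counts = fragio.extract_end_motifs(frags, fa, layout, k=4)
    assert counts.counts[1].sum() == 0
    assert counts.n_masked_skipped > 0
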