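"""Shared fixtures: toy references, layouts and a small simulated cohort.

Everything is generated programmatically at test time; session scope keeps
the expensive cohort simulations to one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from rmdskit import fragio, synthdata
from rmdskit.pipeline import drop_incomplete_bins, zrmds_matrix


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    """2 chromosomes x 1 Mb of uniform random sequence."""
    d = tmp_path_factory.mktemp("toyref")
    return synthdata.make_toy_reference(2, 1_000_000, seed=11, outdir=d)


@pytest.fixture(scope="session")
def toy_layout(toy_ref):
    return fragio.load_layout(toy_ref.chrom_sizes, bin_size=100_000)


@pytest.fixture(scope="session")
def cohort(toy_ref, toy_layout, tmp_path_factory):
    """Small longitudinal cohort with a planted low-entropy effect.

    6 patients per group, 3 timepoints, 20 bins; non-responders carry a
    concentration drop (delta=0.2) at 8 bins spanning all three trajectory
    archetypes.
    """
    d = tmp_path_factory.mktemp("cohort")
    effect = (0, 2, 5, 7, 10, 12, 15, 17)
    pattern = {0: "cluster1", 2: "cluster1", 5: "cluster2", 7: "cluster2",
               10: "cluster2", 12: "cluster3", 15: "cluster3", 17: "cluster3"}
    cfg = synthdata.SimConfig(
        n_chromosomes=2, chrom_length=1_000_000, bin_size=100_000,
        n_patients_per_group=6, coverage=400,
        effect_bins=effect, effect_delta=0.2, trajectory_pattern=pattern,
        seed=7,
    )
    return synthdata.simulate_cohort(cfg, toy_layout, toy_ref.fasta, d)


@pytest.fixture(scope="session")
def cohort_zmatrix(cohort, toy_ref, toy_layout):
    mat = zrmds_matrix(cohort.fragment_files, str(toy_ref.fasta), toy_layout, min_ends=50)
    return drop_incomplete_bins(mat)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
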