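"""Shared fixtures: a small simulated cohort and hand-built toy objects."""

import numpy as np
import pandas as pd
import pytest

from conim.cohort import Cohort
from conim.preprocess import prepare_burdens
from conim.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_cancer_types=2, samples_per_type=100, n_genes=100,
                     n_modifier_genes=2, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_burdens(small_cohort):
    return prepare_burdens(small_cohort)


def make_toy_cohort(sample_specs, mutations=(), segments=(), genome=None):
    """Hand-built cohort. sample_specs: (sample, type, time, event, ploidy)."""
    samples = pd.DataFrame(list(sample_specs),
                           columns=["sample", "cancer_type", "time", "event", "ploidy"])
    mut = pd.DataFrame(list(mutations) or None,
                       columns=["sample", "gene", "mut_class", "protein_pos",
                                "ref_count", "alt_count"])
    if not len(mut):
        mut = pd.DataFrame(columns=["sample", "gene", "mut_class", "protein_pos",
                                    "ref_count", "alt_count"])
    seg = pd.DataFrame(list(segments) or None,
                       columns=["sample", "chrom", "start", "end", "seg_value"])
    if not len(seg):
        seg = pd.DataFrame(columns=["sample", "chrom", "start", "end", "seg_value"])
    return Cohort(samples=samples, mutations=mut, cna_segments=seg,
                  genome=genome or {"chr1": 10_000_000})


@pytest.fixture
def toy_cohort():
    """3 samples, 2 types; segments with known filter outcomes."""
    return make_toy_cohort(
        [("a", "t1", 100.0, 1, 2.0), ("b", "t1", 200.0, 0, 3.1),
         ("c", "t2", 300.0, 1, 2.9)],
        mutations=[("a", "G1", "missense", 10, 30, 20),
                   ("a", "G1", "silent", 11, 25, 25),
                   ("b", "G2", "nonsense", 5, 40, 10)],
        segments=[("a", "chr1", 0, 100, 0.2),     # kept: len 100, |v| > 0.1
                  ("a", "chr1", 500, 800, 0.2),   # kept
                  ("a", "chr1", 1000, 1099, -0.2),  # removed: 99 bp
                  ("b", "chr1", 0, 5000, 0.05),   # removed: |v| <= 0.1
                  ("b", "chr1", 0, 5000, -0.2)])  # kept
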