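"""Shared fixtures: one default synthetic study analyzed once per session."""

import warnings

import numpy as np
import pytest

import cyclenuc as cn


@pytest.fixture(scope="session")
def study():
    """Default-condition two-species study (60 genes/species)."""
    return cn.generate_study(cn.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def raw_track(study):
    a = study.species_a
    return cn.pileup_reads(a.reads, {c: len(s) for c, s in a.genome.items()})


@pytest.fixture(scope="session")
def norm_track(raw_track):
    return cn.normalize_track(raw_track)


@pytest.fixture(scope="session")
def periodicity_a(study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = cn.preprocess(study.species_a.expression, k=10)
        f_cc = cn.detect_cell_cycle_frequency(expr, mode="secondary_max")
        return cn.score_and_classify(expr, f_cc)


@pytest.fixture(scope="session")
def hits_a(study):
    hits, _ = cn.find_upstream_hits(
        study.species_a.genes, study.species_a.genome, study.config.motif(), 600
    )
    return hits


@pytest.fixture(scope="session")
def hits_b(study):
    hits, _ = cn.find_upstream_hits(
        study.species_b.genes, study.species_b.genome, study.config.motif(), 600
    )
    return hits


@pytest.fixture(scope="session")
def profile_a(norm_track, hits_a, periodicity_a):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cn.build_profile_matrix(norm_track, hits_a, periodicity_a, flank=300)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
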