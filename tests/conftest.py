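"""Shared fixtures: synthetic benchmarks are expensive, so build once."""

import numpy as np
import pytest

from cdrdesign.synthetic import (SyntheticSpec, build_scaffold,
                                 default_composition,
                                 make_synthetic_benchmark)


@pytest.fixture(scope="session")
def scaffold():
    """One idealized kappa antibody-antigen complex."""
    return build_scaffold("kappa", seed=0)


@pytest.fixture(scope="session")
def scaffold_no_antigen():
    return build_scaffold("kappa", seed=0, with_antigen=False)


@pytest.fixture(scope="session")
def small_benchmark():
    """Three antibodies + a 12-entries-per-CDR toy database."""
    spec = SyntheticSpec(n_antibodies=3, entries_per_cdr=12, seed=11)
    return make_synthetic_benchmark(spec)


@pytest.fixture(scope="session")
def l1_benchmark():
    """Single-CDR benchmark (L1 only) for focused protocol runs."""
    spec = SyntheticSpec(
        n_antibodies=4, entries_per_cdr=16, seed=23,
        composition=default_composition(
            cdrs=("L1",), lengths={"L1": (10, 11)}, clusters_per_length=2))
    return make_synthetic_benchmark(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
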