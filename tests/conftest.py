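"""Shared fixtures: the three canonical circle topologies as deterministic
synthetic alignment sets, plus small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from nanocirc.simulator import SimConfig, TrueCircle, simulate_alignments

REF_LENGTHS = {"c1": 60_000, "c2": 60_000}


def make_fixture(circles, seed=0, coverage=20.0, background=0.0, jitter=0,
                 read_median=3_000.0, errors=True):
    """Deterministic alignment records for explicitly placed circles."""
    cfg = SimConfig(
        seed=seed,
        n_circles=len(circles),
        circle_coverage=coverage,
        background_coverage=background,
        junction_jitter=jitter,
        read_length_median=read_median,
        read_length_sigma=0.4,
        sub_rate=0.05 if errors else 0.0,
        ins_rate=0.03 if errors else 0.0,
        del_rate=0.04 if errors else 0.0,
    )
    sim = simulate_alignments(REF_LENGTHS, circles, cfg)
    return sim, cfg


@pytest.fixture(scope="session")
def simple_circle():
    return TrueCircle("fig_simple", [("c1", 2_000, 5_000, "+")], "simple")


@pytest.fixture(scope="session")
def chimeric_circle():
    return TrueCircle(
        "fig_chimeric",
        [("c1", 10_000, 14_000, "+"), ("c2", 3_000, 6_000, "+")],
        "chimeric",
    )


@pytest.fixture(scope="session")
def deletion_circle():
    return TrueCircle(
        "fig_deletion",
        [("c1", 20_000, 24_000, "+"), ("c1", 26_000, 30_000, "+")],
        "with_deletion",
    )


@pytest.fixture(scope="session")
def simple_fixture(simple_circle):
    return make_fixture([simple_circle], seed=1)


@pytest.fixture(scope="session")
def chimeric_fixture(chimeric_circle):
    return make_fixture([chimeric_circle], seed=2)


@pytest.fixture(scope="session")
def deletion_fixture(deletion_circle):
    return make_fixture([deletion_circle], seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
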