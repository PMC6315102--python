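"""Stineman interpolation, grid alignment, orthologs, correlation networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dieltx.crossspecies import (
    align_to_grid,
    build_network,
    common_grid,
    kmer_similarity_scores,
    reciprocal_best_hits,
    stineman_interpolate,
)
from dieltx.matrixio import Scale
from dieltx.timecourse import CYANOTHECE_LABELS

from .oracles import rbh_oracle, stineman_oracle


# ---------------------------------------------------------------- stineman

def test_stineman_reproduces_linear_data_exactly():
    t = np.array([0.0, 1.0, 3.0, 7.0, 10.0])
    x = 2 * t + 1
    q = np.linspace(0, 10, 53)
    assert np.allclose(stineman_interpolate(t, x, q), 2 * q + 1, atol=1e-12)


def test_stineman_passes_through_knots(rng):
    t = np.sort(rng.uniform(0, 30, 9))
    x = rng.normal(size=9)
    assert np.allclose(stineman_interpolate(t, x, t), x, atol=1e-12)


def test_stineman_matches_reference_formulas(rng):
    for _ in range(20):
        t = np.sort(rng.uniform(0, 30, 8))
        while (np.diff(t) < 1e-3).any():
            t = np.sort(rng.uniform(0, 30, 8))
        x = rng.normal(size=8)
        q = np.linspace(t[0], t[-1], 41)
        assert np.allclose(
            stineman_interpolate(t, x, q), stineman_oracle(t, x, q), atol=1e-10
        )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(0, 100_000), st.integers(4, 10))
def test_stineman_monotone_inputs_give_monotone_interpolant(seed, n):
    """No overshoot: monotone knots yield a monotone dense interpolant."""
    rng = np.random.default_rng(seed)
    t = np.cumsum(rng.uniform(0.5, 3.0, n))
    x = np.cumsum(rng.uniform(0.0, 2.0, n))
    dense = np.linspace(t[0], t[-1], 400)
    y = stineman_interpolate(t, x, dense)
    assert (np.diff(y) >= -1e-9).all()
    y_dec = stineman_interpolate(t, -x, dense)
    assert (np.diff(y_dec) <= 1e-9).all()


def test_stineman_input_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        stineman_interpolate([0.0, 0.0, 1.0], [1.0, 2.0, 3.0], [0.5])
    with pytest.raises(ValueError, match="extrapolation"):
        stineman_interpolate([0.0, 1.0], [1.0, 2.0], [1.5])
    with pytest.raises(ValueError):
        stineman_interpolate([0.0], [1.0], [0.0])


# ------------------------------------------------------------ grid alignment

def test_common_grid_spans_overlap():
    grid = common_grid([(6.0, 36.0), (2.0, 22.0)], step=1.0)
    assert grid[0] == 6.0 and grid[-1] == 22.0
    assert np.allclose(np.diff(grid), 1.0)
    with pytest.raises(ValueError):
        common_grid([(0.0, 5.0), (10.0, 20.0)])


def test_align_passes_through_observed_points(make_matrix, rng):
    labels = list(CYANOTHECE_LABELS)
    m = make_matrix(rng.normal(size=(5, 6)), labels)
    grid = m.hours
    aligned = align_to_grid(m, grid)
    from dieltx.clustering import standardize

    z, _ = standardize(m)
    assert np.allclose(aligned.to_numpy(), z.to_numpy(), atol=1e-10)


def test_align_recovers_cosine_between_samples(make_matrix):
    """A noiseless diel cosine sampled at 6 points interpolates to within
    5% RMS of the true standardized curve on an hourly grid."""
    hours6 = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0])
    x = 8.0 + np.cos(2 * np.pi * (hours6 - 5.0) / 24.0)
    m = make_matrix([x], CYANOTHECE_LABELS)
    grid = np.arange(2.0, 23.0)
    aligned = align_to_grid(m, grid).to_numpy()[0]
    dense = 8.0 + np.cos(2 * np.pi * (grid - 5.0) / 24.0)
    true_z = (dense - x.mean()) / np.std(x, ddof=1)  # same standardization
    rms = np.sqrt(np.mean((aligned - true_z) ** 2))
    assert rms < 0.05 * np.sqrt(np.mean(true_z**2))


def test_align_refuses_grid_outside_span(make_matrix, rng):
    m = make_matrix(rng.normal(size=(3, 6)), CYANOTHECE_LABELS)
    with pytest.raises(ValueError, match="outside"):
        align_to_grid(m, np.arange(0.0, 36.0))


# ---------------------------------------------------------------- orthologs

def test_rbh_identity_block():
    s = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("wxyz"))
    pairs = reciprocal_best_hits(s, s.T)
    assert [(p.gene_a, p.gene_b) for p in pairs] == [
        ("a", "w"), ("b", "x"), ("c", "y"), ("d", "z")
    ]


def test_rbh_one_way_best_is_no_pair():
    ab = pd.DataFrame([[0.9, 0.1], [0.8, 0.2]], index=["a1", "a2"], columns=["b1", "b2"])
    ba = pd.DataFrame([[0.1, 0.9], [0.3, 0.2]], index=["b1", "b2"], columns=["a1", "a2"])
    pairs = reciprocal_best_hits(ab, ba)
    # a1's best is b1, but b1's best is a2 -> no pair for a1
    assert all(p.gene_a != "a1" for p in pairs)


def test_rbh_matches_double_argmax_oracle(rng):
    for _ in range(10):
        ab = rng.uniform(size=(8, 6))
        ba = rng.uniform(size=(6, 8))
        got = reciprocal_best_hits(
            pd.DataFrame(ab, index=[f"a{i}" for i in range(8)],
                         columns=[f"b{j}" for j in range(6)]),
            pd.DataFrame(ba, index=[f"b{j}" for j in range(6)],
                         columns=[f"a{i}" for i in range(8)]),
        )
        expected = rbh_oracle(ab, ba)
        assert [(int(p.gene_a[1:]), int(p.gene_b[1:])) for p in got] == expected


def test_kmer_similarity_basics(rng):
    seq = "".join(rng.choice(list("ACGT"), 80))
    other = "".join(rng.choice(list("ACGT"), 80))
    scores = kmer_similarity_scores({"a": seq}, {"same": seq, "diff": other})
    assert scores.at["a", "same"] == pytest.approx(1.0)
    assert scores.at["a", "diff"] < 0.3


# ------------------------------------------------------------------ network

def test_network_identical_courses_single_edge():
    t = np.arange(24.0)
    a = np.cos(2 * np.pi * t / 24)
    courses = pd.DataFrame([a, a.copy()], index=["x", "y"])
    net = build_network(courses, threshold=0.5)
    assert net.graph.number_of_edges() == 1
    assert net.graph.edges["x", "y"]["r"] == pytest.approx(1.0)


def test_network_antiphase_makes_no_edge():
    t = np.arange(24.0)
    courses = pd.DataFrame(
        [np.cos(2 * np.pi * t / 24), np.cos(2 * np.pi * (t - 12) / 24)],
        index=["x", "y"],
    )
    net = build_network(courses, threshold=0.5)
    assert net.graph.number_of_edges() == 0
    assert net.correlations.at["x", "y"] == pytest.approx(-1.0)
    anti = build_network(courses, threshold=0.5, include_anticorrelated=True)
    assert anti.graph.number_of_edges() == 1


def test_network_edges_monotone_in_threshold(rng):
    courses = pd.DataFrame(rng.normal(size=(15, 10)))
    strict = build_network(courses, threshold=0.5)
    loose = build_network(courses, threshold=0.2)
    assert set(strict.graph.edges) <= set(loose.graph.edges)
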