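"""Median polish, quantile normalization, summarization, replicate averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dieltx.matrixio import ProbeMap, Scale
from dieltx.preprocess import (
    average_replicates,
    delog,
    log2_transform,
    median_polish,
    preprocess_probes,
    quantile_normalize,
    summarize_genes,
)
from dieltx.simulate import make_truth, simulate_probe_matrix, ucyna_preset

from .oracles import median_polish_oracle, quantile_normalize_oracle


# ------------------------------------------------------------ median polish

def test_median_polish_additive_matrix_zero_residuals():
    r = np.array([1.0, 2.0, 5.0])
    c = np.array([0.5, -1.0, 2.0, 4.0])
    dec = median_polish(r[:, None] + c[None, :])
    assert np.allclose(dec.residuals, 0.0, atol=1e-12)
    assert dec.converged


def test_median_polish_constant_matrix():
    dec = median_polish(np.full((3, 4), 7.5))
    assert dec.overall == pytest.approx(7.5)
    assert np.allclose(dec.row_effects, 0)
    assert np.allclose(dec.column_effects, 0)


def test_median_polish_matches_scalar_oracle(rng):
    # median polish can cycle without converging, so both routes run the
    # same fixed number of sweeps (tol=0 disables the early stop)
    for _ in range(20):
        x = rng.normal(size=(6, 8))
        dec = median_polish(x, max_iter=200, tol=0.0)
        overall, row, col, resid = median_polish_oracle(x, n_iter=200)
        assert dec.overall == pytest.approx(overall, abs=1e-10)
        assert np.allclose(dec.summarized, np.asarray(col) + overall, atol=1e-10)
        assert np.allclose(dec.residuals, resid, atol=1e-10)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(2, 6), st.integers(2, 6), st.integers(0, 10_000))
def test_median_polish_reconstruction_identity(nr, nc, seed):
    """overall + row + col + residual reproduces any input exactly."""
    x = np.random.default_rng(seed).normal(size=(nr, nc)) * 10
    dec = median_polish(x)
    assert np.allclose(dec.reconstruct(), x, atol=1e-9)


def test_median_polish_rejects_non_finite():
    with pytest.raises(ValueError):
        median_polish(np.array([[1.0, np.inf], [0.0, 1.0]]))


# ----------------------------------------------------- quantile normalization

def test_quantile_normalize_two_sample_example(make_matrix):
    m = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]).tolist(),
                    ["L6", "D3"])
    out = quantile_normalize(m)
    assert np.allclose(out.values.to_numpy(), [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])


def test_quantile_normalize_identical_samples_unchanged(make_matrix):
    v = [[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]]
    m = make_matrix(v, ["L6", "D3"])
    assert np.allclose(quantile_normalize(m).values.to_numpy(), v)


def test_quantile_normalize_equalizes_sorted_columns(make_matrix, rng):
    m = make_matrix(rng.normal(size=(50, 4)), ["L6", "L9", "D3", "D6"])
    out = quantile_normalize(m).values.to_numpy()
    sorted_cols = np.sort(out, axis=0)
    assert np.allclose(sorted_cols, sorted_cols[:, :1])
    assert np.allclose(out, quantile_normalize_oracle(m.values.to_numpy()))


def test_quantile_normalize_idempotent(make_matrix, rng):
    m = make_matrix(rng.normal(size=(30, 3)), ["L6", "D3", "2L3"])
    once = quantile_normalize(m)
    twice = quantile_normalize(once)
    assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())


def test_quantile_normalize_preserves_ranks(make_matrix, rng):
    m = make_matrix(rng.normal(size=(40, 3)), ["L6", "D3", "2L3"])
    out = quantile_normalize(m)
    for col in m.values.columns:
        assert (
            m.values[col].rank(method="first").to_numpy()
            == out.values[col].rank(method="first").to_numpy()
        ).all()


def test_quantile_normalize_single_sample_rejected(make_matrix):
    with pytest.raises(ValueError, match=">= 2 samples"):
        quantile_normalize(make_matrix([[1.0], [2.0]], ["L6"]))


# ------------------------------------------------------------- summarization

def _probe_map(gene_probes):
    rows = [(p, g) for g, probes in gene_probes.items() for p in probes]
    return ProbeMap(pd.DataFrame(rows, columns=["probe_id", "gene_id"]))


def test_identical_probe_rows_summarize_to_themselves(make_matrix):
    m = make_matrix([[5.0, 6.0, 7.0]] * 6, ["L6", "D3", "2L3"],
                    gene_ids=[f"p{i}" for i in range(6)])
    pmap = _probe_map({"g1": [f"p{i}" for i in range(6)]})
    out = summarize_genes(m, pmap)
    assert np.allclose(out.values.loc["g1"], [5.0, 6.0, 7.0])


def test_single_probe_gene_passes_through(make_matrix):
    m = make_matrix([[1.0, 2.0, 3.0]], ["L6", "D3", "2L3"], gene_ids=["p1"])
    out = summarize_genes(m, _probe_map({"g1": ["p1"]}))
    assert np.allclose(out.values.loc["g1"], [1.0, 2.0, 3.0])


def test_summarize_recovers_planted_course_up_to_constant(ucyna_timepoints):
    """With affinity offsets but no noise, the summarized gene course equals
    the planted cosinor course plus a gene-specific constant."""
    truth = make_truth(n_genes=6, periodic_fraction=0.5, background_fraction=0.0,
                       seed=4, noise_sd=0.0)
    probes, pmap, truth = simulate_probe_matrix(
        truth, ucyna_timepoints, probes_per_gene=6, probe_noise_sd=0.0,
        sample_scale_sd=0.0, sample_shift_sd=0.0, replicated_labels=(),
    )
    genes = summarize_genes(log2_transform(probes), pmap)
    hours = genes.hours
    for g in truth.genes.itertuples():
        planted = g.mesor + g.amplitude * np.cos(2 * np.pi * (hours - g.phase_hour) / 24)
        diff = genes.values.loc[g.Index].to_numpy() - planted
        assert np.allclose(diff, diff[0], atol=1e-8)


def test_summarize_invariant_to_probe_row_order(make_matrix, rng):
    v = rng.normal(size=(8, 4))
    ids = [f"p{i}" for i in range(8)]
    pmap = _probe_map({"g1": ids[:4], "g2": ids[4:]})
    labels = ["L6", "L9", "D3", "D6"]
    m1 = make_matrix(v, labels, gene_ids=ids)
    perm = rng.permutation(8)
    m2 = make_matrix(v[perm], labels, gene_ids=[ids[i] for i in perm])
    out1 = summarize_genes(m1, pmap)
    out2 = summarize_genes(m2, pmap)
    pd.testing.assert_frame_equal(out1.values, out2.values)


def test_unmapped_probe_warns_and_excluded(make_matrix):
    m = make_matrix([[1.0, 2.0], [3.0, 4.0]], ["L6", "D3"], gene_ids=["p1", "px"])
    with pytest.warns(UserWarning, match="1 probes"):
        out = summarize_genes(m, _probe_map({"g1": ["p1"]}))
    assert out.entity_ids == ["g1"]


# ------------------------------------------------------- replicate averaging

def test_average_replicates_mean(make_matrix):
    m = make_matrix([[4.0, 6.0, 5.0]], ["L6_1", "L6_2", "D3"])
    out = average_replicates(m)
    assert out.sample_ids == ["L6", "D3"]
    assert np.allclose(out.values.to_numpy(), [[5.0, 5.0]])


def test_average_replicates_identity_without_replicates(make_matrix, rng):
    m = make_matrix(rng.normal(size=(3, 3)), ["L6", "D3", "2L3"])
    out = average_replicates(m)
    assert np.allclose(out.values.to_numpy(), m.values.to_numpy())


def test_average_commutes_with_gene_subsetting(rng, make_matrix):
    m = make_matrix(rng.normal(size=(10, 4)), ["L6_1", "L6_2", "D3_1", "D3_2"])
    sub = [f"g{i}" for i in (1, 5, 7)]
    a = average_replicates(m.subset_entities(sub))
    b = average_replicates(m).subset_entities(sub)
    pd.testing.assert_frame_equal(a.values, b.values)


# ------------------------------------------------------------ scale handling

def test_log2_transform_floors_non_positive(make_matrix):
    m = make_matrix([[0.0, 8.0]], ["L6", "D3"], scale=Scale.LINEAR)
    out = log2_transform(m, floor=1.0)
    assert np.allclose(out.values.to_numpy(), [[0.0, 3.0]])
    assert out.scale is Scale.LOG2


def test_delog_inverts_log2(make_matrix, rng):
    m = make_matrix(rng.uniform(1, 100, size=(5, 2)), ["L6", "D3"], scale=Scale.LINEAR)
    back = delog(log2_transform(m))
    assert np.allclose(back.values.to_numpy(), m.values.to_numpy())


def test_preprocess_probes_quantile_equalizes_chips():
    """Per-sample distortions separate chip quantiles; normalization rejoins them."""
    bundle = ucyna_preset(n_genes=60, seed=9)
    raw_log2 = log2_transform(bundle.probe_matrix)
    raw_medians = raw_log2.values.median(axis=0)
    assert raw_medians.max() - raw_medians.min() > 0.1  # distortion visible
    normed = quantile_normalize(raw_log2)
    med = normed.values.median(axis=0)
    assert med.max() - med.min() < 1e-9
    genes = preprocess_probes(bundle.probe_matrix, bundle.probe_map)
    assert genes.scale is Scale.LOG2
    assert len(genes.entity_ids) == 60
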