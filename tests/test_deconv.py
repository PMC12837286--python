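"""Solver contracts: NNLS baseline, dampened weighted LS, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import deconvkit as dk
from deconvkit.deconv import DeconvolutionModel
from deconvkit.errors import ConfigurationError, DomainError
from deconvkit.evaluate import rmse_per_type


def random_signature(n_genes=60, n_types=4, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    v = rng.gamma(0.6, size=(n_genes, n_types)) * 100
    # a few strong markers per type keep the system well conditioned
    for t in range(n_types):
        v[t * 5:(t + 1) * 5, t] += 2000
    return pd.DataFrame(
        v, index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"T{t}" for t in range(n_types)],
    )


class TestNNLS:
    def test_noiseless_recovery(self):
        S = random_signature(n_types=2)
        f = np.array([0.3, 0.7])
        bulk = pd.DataFrame({"s1": S.to_numpy() @ f}, index=S.index)
        est = dk.nnls_deconvolve(S, bulk)
        assert np.allclose(est.values.iloc[0], f, atol=1e-6)

    def test_orthogonal_pure_sample(self):
        S = pd.DataFrame(
            {"a": [10.0, 0, 0, 0], "b": [0, 0, 8.0, 6.0]},
            index=["g1", "g2", "g3", "g4"],
        )
        bulk = pd.DataFrame({"s1": S["a"]})
        est = dk.nnls_deconvolve(S, bulk)
        assert np.allclose(est.values.iloc[0], [1.0, 0.0], atol=1e-9)

    def test_end_to_end_self_consistency(self, stock_reference, stock_signature):
        config = dk.SimulationConfig(
            scenario="random", n_samples=50, n_replicates=1,
            n_cells=10_000, depth=1e7, seed=1,
        )
        ds = dk.simulate_dataset(stock_reference, config)
        est = dk.nnls_deconvolve(stock_signature, ds.expression)
        report = dk.evaluate_fractions(ds.ground_truth, est.values)
        assert report.mean_rmse_s < 0.02

    def test_insufficient_gene_overlap_rejected(self):
        S = random_signature()
        bulk = pd.DataFrame({"s1": np.ones(3)}, index=["G000", "G001", "G002"])
        with pytest.raises(ConfigurationError, match="overlap"):
            DeconvolutionModel(S, bulk)


class TestDWLS:
    def test_noiseless_fixed_point(self):
        S = random_signature(seed=2)
        f = np.array([0.4, 0.3, 0.2, 0.1])
        bulk = pd.DataFrame({"s1": S.to_numpy() @ f}, index=S.index)
        est = dk.dwls_deconvolve(S, bulk)
        assert np.allclose(est.values.iloc[0], f, atol=1e-4)

    def test_equal_weights_reduce_to_nnls(self):
        """Construct S f* = const: fitted weights are flat, so the dampened
        iteration returns the plain NNLS solution."""
        rng = np.random.default_rng(4)
        raw = rng.gamma(1.0, size=(40, 3)) + 0.05
        f_star = np.array([0.5, 0.3, 0.2])
        scale = 100.0 / (raw @ f_star)
        S = pd.DataFrame(raw * scale[:, None],
                         index=[f"G{i:03d}" for i in range(40)],
                         columns=["a", "b", "c"])
        bulk = pd.DataFrame({"s1": S.to_numpy() @ f_star}, index=S.index)
        nnls = dk.nnls_deconvolve(S, bulk)
        dwls = dk.dwls_deconvolve(S, bulk)
        assert np.allclose(nnls.values, dwls.values, atol=1e-6)

    def test_rare_type_beats_nnls_under_noise(self, stock_signature):
        """The design goal of dampened weighting: better rare-type recovery."""
        S = stock_signature.values
        types = list(S.columns)
        rare = "Tregs"
        others = [t for t in types if t != rare]
        rows = []
        for i in range(50):
            rng = np.random.default_rng(100 + i)
            row = pd.Series(rng.dirichlet(np.ones(len(others))) * 0.98, index=others)
            row[rare] = 0.02
            rows.append(row[types])
        truth = pd.DataFrame(rows, index=[f"s{i}" for i in range(50)])
        clean = S.to_numpy() @ truth.to_numpy().T
        noise = np.random.default_rng(7).lognormal(0.0, 0.1, size=clean.shape)
        bulk = pd.DataFrame(clean * noise, index=S.index, columns=truth.index)
        est_nnls = dk.nnls_deconvolve(S, bulk)
        est_dwls = dk.dwls_deconvolve(S, bulk)
        rmse_nnls = rmse_per_type(truth[rare], est_nnls.values[rare])
        rmse_dwls = rmse_per_type(truth[rare], est_dwls.values[rare])
        assert rmse_dwls < rmse_nnls

    def test_nonconvergence_flagged_not_raised(self):
        S = random_signature(seed=5)
        rng = np.random.default_rng(6)
        bulk = pd.DataFrame({"s1": rng.gamma(1.0, size=len(S))}, index=S.index)
        res = DeconvolutionModel(S, bulk).fit("dwls", max_iter=1)
        assert "converged" in res.provenance  # flag present either way
        assert res.fractions.values.iloc[0].sum() == pytest.approx(1.0)


class TestSolverInvariances:
    @pytest.mark.parametrize("method", ["nnls", "dwls"])
    def test_permutation_equivariance(self, method):
        S = random_signature(seed=8)
        rng = np.random.default_rng(9)
        bulk = pd.DataFrame({"s1": S.to_numpy() @ rng.dirichlet(np.ones(4))}, index=S.index)
        base = DeconvolutionModel(S, bulk).fit(method).fractions.values
        perm = list(S.columns[::-1])
        permuted = DeconvolutionModel(S[perm], bulk).fit(method).fractions.values
        assert np.allclose(base[perm].to_numpy(), permuted.to_numpy(), atol=1e-8)

    @pytest.mark.parametrize("method", ["nnls", "dwls"])
    def test_bulk_scale_invariance(self, method):
        S = random_signature(seed=10)
        rng = np.random.default_rng(11)
        b = S.to_numpy() @ rng.dirichlet(np.ones(4)) + rng.gamma(0.5, size=len(S))
        bulk1 = pd.DataFrame({"s1": b}, index=S.index)
        bulk2 = pd.DataFrame({"s1": b * 37.5}, index=S.index)
        f1 = DeconvolutionModel(S, bulk1).fit(method).fractions.values
        f2 = DeconvolutionModel(S, bulk2).fit(method).fractions.values
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-8)

    def test_deterministic_given_inputs(self):
        S = random_signature(seed=12)
        rng = np.random.default_rng(13)
        bulk = pd.DataFrame(
            rng.gamma(1.0, size=(len(S), 3)) * 50, index=S.index,
            columns=["s1", "s2", "s3"],
        )
        a = dk.dwls_deconvolve(S, bulk)
        b = dk.dwls_deconvolve(S, bulk)
        assert a.values.equals(b.values)


class TestNormalizeFractions:
    def test_simple_and_idempotent(self):
        raw = pd.DataFrame([[2.0, 2.0]], index=["s"], columns=["a", "b"])
        out = dk.normalize_fractions(raw)
        assert np.allclose(out.values, [[0.5, 0.5]])
        again = dk.normalize_fractions(out.values)
        assert np.allclose(again.values, out.values)

    def test_scale_invariance(self):
        raw = pd.DataFrame([[0.1, 0.3, 0.6]], index=["s"], columns=list("abc"))
        out = dk.normalize_fractions(raw * 7)
        assert np.allclose(out.values, [[0.1, 0.3, 0.6]])

    def test_zero_row_named(self):
        raw = pd.DataFrame([[0.0, 0.0]], index=["bad_sample"], columns=["a", "b"])
        with pytest.raises(DomainError, match="bad_sample"):
            dk.normalize_fractions(raw)


class TestAggregateFractions:
    def test_identity_map(self):
        fm = dk.FractionMatrix(pd.DataFrame(
            [[0.2, 0.8], [0.6, 0.4]], index=["s1", "s2"], columns=["a", "b"]
        ))
        out = dk.aggregate_fractions(fm, {"a": "a", "b": "b"})
        assert out.values.equals(fm.values[sorted(fm.values.columns)])

    def test_t_cell_subsets_sum_into_parent(self):
        fm = dk.FractionMatrix(pd.DataFrame(
            [[0.1, 0.2, 0.05, 0.65]], index=["s"],
            columns=["CD4+ T", "CD8+ T", "Treg", "B"],
        ))
        mapping = {"CD4+ T": "T cells", "CD8+ T": "T cells", "Treg": "T cells", "B": "B"}
        out = dk.aggregate_fractions(fm, mapping)
        assert out.values.loc["s", "T cells"] == pytest.approx(0.35)
        assert out.values.loc["s", "B"] == pytest.approx(0.65)

    def test_unmapped_label_rejected(self):
        fm = dk.FractionMatrix(
            pd.DataFrame([[1.0]], index=["s"], columns=["orphan"]),
            sum_constrained=False,
        )
        with pytest.raises(ConfigurationError, match="orphan"):
            dk.aggregate_fractions(fm, {"some_other_type": "x"})

    @given(
        hnp.arrays(
            np.float64, (4, 5),
            elements=st.floats(0.001, 1.0, allow_nan=False),
        )
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_row_sums_preserved_and_commutes_with_normalization(self, raw):
        frame = pd.DataFrame(raw, index=[f"s{i}" for i in range(4)],
                             columns=list("abcde"))
        mapping = {"a": "x", "b": "x", "c": "y", "d": "y", "e": "y"}
        fm = dk.FractionMatrix(frame, sum_constrained=False)
        agg = dk.aggregate_fractions(fm, mapping)
        assert np.allclose(agg.values.sum(axis=1), frame.sum(axis=1), atol=1e-12)
        path1 = dk.aggregate_fractions(dk.normalize_fractions(frame), mapping).values
        path2 = dk.normalize_fractions(dk.aggregate_fractions(fm, mapping).values).values
        assert np.allclose(path1.to_numpy(), path2.to_numpy(), atol=1e-12)
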