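"""Metrics against brute-force oracles, and the benchmark experiments."""

import numpy as np
import pandas as pd
import pytest

import deconvkit as dk
from deconvkit.errors import ConfigurationError
from deconvkit.evaluate import (
    mae_per_type,
    mape_per_type,
    pearson_r,
    rmse_per_sample,
    rmse_per_type,
)

from conftest import make_orthogonal_reference


def random_pair(rng, n_samples=5, n_types=4):
    truth = rng.dirichlet(np.ones(n_types), size=n_samples)
    est = np.clip(truth + rng.normal(0, 0.1, size=truth.shape), 0, None)
    idx = [f"s{i}" for i in range(n_samples)]
    cols = [f"t{j}" for j in range(n_types)]
    return (pd.DataFrame(truth, index=idx, columns=cols),
            pd.DataFrame(est, index=idx, columns=cols))


class TestPearson:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        truth, _ = random_pair(rng)
        r, ok = pearson_r(truth, truth, "global")
        assert ok and r == pytest.approx(1.0)
        per_type = pearson_r(truth, truth, "per_type")
        assert np.allclose(per_type, 1.0)

    def test_complement_anticorrelated(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.1, 0.9, size=6)
        truth = pd.DataFrame({"x": a, "y": 1 - a}, index=[f"s{i}" for i in range(6)])
        est = truth[["y", "x"]].rename(columns={"y": "x", "x": "y"})
        per_type = pearson_r(truth, est, "per_type")
        assert np.allclose(per_type, -1.0)

    def test_all_zero_estimate_flagged_undefined(self):
        rng = np.random.default_rng(2)
        truth, est = random_pair(rng)
        est["t0"] = 0.0  # a cell type never detected
        per_type = pearson_r(truth, est, "per_type")
        assert "t0" in per_type.attrs["undefined"]
        assert np.isnan(per_type["t0"])

    def test_label_mismatch_lists_difference(self):
        rng = np.random.default_rng(3)
        truth, est = random_pair(rng)
        est = est.rename(columns={"t0": "zz"})
        with pytest.raises(ConfigurationError, match="zz"):
            pearson_r(truth, est, "global")


class TestErrorMetrics:
    def test_rmse_hand_values(self):
        assert rmse_per_sample([0.5, 0.5], [0.3, 0.7]) == pytest.approx(0.2)
        assert rmse_per_sample([1, 0], [0, 1]) == pytest.approx(1.0)
        assert rmse_per_sample([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_mae_mape_hand_values(self):
        assert mae_per_type([0.2, 0.4], [0.1, 0.5]) == pytest.approx(0.1)
        mape, excluded = mape_per_type([0.2, 0.4], [0.1, 0.5])
        assert mape == pytest.approx(0.375)
        assert excluded == 0

    def test_mape_excludes_zero_truth(self):
        mape, excluded = mape_per_type([0.0, 0.5], [0.3, 0.5])
        assert mape == 0.0 and excluded == 1
        mape, excluded = mape_per_type([0.0, 0.0], [0.3, 0.5])
        assert np.isnan(mape) and excluded == 2

    def test_oracle_equivalence_on_random_pairs(self):
        """All metrics agree with naive loop recomputation to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            truth, est = random_pair(rng)
            report = dk.evaluate_fractions(truth, est)
            t, e = truth.to_numpy(), est.to_numpy()
            S, C = t.shape
            # brute-force recomputation from the printed definitions
            for si, s in enumerate(truth.index):
                rmse = np.sqrt(sum((t[si, c] - e[si, c]) ** 2 for c in range(C)) / C)
                assert abs(report.rmse_s[s] - rmse) < 1e-10
            for ci, c in enumerate(truth.columns):
                rmse = np.sqrt(sum((t[s, ci] - e[s, ci]) ** 2 for s in range(S)) / S)
                mae = sum(abs(t[s, ci] - e[s, ci]) for s in range(S)) / S
                assert abs(report.rmse_c[c] - rmse) < 1e-10
                assert abs(report.mae_c[c] - mae) < 1e-10
                nz = [s for s in range(S) if t[s, ci] > 0]
                mape = sum(abs((t[s, ci] - e[s, ci]) / t[s, ci]) for s in nz) / len(nz)
                assert abs(report.mape_c[c] - mape) < 1e-10
                r = np.corrcoef(t[:, ci], e[:, ci])[0, 1]
                assert abs(report.per_type_pearson[c] - r) < 1e-10
            r_global = np.corrcoef(t.ravel(), e.ravel())[0, 1]
            assert abs(report.global_pearson - r_global) < 1e-10


class TestDeltaRmseBias:
    def test_identical_reports_give_zero(self):
        rng = np.random.default_rng(5)
        truth, est = random_pair(rng)
        rep = dk.evaluate_fractions(truth, est, provenance={"seed": 1})
        delta = dk.delta_rmse_bias(rep, rep)
        assert np.allclose(delta, 0.0)

    def test_unpaired_seeds_rejected(self):
        rng = np.random.default_rng(6)
        truth, est = random_pair(rng)
        a = dk.evaluate_fractions(truth, est, provenance={"seed": 1})
        b = dk.evaluate_fractions(truth, est, provenance={"seed": 2})
        with pytest.raises(ConfigurationError, match="unpaired"):
            dk.delta_rmse_bias(a, b)

    def test_uncorrected_bias_inflates_high_content_type(self, stock_reference):
        """2x expressed-genes spread + plain CPM signature: the high-content
        type's RMSE rises when bias is switched on."""
        sig = dk.make_signature(stock_reference)
        with_bias, without = dk.paired_bias_datasets(
            stock_reference, n_samples=15, n_cells=3000, seed=11
        )
        rep_b = dk.evaluate_fractions(
            with_bias.ground_truth,
            dk.nnls_deconvolve(sig, with_bias.expression).values,
            provenance={"seed": 11},
        )
        rep_n = dk.evaluate_fractions(
            without.ground_truth,
            dk.nnls_deconvolve(sig, without.expression).values,
            provenance={"seed": 11},
        )
        delta = dk.delta_rmse_bias(rep_b, rep_n)
        assert delta["Monocytes"] > 0  # the high-mRNA-content type

    def test_mrna_rescaled_signature_shrinks_delta(self, stock_reference):
        """Scaling signature columns by per-type mRNA content corrects most
        of the bias-induced error."""
        sig = dk.make_signature(stock_reference)
        content = pd.Series(stock_reference.genes_per_cell()).groupby(
            stock_reference.obs["fine"].to_numpy()
        ).mean()
        rescaled = dk.SignatureMatrix(
            sig.values * (content[sig.values.columns] / content.mean())
        )
        with_bias, _ = dk.paired_bias_datasets(
            stock_reference, n_samples=15, n_cells=3000, seed=11
        )
        plain = dk.evaluate_fractions(
            with_bias.ground_truth,
            dk.nnls_deconvolve(sig, with_bias.expression).values,
        )
        corrected = dk.evaluate_fractions(
            with_bias.ground_truth,
            dk.nnls_deconvolve(rescaled, with_bias.expression).values,
        )
        assert corrected.rmse_c["Monocytes"] < plain.rmse_c["Monocytes"]


class TestSpillover:
    def test_rows_compositional_and_orthogonal_fixture_clean(self, orthogonal_reference):
        report = dk.spillover_experiment(
            orthogonal_reference, n_reps=10, n_cells=200, seed=0
        )
        assert np.allclose(report.matrix.sum(axis=1), 100.0, atol=1e-6)
        assert report.total_spillover < 1.0
        assert (report.correct > 99.0).all()

    def test_similar_pair_concentrates_spill(self, similar_pair_reference):
        report = dk.spillover_experiment(
            similar_pair_reference, n_reps=10, n_cells=300, seed=1
        )
        spill_a = report.spill("twinA")
        assert spill_a["twinB"] > spill_a["distinct"]
        spill_b = report.spill("twinB")
        assert spill_b["twinA"] > spill_b["distinct"]

    def test_missing_type_in_training_reference_rejected(
        self, orthogonal_reference
    ):
        train = orthogonal_reference.drop_cell_types(["type1"])
        with pytest.raises(ConfigurationError, match="type1"):
            dk.spillover_experiment(orthogonal_reference, train, seed=0)


@pytest.fixture(scope="module")
def unknown_result(stock_reference):
    return dk.unknown_content_experiment(
        stock_reference,
        known_types=["B cells", "NK cells", "T CD4", "T CD8"],
        spike_type="Monocytes",
        levels=(0.0, 0.5),
        n_replicates=2,
        n_samples=5,
        n_cells=2000,
        seed=4,
    )


@pytest.fixture(scope="module")
def granularity_result(stock_reference):
    return dk.granularity_experiment(
        stock_reference, n_replicates=2, n_samples=5, n_cells=2000, seed=6
    )


class TestUnknownContent:
    def test_level_zero_reduces_to_plain_run(self, unknown_result):
        report = unknown_result["per_level"][0.0]["raw"]
        assert report.global_pearson >= 0.95

    def test_sum_constraint_inflates_estimates(self, unknown_result):
        """Estimates sum to 1 although true known-type mass is 1 - level."""
        level = unknown_result["per_level"][0.5]
        est_sums = level["estimates"].values.sum(axis=1)
        truth_sums = level["truth"].sum(axis=1)
        assert np.allclose(est_sums, 1.0, atol=1e-9)
        assert np.allclose(truth_sums, 0.5, atol=1e-9)

    def test_paper_protocol_sample_count(self, stock_reference):
        out = dk.unknown_content_experiment(
            stock_reference,
            known_types=["B cells", "NK cells", "T CD4", "T CD8"],
            spike_type="Monocytes",
            n_replicates=5, n_samples=10, n_cells=1000, seed=2,
        )
        assert out["n_samples_total"] == 450

    def test_spike_in_known_types_rejected(self, stock_reference):
        with pytest.raises(ConfigurationError):
            dk.unknown_content_experiment(
                stock_reference, known_types=["B cells"], spike_type="B cells", seed=0
            )


class TestGranularity:
    def test_aggregated_truth_matches_direct_coarse_truth(self, granularity_result, stock_reference):
        ds = granularity_result["dataset"]
        mapping = stock_reference.hierarchy_map("fine", "coarse")
        agg = dk.aggregate_fractions(dk.FractionMatrix(ds.ground_truth), mapping)
        props = stock_reference.proportions("coarse")
        assert np.allclose(agg.values[props.index], props.to_numpy(), atol=1 / 2000)

    def test_mirror_db_rows_identical(self, granularity_result):
        assert (granularity_result["dataset"].ground_truth.nunique() == 1).all()

    def test_noise_split_fine_types_aggregate_at_least_as_well(self):
        """Fine types that are copies of one another: aggregating their
        estimates cannot do worse than deconvolving the coarse parent of a
        matched run."""
        spec = dict(n_cells=120, expressed_gene_target=500,
                    mean_library_size=4000.0, n_markers=0)
        specs = [
            dk.CellTypeSpec("copy1", parent_normal="parent", parent_coarse="parent", **spec),
            dk.CellTypeSpec("copy2", parent_normal="parent", parent_coarse="parent", **spec),
            dk.CellTypeSpec("other", 120, 700, 5000.0, n_markers=25,
                            parent_normal="other", parent_coarse="other"),
        ]
        ref = dk.generate_reference(specs, n_genes=1500, seed=5)
        out = dk.granularity_experiment(ref, n_replicates=2, n_samples=5,
                                        n_cells=2000, seed=5)
        agg_rmse = out["aggregated_coarse"].rmse_c["parent"]
        fine_rmse = max(out["reports"]["fine"].rmse_c["copy1"],
                        out["reports"]["fine"].rmse_c["copy2"])
        assert agg_rmse <= fine_rmse + 1e-9


class TestLeaveOneOut:
    def test_removing_absent_type_changes_nothing(self):
        ref = make_orthogonal_reference(n_types=4, seed=3)
        # bulk contains only types 1-3; type4 is absent (truth zero)
        config = dk.SimulationConfig(
            scenario="mirror_fractions",
            target_fractions=pd.DataFrame(
                {"type1": [0.5], "type2": [0.3], "type3": [0.2]}
            ),
            n_replicates=5, n_cells=500, depth=1e6, seed=0,
        )
        ds = dk.simulate_dataset(ref, config)
        delta = dk.leave_one_out_experiment(ref, "nnls", ds, seed=0)
        assert delta.loc["type4"].abs().max() < 0.01

    def test_similar_type_absorbs_removed_mass(self, similar_pair_reference):
        config = dk.SimulationConfig(
            scenario="random", n_samples=10, n_replicates=1,
            n_cells=1000, depth=1e6, seed=4,
        )
        ds = dk.simulate_dataset(similar_pair_reference, config)
        delta = dk.leave_one_out_experiment(similar_pair_reference, "nnls", ds, seed=4)
        assert delta.loc["twinA", "twinB"] > 0

    def test_too_few_types_rejected(self):
        ref = make_orthogonal_reference(n_types=2, seed=0)
        config = dk.SimulationConfig(
            scenario="mirror_db", n_samples=1, n_replicates=1, n_cells=100, seed=0
        )
        ds = dk.simulate_dataset(ref, config)
        with pytest.raises(ConfigurationError, match="3"):
            dk.leave_one_out_experiment(ref, "nnls", ds, seed=0)
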