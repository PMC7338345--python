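import numpy as np
import pytest

from taguchi_biocat.anova import anova_snr, auto_pool, factor_ss, total_ss
from taguchi_biocat.design import build_l9
from taguchi_biocat.errors import (
    InvalidParameterError,
    InvalidSelectionError,
    NoResidualError,
)
from taguchi_biocat.simulate import study_like_model, simulate_doe
from taguchi_biocat.snr import compute_snr


@pytest.fixture
def study_values(study_snr):
    return np.array([r.snr for r in study_snr])


class TestFactorSS:
    @pytest.mark.parametrize(
        "factor,printed",
        [
            ("Temperature", 59.5),
            ("Time", 20.5),
            ("Molar ratio", 147.2),
            ("Biocatalyst", 453.9),
        ],
    )
    def test_study_ss_within_1pc(self, l9, study_values, factor, printed):
        assert factor_ss(l9, study_values, factor) == pytest.approx(printed, rel=0.01)

    def test_constant_snr_gives_zero(self, l9):
        for f in l9.factor_names:
            assert factor_ss(l9, [12.0] * 9, f) == pytest.approx(0.0, abs=1e-12)

    def test_saturated_decomposition_to_total(self, l9, study_values):
        """Brute-force oracle: sum of four factor SS equals total SS (L9 is saturated)."""
        total = float(((study_values - study_values.mean()) ** 2).sum())
        parts = sum(factor_ss(l9, study_values, f) for f in l9.factor_names)
        assert parts == pytest.approx(total, rel=1e-9)
        assert total_ss(l9, study_values) == pytest.approx(total, rel=1e-12)

    def test_unknown_factor_rejected(self, l9, study_values):
        with pytest.raises(InvalidSelectionError):
            factor_ss(l9, study_values, "Pressure")


class TestAutoPool:
    def test_study_pools_time(self, l9, study_values):
        """Time has the smallest SS of the four factors and is pooled."""
        assert auto_pool(l9, study_values) == ("Time",)

    def test_explicit_returns_unchanged(self, l9, study_values):
        assert auto_pool(l9, study_values, "explicit", ["Biocatalyst"]) == ("Biocatalyst",)

    def test_planted_smallest_factor_pooled(self, l9):
        model = study_like_model(noise_sd=0.0)
        responses = simulate_doe(model, l9)
        records = compute_snr(responses)
        # Time has the smallest planted offsets, hence the smallest SS
        assert auto_pool(l9, records) == ("Time",)

    def test_single_factor_design_pools_nothing(self):
        from taguchi_biocat.design import OrthogonalArray

        arr = OrthogonalArray(np.array([[1], [2], [3], [1], [2], [3], [1], [2], [3]]))
        assert auto_pool(arr, list(range(9))) == ()


class TestAnovaTable:
    def test_study_table_matches_printed_values(self, l9, study_values):
        """Pooling Time reproduces the published F, p and contribution columns."""
        table = anova_snr(l9, study_values, pooled_factors=["Time"])
        assert table.row("Biocatalyst")["contribution"] == pytest.approx(66.6, abs=0.2)
        assert table.row("Temperature")["contribution"] == pytest.approx(8.7, abs=0.2)
        assert table.row("Time")["contribution"] == pytest.approx(3.0, abs=0.2)
        assert table.row("Molar ratio")["contribution"] == pytest.approx(21.6, abs=0.2)
        assert table.row("Temperature")["f_value"] == pytest.approx(2.9, abs=0.3)
        assert table.row("Molar ratio")["f_value"] == pytest.approx(7.2, abs=0.3)
        assert table.row("Biocatalyst")["f_value"] == pytest.approx(22.1, abs=0.3)
        # residual = pooled Time: MS ~ 10.2 with 2 df
        resid = table.row("Residual")
        assert resid["df"] == 2
        assert resid["ms"] == pytest.approx(10.2, abs=0.1)
        # only the biocatalyst content is significant at alpha = 0.05
        sig = table.rows.set_index("source")["significant"]
        assert sig["Biocatalyst"] and not sig["Temperature"] and not sig["Molar ratio"]

    def test_p_values_match_analytic_f22_oracle(self, l9, study_values):
        """For (2,2) df the F survival function is exactly 1/(1+F)."""
        table = anova_snr(l9, study_values, pooled_factors=["Time"])
        for f in ("Temperature", "Molar ratio", "Biocatalyst"):
            row = table.row(f)
            assert row["p_value"] == pytest.approx(1.0 / (1.0 + row["f_value"]), abs=1e-9)

    def test_contributions_sum_to_100(self, l9, study_values):
        table = anova_snr(l9, study_values, pooled_factors=["Time"])
        contrib = table.rows.set_index("source")["contribution"]
        assert contrib[list(l9.factor_names)].sum() == pytest.approx(100.0, abs=0.05)

    def test_shift_invariance(self, l9, study_values):
        """Adding a constant to all S/N leaves SS, F and p unchanged."""
        base = anova_snr(l9, study_values, ["Time"])
        shifted = anova_snr(l9, study_values + 13.5, ["Time"])
        for col in ("ss", "f_value", "p_value", "contribution"):
            np.testing.assert_allclose(
                base.rows[col].to_numpy(dtype=float),
                shifted.rows[col].to_numpy(dtype=float),
                rtol=1e-9,
                atol=1e-9,
            )

    def test_run_permutation_invariance(self, l9, study_values):
        perm = np.array([4, 2, 8, 0, 6, 1, 7, 3, 5])
        from taguchi_biocat.design import OrthogonalArray

        arr_p = OrthogonalArray(l9.cells[perm], l9.factor_names)
        base = anova_snr(l9, study_values, ["Time"])
        permuted = anova_snr(arr_p, study_values[perm], ["Time"])
        for col in ("ss", "f_value", "p_value", "contribution"):
            np.testing.assert_allclose(
                base.rows[col].to_numpy(dtype=float),
                permuted.rows[col].to_numpy(dtype=float),
                rtol=1e-9,
                atol=1e-9,
            )

    def test_saturated_design_requires_pooling(self, l9, study_values):
        with pytest.raises(NoResidualError):
            anova_snr(l9, study_values, pooled_factors=[])

    def test_alpha_bounds(self, l9, study_values):
        with pytest.raises(InvalidParameterError):
            anova_snr(l9, study_values, ["Time"], alpha=1.5)

    def test_constant_snr_degenerate(self, l9):
        table = anova_snr(l9, [12.0] * 9, ["Time"])
        assert table.degenerate
        assert table.rows.set_index("source").loc["Biocatalyst", ["f_value", "p_value", "contribution"]].isna().all()


class TestPlantedEffectRecovery:
    def test_contribution_ordering_matches_planted_ordering(self, l9):
        """Planted Biocatalyst > Ratio > Temperature > Time ordering is recovered
        as the ANOVA contribution ordering in >= 95% of 200 seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            model = study_like_model(noise_sd=1.0, seed=seed)
            records = compute_snr(simulate_doe(model, l9))
            ss = {f: factor_ss(l9, records, f) for f in l9.factor_names}
            order = sorted(ss, key=ss.get, reverse=True)
            hits += order == ["Biocatalyst", "Molar ratio", "Temperature", "Time"]
        assert hits >= 0.95 * n_seeds

    def test_dominant_factor_rank1(self, l9):
        """With noise far below the biocatalyst effect, it always ranks first."""
        for seed in range(50):
            model = study_like_model(noise_sd=0.5, seed=seed)
            records = compute_snr(simulate_doe(model, l9))
            table = anova_snr(l9, records, auto_pool(l9, records))
            contrib = table.rows.set_index("source")["contribution"]
            assert contrib[list(l9.factor_names)].idxmax() == "Biocatalyst"
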