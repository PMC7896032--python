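"""Size-number fits: closed-form cases, OLS oracle equality, analytic limits."""
import numpy as np
import pytest

import padcyto as pc
from padcyto.types import CellPADSummary

from tests.conftest import make_pad


def normal_equations(x, y):
    """Independent OLS oracle: solve X'X b = X'y explicitly."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    return beta, r2


def cell(n, mean_area):
    return CellPADSummary(
        nucleus_id=0, n_pads=n, mean_area_um2=mean_area,
        total_area_um2=n * mean_area, sqrt_mean_area=float(np.sqrt(mean_area)),
    )


class TestReciprocalSqrt:
    def test_exact_line_recovered(self):
        cells = [cell(n, (0.2 * n) ** -2) for n in range(2, 10)]
        # 1/n = 0.2 * sqrt(a)  <=>  sqrt(a) = 5/n
        fit = pc.fit_reciprocal_sqrt(cells)
        assert fit.slope == pytest.approx(0.2, rel=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response_gives_zero_slope(self):
        cells = [cell(4, a) for a in (1.0, 2.0, 3.0, 4.0)]
        fit = pc.fit_reciprocal_sqrt(cells)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_zero_variance_predictor_rejected(self):
        cells = [cell(n, 2.0) for n in (2, 3, 4)]
        with pytest.raises(ValueError):
            pc.fit_reciprocal_sqrt(cells)

    def test_conserved_cohort_matches_oracle(self):
        params = pc.PopulationParams(n_cells=200, total_pad_area=16.0, area_cv=0.0,
                                     count_law=(4, 32), seed=9)
        truth = pc.sample_population_truth(params)
        cells = [cell(c.n_pads, c.pad_areas_um2.mean()) for c in truth.cells]
        fit = pc.fit_reciprocal_sqrt(cells)
        x = np.array([c.sqrt_mean_area for c in cells])
        y = np.array([1.0 / c.n_pads for c in cells])
        (b0, b1), r2 = normal_equations(x, y)
        assert fit.slope == pytest.approx(b1, abs=1e-10)
        assert fit.intercept == pytest.approx(b0, abs=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)
        assert fit.slope > 0


class TestPowerLaw:
    def test_exact_inverse_law(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        fit = pc.fit_power_law(x, 5.0 / x)
        assert fit.exponent == pytest.approx(-1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_counts_give_zero_exponent(self):
        fit = pc.fit_power_law(np.array([1, 2, 3, 4.0]), np.full(4, 7.0))
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_exponent_invariant_under_positive_rescaling(self, rng):
        x = rng.uniform(0.5, 8.0, 50)
        y = 3.0 * x ** -1.2 * rng.lognormal(0, 0.1, 50)
        base = pc.fit_power_law(x, y).exponent
        assert pc.fit_power_law(4.2 * x, y).exponent == pytest.approx(base, abs=1e-10)
        assert pc.fit_power_law(x, 0.3 * y).exponent == pytest.approx(base, abs=1e-10)

    def test_nonpositive_points_excluded(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([3.0, 5.0, 2.5, 1.25])
        fit = pc.fit_power_law(x, y)
        assert fit.n_excluded == 1 and fit.n_points == 3

    def test_too_few_survivors_rejected(self):
        with pytest.raises(ValueError):
            pc.fit_power_law(np.array([0, 0, 1.0]), np.array([1, 1, 1.0]))


class TestExponentialFit:
    def test_exponential_sample_rate_recovered(self, rng):
        areas = rng.exponential(scale=0.5, size=5000)  # rate 2
        fit = pc.fit_exponential(areas)
        assert fit.slope == pytest.approx(-2.0, abs=0.2)

    def test_geometric_bin_counts_fit_perfectly(self):
        centers = 0.15 + 0.3 * np.arange(10)
        areas = np.concatenate(
            [np.full(2 ** (10 - k), c) for k, c in enumerate(centers)]
        )
        fit = pc.fit_exponential(areas)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope < 0

    def test_degenerate_single_bin_rejected(self):
        with pytest.raises(ValueError):
            pc.fit_exponential(np.full(100, 1.0))

    def test_matches_oracle_on_binned_counts(self, rng):
        areas = rng.exponential(scale=1.0, size=2000)
        fit = pc.fit_exponential(areas, n_bins=15)
        counts, edges = np.histogram(areas[(areas > 0) & (areas <= 6.0)],
                                     bins=15, range=(0, 6.0))
        centers = 0.5 * (edges[:-1] + edges[1:])
        nz = counts > 0
        (b0, b1), r2 = normal_equations(centers[nz], np.log(counts[nz]))
        assert fit.slope == pytest.approx(b1, abs=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)


class TestCentromereClustering:
    def test_exact_linear_relation(self):
        pads = [make_pad(a, centromere_count=int(2 * a), pad_id=i)
                for i, a in enumerate(range(1, 13))]
        linear, exponential = pc.fit_centromere_clustering(pads)
        assert linear.slope == pytest.approx(2.0, rel=1e-9)
        assert linear.r2 == pytest.approx(1.0)
        assert not exponential.degenerate

    def test_density_recovered_from_simulated_pads(self):
        params = pc.PopulationParams(n_cells=60, centromere_density=1.0,
                                     count_law=(6, 12), seed=13)
        truth = pc.sample_population_truth(params)
        pads = [
            make_pad(a, centromere_count=c, pad_id=i)
            for i, (a, c) in enumerate(
                (a, c)
                for cell in truth.cells
                for a, c in zip(cell.pad_areas_um2, cell.centromere_counts)
            )
        ]
        assert len(pads) >= 500
        linear, _ = pc.fit_centromere_clustering(pads)
        assert linear.slope == pytest.approx(1.0, rel=0.15)

    def test_uniform_counts_flag_degenerate_exponential(self):
        pads = [make_pad(a, centromere_count=1, pad_id=i)
                for i, a in enumerate(np.linspace(0.5, 8, 15))]
        linear, exponential = pc.fit_centromere_clustering(pads)
        assert exponential.degenerate
        assert linear.slope == pytest.approx(0.0, abs=1e-12)


class TestCompareConditions:
    def _cohort(self, ns, areas):
        return [cell(n, a) for n, a in zip(ns, areas)]

    def test_unravelled_cohort_has_smaller_median(self):
        ctrl_params = pc.PopulationParams(n_cells=80, count_law=(6, 16), seed=21)
        trt_params = pc.PopulationParams(n_cells=80, count_law=(18, 32), seed=22)
        def cells(params):
            # frankly preapoptotic cells (aggregated giant PADs) are excluded
            # from cohort comparisons, as in the imaging analysis itself
            truth = pc.sample_population_truth(params)
            return [cell(c.n_pads, c.pad_areas_um2.mean()) for c in truth.cells
                    if c.dna_class != "preapoptotic"]
        report = pc.compare_conditions(cells(ctrl_params), cells(trt_params))
        assert report.treated_median_area < report.control_median_area
        assert report.p_value < 0.001

    def test_identical_cohorts_not_different(self):
        cohort = self._cohort([4, 5, 6, 8], [4.0, 3.2, 2.7, 2.0])
        report = pc.compare_conditions(cohort, cohort)
        assert report.p_value == pytest.approx(1.0)

    def test_scale_free_control_fits_better_than_fixed_size(self, rng):
        ctrl = self._cohort(range(2, 42), 16.0 / np.arange(2, 42))
        sizes = 1.0 + 0.05 * rng.standard_normal(40)  # fixed-size PADs
        trt = self._cohort(rng.integers(15, 30, 40), sizes)
        report = pc.compare_conditions(ctrl, trt)
        assert report.control_fit.r2 > report.treated_fit.r2
        assert report.r2_drop > 0.3


class TestR2Properties:
    def test_permuting_response_destroys_fit(self, rng):
        x = np.linspace(1, 10, 100)
        y = 2.0 * x + 1.0
        r2s = []
        for _ in range(60):
            perm = rng.permutation(y)
            if np.ptp(perm) == 0:
                continue
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.lstsq(X, perm, rcond=None)[0]
            resid = perm - X @ beta
            r2s.append(1 - resid @ resid / ((perm - perm.mean()) @ (perm - perm.mean())))
        assert np.median(r2s) < 0.05
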