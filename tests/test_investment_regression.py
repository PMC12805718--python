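"""Investment aggregation and power-law ML regression."""

import numpy as np
import pandas as pd
import pytest

from phagedefense.investment_regression import (
    DefenseSystemMap,
    GenomeRecord,
    compare_bic,
    compute_investment,
    fit_power_law,
    predictive_band,
)


@pytest.fixture
def smap():
    return DefenseSystemMap({"TA": "PCD", "Abi": "PCD", "RM": "immunity",
                             "CRISPR-Cas": "immunity", "Wadjet": "undefined"})


def _records_from_curve(n, alpha, beta, gamma, rng, mu=-4.6, sd=0.8):
    log_imm = rng.normal(mu, sd, n)
    log_pcd = np.log(beta) + alpha * log_imm + rng.normal(0, gamma, n)
    recs = []
    L = 10_000_000
    for i, (li, lp) in enumerate(zip(log_imm, log_pcd)):
        recs.append(GenomeRecord(species_id=f"s{i}", genome_length=L,
                                 pcd_nt=int(np.exp(lp) * L),
                                 imm_nt=int(np.exp(li) * L)))
    return recs


class TestComputeInvestment:
    def test_direct_ratio(self, smap):
        genes = pd.DataFrame({
            "system_name": ["TA", "RM", "RM"],
            "gene_length": [10_000, 12_000, 13_000]})
        rec = compute_investment(genes, smap, genome_length=1_000_000)
        assert rec.I_PCD == pytest.approx(0.01)
        assert rec.I_Imm == pytest.approx(0.025)

    def test_overlapping_genes_counted_once_with_coordinates(self, smap):
        genes = pd.DataFrame({
            "system_name": ["TA", "TA"],
            "contig": ["c1", "c1"],
            "start": [1000, 1700],
            "end": [2000, 2700]})
        rec = compute_investment(genes, smap, genome_length=100_000)
        assert rec.pcd_nt == 1700  # union of [1000,2000) and [1700,2700)

    def test_no_defense_genes_gives_zero(self, smap):
        genes = pd.DataFrame({"system_name": [], "gene_length": []})
        rec = compute_investment(genes, smap, genome_length=5_000_000)
        assert rec.I_PCD == 0.0 and rec.I_Imm == 0.0

    def test_undefined_and_unknown_systems_excluded(self, smap):
        genes = pd.DataFrame({
            "system_name": ["Wadjet", "NeverHeardOfIt", "TA"],
            "gene_length": [5000, 5000, 1000]})
        with pytest.warns(UserWarning, match="NeverHeardOfIt"):
            rec = compute_investment(genes, smap, genome_length=1_000_000)
        assert rec.pcd_nt == 1000
        assert rec.imm_nt == 0


class TestFitPowerLaw:
    def test_noiseless_data_recovered_exactly(self, rng):
        recs = _records_from_curve(50, 0.7, 0.2, 0.0, rng)
        fit = fit_power_law(recs)
        assert fit.alpha == pytest.approx(0.7, abs=1e-4)
        assert fit.beta == pytest.approx(0.2, rel=1e-3)

    def test_ml_equals_log_log_least_squares(self, rng):
        """Free-alpha ML and the closed-form OLS solution coincide."""
        recs = _records_from_curve(200, 0.5, 0.1, 0.4, rng)
        fit = fit_power_law(recs)
        x = np.log([r.I_Imm for r in recs])
        y = np.log([r.I_PCD for r in recs])
        X = np.vstack([x, np.ones_like(x)]).T
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.alpha == pytest.approx(coef[0], abs=1e-10)
        assert np.log(fit.beta) == pytest.approx(coef[1], abs=1e-10)

    def test_scale_equivariance(self, rng):
        recs = _records_from_curve(100, 0.6, 0.05, 0.3, rng)
        fit = fit_power_law(recs)
        c = 3.0
        scaled = [GenomeRecord(r.species_id, r.genome_length,
                               pcd_nt=r.pcd_nt, imm_nt=int(r.imm_nt * c))
                  for r in recs]
        fit2 = fit_power_law(scaled)
        # imm_nt rounding limits the match, not the estimator
        assert fit2.alpha == pytest.approx(fit.alpha, abs=1e-4)
        assert np.log(fit2.beta) == pytest.approx(
            np.log(fit.beta) - fit.alpha * np.log(c), abs=1e-3)

    def test_fixed_alpha_closed_form(self, rng):
        recs = _records_from_curve(100, 0.6, 0.05, 0.3, rng)
        fit = fit_power_law(recs, fixed_alpha=1.0)
        x = np.log([r.I_Imm for r in recs])
        y = np.log([r.I_PCD for r in recs])
        assert np.log(fit.beta) == pytest.approx(np.mean(y - x), abs=1e-12)
        assert fit.alpha_fixed
        assert fit.k_params == 2

    def test_zero_investment_records_excluded(self, rng):
        recs = _records_from_curve(20, 0.6, 0.05, 0.3, rng)
        recs.append(GenomeRecord("z", 1_000_000, pcd_nt=0, imm_nt=100))
        fit = fit_power_law(recs)
        assert fit.n == 20
        assert fit.n_excluded_zero == 1

    def test_degenerate_predictor_rejected(self):
        recs = [GenomeRecord(f"s{i}", 1_000_000, pcd_nt=100 + i, imm_nt=500)
                for i in range(5)]
        with pytest.raises(ValueError, match="unidentifiable|rank"):
            fit_power_law(recs)


class TestCompareBic:
    def test_identical_loglik_gives_pure_penalty_difference(self, rng):
        recs = _records_from_curve(100, 1.0, 0.05, 0.3, rng)
        free = fit_power_law(recs)
        # fixing alpha at the ML estimate leaves the fit unchanged
        fixed = fit_power_law(recs, fixed_alpha=free.alpha)
        assert fixed.loglik == pytest.approx(free.loglik, abs=1e-9)
        table = compare_bic(free, fixed)
        assert table.delta_bic[1] == pytest.approx(-np.log(free.n), abs=1e-9)

    def test_free_fit_has_zero_delta_to_itself(self, rng):
        recs = _records_from_curve(50, 0.6, 0.05, 0.3, rng)
        free = fit_power_law(recs)
        table = compare_bic(free)
        assert table.delta_bic[0] == 0.0

    def test_mismatched_subsets_rejected(self, rng):
        recs = _records_from_curve(50, 0.6, 0.05, 0.3, rng)
        free = fit_power_law(recs)
        other = fit_power_law(recs[:40], fixed_alpha=1.0)
        with pytest.raises(ValueError):
            compare_bic(free, other)

    def test_wrong_models_strongly_rejected_on_sublinear_truth(self, rng):
        recs = _records_from_curve(2000, 0.554, 0.05, 0.8, rng)
        free = fit_power_law(recs)
        f1 = fit_power_law(recs, fixed_alpha=1.0)
        f0 = fit_power_law(recs, fixed_alpha=0.0)
        table = compare_bic(free, f1, f0)
        d1, d0 = table.delta_bic[1], table.delta_bic[2]
        assert d0 > d1 > 10
        assert table.preferred[0]


class TestPredictiveBand:
    def test_zero_noise_collapses_to_median_curve(self, rng):
        recs = _records_from_curve(50, 0.7, 0.2, 0.0, rng)
        fit = fit_power_law(recs)
        band = predictive_band(fit, [0.001, 0.01, 0.1])
        for qt in ("q0.05", "q0.5", "q0.95"):
            assert np.allclose(band[qt], fit.beta * band["I_Imm"] ** fit.alpha,
                               rtol=1e-4)

    def test_median_at_unit_predictor_is_beta(self, rng):
        recs = _records_from_curve(100, 0.6, 0.05, 0.3, rng)
        fit = fit_power_law(recs)
        band = predictive_band(fit, [1.0])
        assert band["q0.5"][0] == pytest.approx(fit.beta, rel=1e-9)

    def test_empirical_coverage_of_ninety_percent_band(self, rng):
        truth = dict(alpha=0.6, beta=0.05, gamma=0.5)
        recs = _records_from_curve(4000, rng=rng, **truth)
        fit = fit_power_law(recs)
        x = np.array([r.I_Imm for r in recs])
        y = np.array([r.I_PCD for r in recs])
        band = predictive_band(fit, x)
        inside = (y >= band["q0.05"]) & (y <= band["q0.95"])
        assert inside.mean() == pytest.approx(0.90, abs=0.02)
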