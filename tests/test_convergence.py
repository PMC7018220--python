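"""Convergence-mode inference: covariance builders, composite likelihood,
grid search and refinement, with brute-force linear-algebra oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sstats

from repadapt.convergence import (
    REDUCED_GRIDS,
    CoancestryMatrix,
    SweepModelParams,
    composite_loglik,
    dense_t_refinement,
    estimate_F,
    grid_search,
    median_spacing,
    model_covariance,
    modified_F,
    rank_models,
    sweep_y,
)
from repadapt.synthetic import default_coancestry, simulate_region

POPS = [f"P{i}" for i in range(8)]
SEL = ("P0", "P1", "P2", "P3")
SIZES = {p: 10 for p in POPS}


def _F():
    return default_coancestry()


class TestEstimateF:
    def test_identical_populations_give_zero_matrix(self):
        x = np.tile(np.linspace(0.1, 0.9, 100)[:, None], (1, 8))
        Fhat = estimate_F(x, POPS)
        assert np.abs(Fhat.F).max() < 1e-5  # only the PSD floor remains

    def test_fixed_sites_skipped(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.2, 0.8, size=(100, 8))
        x[0] = 0.0
        x[1] = 1.0
        Fhat = estimate_F(x, POPS)
        assert np.isfinite(Fhat.F).all()

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            estimate_F(np.full((10, 8), 0.5), POPS)


class TestSweepY:
    def test_unity_at_zero_distance(self):
        p = SweepModelParams(model="independent", s=0.5, selected_pops=SEL)
        assert sweep_y(0.0, p) == 1.0

    def test_vanishes_far_away(self):
        p = SweepModelParams(model="independent", s=0.5, selected_pops=SEL)
        assert sweep_y(1e12, p) < 1e-12

    def test_hand_calculated_value(self):
        # Ne=7.5e5, s=1, r=1e-8, d=1e5: y = exp(-1e-3 * ln(1.5e6))
        p = SweepModelParams(model="independent", s=1.0, r=1e-8, Ne=7.5e5, selected_pops=SEL)
        expected = math.exp(-1e-8 * 1e5 * math.log(1.5e6))
        assert sweep_y(1e5, p) == pytest.approx(expected, rel=1e-12)

    def test_standing_uses_g_as_start_frequency(self):
        p = SweepModelParams(model="standing", s=1.0, g=1e-2, r=1e-8, selected_pops=SEL)
        expected = math.exp(-1e-8 * 1e5 * math.log(100.0))
        assert sweep_y(1e5, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_d_increasing_in_s(self):
        p = SweepModelParams(model="independent", s=0.5, selected_pops=SEL)
        d = np.linspace(0, 1e6, 50)
        y = np.asarray(sweep_y(d, p))
        assert (np.diff(y) < 0).all()
        y_strong = np.asarray(sweep_y(d[1:], replace(p, s=1.0)))
        assert (y_strong > y[1:]).all()


class TestModelCovariance:
    def test_far_distance_equals_neutral(self):
        F = _F()
        for model in ("independent", "migration", "standing"):
            p = SweepModelParams(
                model=model,
                s=0.8,
                m=0.1,
                source="R1",
                selected_pops=("R1", "R2", "R3", "R4"),
            )
            sc = model_covariance(F, 1e12, p, eps=0.4, sample_sizes={q: 10 for q in F.populations})
            neutral = model_covariance(
                F, 1e12, replace(p, model="neutral"), eps=0.4,
                sample_sizes={q: 10 for q in F.populations},
            )
            assert np.allclose(sc.Sigma, neutral.Sigma, atol=1e-9), model

    def test_standing_t_zero_matches_free_migration(self):
        # standing(t=0, g=1/(2Ne)) and migration(m=1) build identical
        # covariances: the algebra collapses (P_coal=0, P_through=1, delta=0)
        F = _F()
        sel = ("R1", "R2", "R3", "R4")
        Ne = 7.5e5
        st = SweepModelParams(model="standing", s=0.65, g=1.0 / (2 * Ne), t=0.0, Ne=Ne, selected_pops=sel)
        mig = SweepModelParams(model="migration", s=0.65, m=1.0, source="R1", Ne=Ne, selected_pops=sel)
        d = np.array([0.0, 1e4, 1e5, 5e5, 2e6])
        assert np.allclose(modified_F(F, d, st), modified_F(F, d, mig), atol=1e-12)

    def test_standing_old_limit(self):
        F = _F()
        sel = ("R1", "R2", "R3", "R4")
        p = SweepModelParams(model="standing", s=1.0, g=1e-3, t=1e7, selected_pops=sel)
        d = np.array([2e5])
        out = modified_F(F, d, p)[0]
        i, j = F.index_of(("R1",))[0], F.index_of(("R2",))[0]
        # between-population entries revert to neutral coancestry
        assert out[i, j] == pytest.approx(F.F[i, j], abs=1e-9)
        # within-population weight tends to y^2 * K_s / (K_s + 2 r_d)
        Ks = 1.0 / (2 * p.Ne * p.g)
        r_d = p.r * d[0]
        y = float(sweep_y(d[0], p))
        w = y**2 * Ks / (Ks + 2 * r_d)
        assert out[i, i] == pytest.approx(w + (1 - w) * F.F[i, i], abs=1e-9)

    def test_between_population_standing_term_decreases_in_t_and_d(self):
        F = _F()
        sel = ("R1", "R2", "R3", "R4")
        i, j = F.index_of(("R1",))[0], F.index_of(("R2",))[0]
        base = dict(model="standing", s=1.0, g=1e-2, selected_pops=sel)
        vals_t = [
            modified_F(F, np.array([1e5]), SweepModelParams(t=t, **base))[0, i, j]
            for t in (0.0, 10.0, 100.0, 1000.0)
        ]
        assert (np.diff(vals_t) < 0).all()
        vals_d = [
            modified_F(F, np.array([d]), SweepModelParams(t=100.0, **base))[0, i, j]
            for d in (0.0, 1e4, 1e5, 1e6)
        ]
        assert (np.diff(vals_d) < 0).all()


class TestCompositeLoglik:
    def _region(self, seed=0, model="neutral", **kw):
        F = _F()
        p = SweepModelParams(
            model=model, x0=500_000, selected_pops=("R1", "R2", "R3", "R4"), **kw
        )
        freqs, pos = simulate_region(F, p, n_snps=40, span=400_000, seed=seed)
        return F, freqs, pos

    def test_neutral_ratio_against_itself_is_zero(self):
        F, freqs, pos = self._region()
        p = SweepModelParams(model="neutral", selected_pops=("R1",))
        a = composite_loglik(freqs, pos, int(pos[0]), p, F, SIZES_F(F))
        b = composite_loglik(freqs, pos, int(pos[-1]), p, F, SIZES_F(F))
        assert np.isfinite(a) and a == pytest.approx(b)  # x0 irrelevant when neutral

    def test_allele_label_flip_invariance(self):
        F, freqs, pos = self._region(seed=1)
        p = SweepModelParams(
            model="independent", s=0.8, selected_pops=("R1", "R2", "R3", "R4")
        )
        a = composite_loglik(freqs, pos, 500_000, p, F, SIZES_F(F))
        b = composite_loglik(1.0 - freqs, pos, 500_000, p, F, SIZES_F(F))
        assert a == pytest.approx(b, abs=1e-8)

    def test_matches_brute_force_multivariate_normal(self):
        F, freqs, pos = self._region(seed=2)
        freqs, pos = freqs[:5], pos[:5]
        p = SweepModelParams(
            model="migration", s=0.65, m=0.1, source="R1",
            selected_pops=("R1", "R2", "R3", "R4"),
        )
        mine = composite_loglik(freqs, pos, 500_000, p, F, SIZES_F(F))
        # oracle: explicit per-SNP (K-1)-dim density via scipy
        K = F.K
        A = (np.eye(K) - np.ones((K, K)) / K)[: K - 1]
        total = 0.0
        X = np.clip(freqs, 0.01, 0.99)
        for s in range(5):
            eps = X[s].mean()
            sc = model_covariance(
                F, abs(int(pos[s]) - 500_000), p, eps, {q: 10 for q in F.populations}
            )
            C = A @ sc.Sigma @ A.T
            z = A @ (X[s] - eps)
            total += sstats.multivariate_normal(mean=np.zeros(K - 1), cov=C).logpdf(z)
        assert mine == pytest.approx(total, abs=1e-8)


def SIZES_F(F):
    return {p: 10 for p in F.populations}


class TestGridSearch:
    def test_migration_truth_beats_independent_and_locates_x0(self):
        F = _F()
        sel = ("R1", "R2", "R3", "R4")
        p = SweepModelParams(
            model="migration", s=0.65, m=1e-4, source="R1", x0=15_000_000, selected_pops=sel
        )
        freqs, pos = simulate_region(F, p, n_snps=120, span=1_000_000, seed=4)
        fits = grid_search(
            freqs, pos, F, sel, SIZES_F(F), grids=REDUCED_GRIDS, x0_stride=12
        )
        assert fits["migration"].max_ratio >= fits["independent"].max_ratio
        assert abs(fits["migration"].x0_hat - p.x0) <= 100_000
        assert fits["neutral"].max_ratio == 0.0

    def test_neutral_data_yields_small_ratios(self):
        F = _F()
        sel = ("R1", "R2", "R3", "R4")
        neutral = SweepModelParams(model="neutral", x0=15_000_000, selected_pops=sel)
        freqs, pos = simulate_region(F, neutral, n_snps=120, span=1_000_000, seed=5)
        fits = grid_search(freqs, pos, F, sel, SIZES_F(F), grids=REDUCED_GRIDS, x0_stride=12)
        sweep = SweepModelParams(
            model="migration", s=0.65, m=1e-4, source="R1", x0=15_000_000, selected_pops=sel
        )
        fs, ps = simulate_region(F, sweep, n_snps=120, span=1_000_000, seed=5)
        sweep_fits = grid_search(fs, ps, F, sel, SIZES_F(F), grids=REDUCED_GRIDS, x0_stride=12)
        best_null = max(f.max_ratio for m, f in fits.items() if m != "neutral")
        assert best_null < 0.25 * sweep_fits["migration"].max_ratio

    def test_empty_or_tiny_region_rejected(self):
        F = _F()
        with pytest.raises(ValueError):
            grid_search(
                np.zeros((5, 8)), np.arange(5), F, ("R1",), SIZES_F(F), grids=REDUCED_GRIDS
            )


class TestRanking:
    def test_overlap_rule_only_reorders_unresolvable_standing(self):
        from repadapt.convergence import ConvergenceFit

        def fit(model, ratio, t=0.0):
            p = SweepModelParams(
                model=model, s=1.0, t=t, g=1e-6, selected_pops=("R1",), m=0.1, source="R1"
            )
            return ConvergenceFit(model, ratio, p, 0, None, 0.0)

        # standing at grid-top t within margin -> independent promoted
        fits = {"independent": fit("independent", 99.0), "standing": fit("standing", 100.0, t=1e4)}
        assert rank_models(fits, t_grid_max=1e4)[0] == "independent"
        # resolvable standing (small t) stays first
        fits = {"independent": fit("independent", 99.0), "standing": fit("standing", 100.0, t=100.0)}
        assert rank_models(fits, t_grid_max=1e4, snp_spacing=5000)[0] == "standing"
        # a decisive standing lead is never overturned
        fits = {"independent": fit("independent", 50.0), "standing": fit("standing", 100.0, t=1e4)}
        assert rank_models(fits, t_grid_max=1e4)[0] == "standing"

    def test_median_spacing(self):
        assert median_spacing(np.array([0, 10, 20, 30])) == 10.0


class TestDenseTRefinement:
    def test_single_value_grid_returned(self):
        F = _F()
        sel = ("R1", "R2", "R3", "R4")
        p = SweepModelParams(model="standing", s=1.0, g=1e-2, t=100.0, x0=500_000, selected_pops=sel)
        freqs, pos = simulate_region(F, p, n_snps=40, span=400_000, seed=6)
        fits = grid_search(
            freqs, pos, F, sel, SIZES_F(F),
            grids={"s": (1.0,), "g": (1e-2,), "t": (0.0, 100.0), "m": (1.0,)},
            x0_stride=10,
        )
        t = dense_t_refinement(fits["standing"], freqs, pos, F, SIZES_F(F), np.array([42.0]))
        assert t == 42.0

    def test_requires_standing_fit(self):
        from repadapt.convergence import ConvergenceFit

        bogus = ConvergenceFit("migration", 1.0, None, 0, None, 0.0)
        with pytest.raises(ValueError):
            dense_t_refinement(bogus, None, None, None, None, np.array([0.0]))
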