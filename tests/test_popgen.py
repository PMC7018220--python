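"""Diversity/differentiation statistics against independent oracles.

Oracles are deliberately separate code paths: all-pairs haplotype
counting for theta_pi, the textbook a/b/c variance components for the
Weir-Cockerham estimator, a from-scratch Tajima's D, and a direct
step-up implementation of Benjamini-Hochberg.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repadapt import io_tables, popgen
from repadapt.io_tables import MISSING, GenotypeMatrix, PopulationPanel, PopulationRow
from repadapt.popgen import (
    candidate_gene_assoc,
    fay_wu_h,
    group_mean_fst,
    ld_r2,
    nei_gst,
    pop_summary_stats,
    site_pi,
    tajimas_d,
    wc_fst,
    window_stats,
)


def _make_gm(G, pops, pos=None, chrom=None, ancestral_ref=True):
    G = np.asarray(G, dtype=np.int16)
    n_sites, n_samples = G.shape
    samples, pop_map = [], {}
    counts = {}
    for p in pops:
        counts[p] = counts.get(p, 0) + 1
        s = f"{p}_{counts[p]}"
        samples.append(s)
        pop_map[s] = p
    ref = np.full(n_sites, "A", dtype=object)
    return GenotypeMatrix(
        samples=samples,
        populations=pop_map,
        chrom=np.full(n_sites, "c1", dtype=object) if chrom is None else chrom,
        pos=np.arange(n_sites) * 100 if pos is None else pos,
        ref=ref,
        alt=np.full(n_sites, "T", dtype=object),
        G=G,
        ancestral=ref.copy() if ancestral_ref else None,
    )


def _panel(pops_classes):
    return PopulationPanel(
        [
            PopulationRow(population=p, survival=0.9 if c == "R" else 0.1, usage=frozenset({"P"}))
            for p, c in pops_classes
        ]
    )


class TestSitePi:
    @pytest.mark.parametrize(
        "c,n,expected", [(0, 10, 0.0), (2, 4, 2 / 3), (10, 10, 0.0), (1, 2, 1.0)]
    )
    def test_formula_values(self, c, n, expected):
        assert site_pi(c, n) == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_two_alleles_is_nan(self):
        assert np.isnan(site_pi(0, 1))

    @given(st.integers(2, 10), st.data())
    @settings(max_examples=30, deadline=None)
    def test_window_theta_pi_equals_all_pairs_haplotype_oracle(self, n_hap, data):
        n_sites = data.draw(st.integers(1, 30))
        hap = np.array(
            [[data.draw(st.integers(0, 1)) for _ in range(n_hap)] for _ in range(n_sites)]
        )
        counts = hap.sum(axis=1)
        theta_pi = float(np.sum(site_pi(counts, np.full(n_sites, n_hap))))
        # brute force: mean pairwise difference over all haplotype pairs
        total, n_pairs = 0, 0
        for i in range(n_hap):
            for j in range(i + 1, n_hap):
                total += int(np.sum(hap[:, i] != hap[:, j]))
                n_pairs += 1
        assert theta_pi == pytest.approx(total / n_pairs, abs=1e-10)


def _tajima_oracle(theta_pi, S, n):
    """Independent from-scratch D (harmonic sums written out longhand)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    var = c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1)
    return (theta_pi - S / a1) / var**0.5


class TestTajimaFayWu:
    def test_zero_when_pi_equals_watterson(self):
        n, S = 10, 7
        a1 = sum(1.0 / i for i in range(1, n))
        assert tajimas_d(S / a1, S, n) == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(4, 60), st.integers(1, 40), st.floats(0.01, 20))
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_implementation(self, n, S, theta_pi):
        assert tajimas_d(theta_pi, S, n) == pytest.approx(
            _tajima_oracle(theta_pi, S, n), abs=1e-8
        )

    def test_excess_rare_variants_negative(self):
        # 20 singleton sites among 20 alleles
        n, S = 20, 20
        theta_pi = S * site_pi(1, n)
        assert tajimas_d(theta_pi, S, n) < 0

    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(0.0, 0, 10))

    def test_fay_wu_hand_example(self):
        # one site, 4 alleles, derived count 3: theta_pi=0.5, theta_H=1.5
        assert fay_wu_h([3], [4]) == pytest.approx(-1.0, abs=1e-12)

    def test_fay_wu_zero_for_singletons_heavy(self):
        # derived singletons: theta_H = 2/(n(n-1)) per site < theta_pi -> H > 0
        assert fay_wu_h([1] * 10, [10] * 10) > 0


class TestGst:
    def test_identical_frequencies_zero(self):
        assert nei_gst(np.array([0.3, 0.3, 0.3])) == pytest.approx(0.0)

    def test_fixed_opposite_alleles_one(self):
        assert nei_gst(np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_hand_value(self):
        assert nei_gst(np.array([0.2, 0.8])) == pytest.approx(0.36, abs=1e-12)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            nei_gst(np.array([[0.5]]))


def _wc_oracle_from_genotypes(g1, g2):
    """Textbook two-population Weir-Cockerham theta from dosage vectors;
    written independently from the package implementation."""
    thetas = []
    for s in range(g1.shape[0]):
        x1 = g1[s][g1[s] != MISSING]
        x2 = g2[s][g2[s] != MISSING]
        n1, n2 = len(x1), len(x2)
        p1, p2 = x1.sum() / (2 * n1), x2.sum() / (2 * n2)
        h1, h2 = np.mean(x1 == 1), np.mean(x2 == 1)
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        thetas.append(np.nan if a + b + c == 0 else a / (a + b + c))
    return np.array(thetas)


class TestWcFst:
    def test_identical_populations_clamped_to_zero(self):
        G = np.tile([0, 1, 2, 1, 0, 1, 2, 1], (5, 1)).astype(np.int16)
        gm = _make_gm(G, ["A"] * 4 + ["B"] * 4)
        theta = wc_fst(gm, "A", "B")
        assert np.all(theta[~np.isnan(theta)] == 0.0)

    def test_fixed_opposite_alleles_one(self):
        G = np.tile([2] * 10 + [0] * 10, (3, 1)).astype(np.int16)
        gm = _make_gm(G, ["A"] * 10 + ["B"] * 10)
        assert np.allclose(wc_fst(gm, "A", "B"), 1.0)

    def test_matches_component_oracle_on_random_data(self):
        rng = np.random.default_rng(42)
        p1, p2 = 0.9, 0.3
        g1 = rng.binomial(2, p1, size=(50, 20)).astype(np.int16)
        g2 = rng.binomial(2, p2, size=(50, 20)).astype(np.int16)
        gm = _make_gm(np.hstack([g1, g2]), ["A"] * 20 + ["B"] * 20)
        mine = wc_fst(gm, "A", "B", clamp=False)
        oracle = _wc_oracle_from_genotypes(g1, g2)
        assert np.allclose(mine, oracle, atol=1e-8, equal_nan=True)

    def test_agrees_with_gst_in_two_pop_hwe_limit(self):
        # weak-differentiation HWE limit: the moment estimator and Nei's
        # heterozygosity partition coincide to first order there
        rng = np.random.default_rng(3)
        n_sites, n = 3000, 200
        p1 = rng.uniform(0.3, 0.7, n_sites)
        p2 = np.clip(p1 + rng.normal(0, 0.05, n_sites), 0.05, 0.95)
        g1 = rng.binomial(2, p1[:, None], size=(n_sites, n)).astype(np.int16)
        g2 = rng.binomial(2, p2[:, None], size=(n_sites, n)).astype(np.int16)
        gm = _make_gm(np.hstack([g1, g2]), ["A"] * n + ["B"] * n)
        theta = wc_fst(gm, "A", "B", clamp=False)
        gst = nei_gst(np.stack([g1.mean(1) / 2, g2.mean(1) / 2], axis=1))
        ok = ~np.isnan(theta)
        assert abs(np.mean(theta[ok]) - np.mean(gst[ok])) < 0.02


class TestGroupMeanFst:
    def test_zero_differentiation_mean_near_zero(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.5, size=(300, 40)).astype(np.int16)
        gm = _make_gm(G, ["A"] * 10 + ["B"] * 10 + ["C"] * 10 + ["D"] * 10)
        panel = _panel([("A", "R"), ("B", "R"), ("C", "R"), ("D", "R")])
        res = group_mean_fst(gm, panel, "R", n_boot=200, seed=1)
        # negatives are clamped to zero, so the null mean is small positive
        assert res["mean"] < 0.03
        assert res["ci"][0] < 0.03

    def test_single_bootstrap_ci_degenerates_to_replicate(self):
        rng = np.random.default_rng(1)
        G = rng.binomial(2, 0.4, size=(50, 20)).astype(np.int16)
        gm = _make_gm(G, ["A"] * 10 + ["B"] * 10)
        panel = _panel([("A", "R"), ("B", "R")])
        res = group_mean_fst(gm, panel, "R", n_boot=1, seed=2)
        assert res["ci"][0] == res["ci"][1]

    def test_single_population_group_rejected(self, tiny_gm):
        panel = _panel([("A", "R"), ("B", "S")])
        with pytest.raises(ValueError):
            group_mean_fst(tiny_gm, panel, "R", n_boot=2)


class TestWindowStats:
    def test_windows_are_consecutive_and_trailing_dropped(self, scenario):
        gm, panel, _, _ = scenario
        ws = window_stats(gm, panel, window=25)
        assert (ws.table["n_snps"] == 25).all()
        per_chrom = ws.table.groupby("chrom").size()
        for chrom, n_win in per_chrom.items():
            assert n_win == (gm.chrom == chrom).sum() // 25

    def test_monomorphic_window_reports_undefined_d(self):
        G = np.zeros((25, 8), dtype=np.int16)
        G[:, 0] = 0  # fully monomorphic
        gm = _make_gm(G, ["A"] * 4 + ["B"] * 4)
        panel = _panel([("A", "R"), ("B", "S")])
        tab = window_stats(gm, panel, window=25).table
        assert np.isnan(tab["D_R"].iloc[0]) and np.isnan(tab["H_R"].iloc[0])

    def test_allele_label_flip_preserves_pi_d_gst_and_h(self, scenario):
        gm, panel, _, _ = scenario
        sub = gm.take_sites(np.arange(200))
        flipped = GenotypeMatrix(
            samples=list(sub.samples),
            populations=dict(sub.populations),
            chrom=sub.chrom.copy(),
            pos=sub.pos.copy(),
            ref=sub.alt.copy(),
            alt=sub.ref.copy(),
            G=np.where(sub.G == MISSING, MISSING, 2 - sub.G).astype(np.int16),
            ancestral=sub.ancestral.copy(),  # ancestral label flips with ref
        )
        a = window_stats(sub, panel).table
        b = window_stats(flipped, panel).table
        for col in ("pi_R", "pi_S", "D_R", "D_S", "H_R", "H_S", "gst_mean"):
            assert np.allclose(a[col], b[col], equal_nan=True), col


class TestLd:
    def test_duplicated_snp_gives_r2_one(self):
        rng = np.random.default_rng(4)
        col = rng.binomial(2, 0.5, size=80).astype(np.int16)
        gm = _make_gm(np.vstack([col, col]), ["A"] * 80, pos=np.array([100, 200]))
        s = ld_r2(gm, "c1")
        assert s.mean_r2 == pytest.approx(1.0, abs=1e-12)

    def test_independent_snps_mean_r2_near_one_over_n(self):
        rng = np.random.default_rng(5)
        n = 80
        G = rng.binomial(2, rng.uniform(0.2, 0.8, size=(400, 1)), size=(400, n)).astype(np.int16)
        gm = _make_gm(G, ["A"] * n, pos=np.arange(400) * 1000)
        s = ld_r2(gm, "c1")
        assert s.mean_r2 == pytest.approx(1.0 / (n - 1), abs=0.01)

    def test_span_detection_covers_perfectly_linked_block(self):
        rng = np.random.default_rng(6)
        base = rng.binomial(2, 0.5, size=80).astype(np.int16)
        block = np.tile(base, (30, 1))
        noise = rng.binomial(2, rng.uniform(0.3, 0.7, size=(60, 1)), size=(60, 80)).astype(np.int16)
        G = np.vstack([noise[:30], block, noise[30:]])
        pos = np.arange(90) * 10_000  # block occupies [300 kb, 600 kb)
        gm = _make_gm(G, ["A"] * 80, pos=pos)
        s = ld_r2(gm, "c1", window_bp=100_000)
        assert any(a <= 300_000 and b >= 590_000 for a, b in s.spans)

    def test_too_few_snps_rejected(self):
        gm = _make_gm(np.array([[0, 1, 2, 1] * 5]), ["A"] * 20)
        with pytest.raises(ValueError):
            ld_r2(gm, "c1")


class TestPopSummary:
    def test_all_heterozygotes_negative_fis(self):
        G = np.ones((10, 10), dtype=np.int16)
        gm = _make_gm(G, ["A"] * 10)
        panel = _panel([("A", "R")])
        row = pop_summary_stats(gm, panel).iloc[0]
        assert row.Ho == 1.0 and row.F_IS < 0

    def test_selfed_population_fis_one(self):
        rng = np.random.default_rng(7)
        G = 2 * rng.binomial(1, 0.5, size=(50, 10)).astype(np.int16)
        gm = _make_gm(G, ["A"] * 10)
        panel = _panel([("A", "R")])
        row = pop_summary_stats(gm, panel).iloc[0]
        assert row.Ho == 0.0 and row.F_IS == pytest.approx(1.0)

    def test_hwe_simulation_fis_near_zero(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.9, size=2000)
        G = rng.binomial(2, p[:, None], size=(2000, 30)).astype(np.int16)
        gm = _make_gm(G, ["A"] * 30)
        panel = _panel([("A", "R")])
        row = pop_summary_stats(gm, panel).iloc[0]
        assert abs(row.F_IS) < 0.05


def _bh_oracle(p):
    """Step-up Benjamini-Hochberg, written directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestCandidateGeneAssoc:
    def _gm_panel(self, G):
        gm = _make_gm(G, ["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5)
        panel = PopulationPanel(
            [
                PopulationRow("A", 0.9, frozenset({"E"})),
                PopulationRow("B", 0.9, frozenset({"E"})),
                PopulationRow("C", 0.1, frozenset({"E"})),
                PopulationRow("D", 0.1, frozenset({"E"})),
            ]
        )
        return gm, panel

    def test_identical_class_frequencies_give_null_chi2(self):
        G = np.tile([0, 1, 2, 1, 0] * 4, (3, 1)).astype(np.int16)
        gm, panel = self._gm_panel(G)
        tab = candidate_gene_assoc(gm, panel)
        assert tab["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert tab["p_chi2"].iloc[0] == pytest.approx(1.0)

    def test_perfectly_separating_snp_has_unit_correlation(self):
        G = np.tile([2] * 10 + [0] * 10, (2, 1)).astype(np.int16)
        gm, panel = self._gm_panel(G)
        tab = candidate_gene_assoc(gm, panel)
        assert abs(tab["pearson_r"].iloc[0]) == pytest.approx(1.0)

    def test_bh_adjustment_matches_direct_step_up(self):
        rng = np.random.default_rng(9)
        G = rng.binomial(2, rng.uniform(0.2, 0.8, (12, 1)), size=(12, 20)).astype(np.int16)
        gm, panel = self._gm_panel(G)
        tab = candidate_gene_assoc(gm, panel)
        ok = tab["p_chi2"].notna()
        expect = _bh_oracle(tab.loc[ok, "p_chi2"].to_numpy())
        assert np.allclose(tab.loc[ok, "q_chi2"].to_numpy(), expect, atol=1e-10)
        # adjusted p monotone nondecreasing in raw-p rank
        srt = tab.loc[ok].sort_values("p_chi2")
        assert (np.diff(srt["q_chi2"].to_numpy()) >= -1e-12).all()
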