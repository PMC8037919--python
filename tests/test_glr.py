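"""GLR and scan statistics, Monte-Carlo null, p-value conversion."""

import math

import numpy as np
import pytest
from scipy import stats

from tadscan.hic_io import ContactMap, RegionGeometry, RegionSummer, RegionSums
from tadscan.glr import (NullTable, TestConfig as ScanConfig, glr_nb, estimate_sigma0,
                         min_tad_bins, pvalue_fixed, pvalue_max, scan_max,
                         scan_stat_zm, simulate_fixed_t, simulate_null)

from conftest import random_contact_map


# ---------------------------------------------------------------------------
# minimum TAD size
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("resolution,expected", [
    (40_000, 3),      # the 40-kb worked example
    (25_000, 4),
    (100_000, 1),     # exact division
    (30_000, 4),      # ceiling, not rounding
])
def test_min_tad_bins(resolution, expected):
    assert min_tad_bins(resolution) == expected


def test_min_tad_bins_rejects_bad_resolution():
    with pytest.raises(ValueError):
        min_tad_bins(0)


# ---------------------------------------------------------------------------
# GLR statistic
# ---------------------------------------------------------------------------

def glr_oracle(sa1, sa2, sr, n1, n2, nr, r):
    """Term-by-term transcription of the log likelihood-ratio formula,
    kept deliberately independent of the library implementation."""
    total = 0.0
    for s, size in ((sa1, n1), (sa2, n2), (sr, nr)):
        lam = s / size
        if s > 0:
            total += s * math.log(lam / (r + lam))
        total += r * size * math.log(r / (r + lam))
    sa, na = sa1 + sa2 + sr, n1 + n2 + nr
    lam = sa / na
    if sa > 0:
        total -= sa * math.log(lam / (r + lam))
    total -= r * na * math.log(r / (r + lam))
    return total


def test_glr_zero_when_means_equal():
    geom = RegionGeometry(0, 4, 2)   # sizes 3, 3, 4
    sums = RegionSums(s_a1=6.0, s_a2=6.0, s_r=8.0)  # common mean 2
    assert glr_nb(sums, geom, r=1.0) == pytest.approx(0.0, abs=1e-12)


def test_glr_matches_direct_formula():
    geom = RegionGeometry(0, 4, 2)
    sums = RegionSums(s_a1=30.0, s_a2=30.0, s_r=4.0)
    expected = glr_oracle(30.0, 30.0, 4.0, 3, 3, 4, r=1.0)
    assert glr_nb(sums, geom, r=1.0) == pytest.approx(expected, rel=1e-12)


def test_glr_matches_oracle_on_random_instances(rng):
    for _ in range(300):
        g, h = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        geom = RegionGeometry(0, g + h, g)
        sums = RegionSums(*(rng.random(3) * 50))
        r = float(rng.random() * 20 + 0.1)
        assert glr_nb(sums, geom, r) == pytest.approx(
            max(glr_oracle(sums.s_a1, sums.s_a2, sums.s_r,
                           geom.n_a1, geom.n_a2, geom.n_r, r), 0.0),
            rel=1e-10, abs=1e-10)


def test_glr_rejects_nonpositive_r():
    geom = RegionGeometry(0, 4, 2)
    sums = RegionSums(1.0, 1.0, 1.0)
    for r in (0.0, -1.0):
        with pytest.raises(ValueError):
            glr_nb(sums, geom, r)


# ---------------------------------------------------------------------------
# scan statistic
# ---------------------------------------------------------------------------

def zm_oracle(cm, s, e, m, sigma0_sq):
    """Direct evaluation of the two-contrast scan statistic from raw cells."""
    sa1 = sum(cm.value_at(i, j) for i in range(s, m) for j in range(i, m))
    sa = sum(cm.value_at(i, j) for i in range(s, e) for j in range(i, e))
    sa1r = sum(cm.value_at(i, j) for i in range(s, m) for j in range(i, e))
    g, w = m - s, e - s
    n1 = g * (g + 1) / 2
    n1r = n1 + g * (w - g)
    na = w * (w + 1) / 2
    t1 = (sa1 - n1 / n1r * sa1r) ** 2 / (n1 * (1 - n1 / n1r))
    t2 = (sa1r - n1r / na * sa) ** 2 / (n1r * (1 - n1r / na))
    return (t1 + t2) / (2 * sigma0_sq)


def test_zm_zero_on_constant_matrix():
    cm = ContactMap.from_dense(np.full((6, 6), 5.0), resolution=1)
    summer = RegionSummer(cm, 0, 6)
    for m in range(1, 6):
        z = scan_stat_zm(summer.sums(m), RegionGeometry(0, 6, m), 1.0)
        assert z == pytest.approx(0.0, abs=1e-18)


def test_zm_scales_inversely_with_sigma0(rng):
    cm = random_contact_map(rng, 8)
    summer = RegionSummer(cm, 0, 8)
    sums, geom = summer.sums(4), RegionGeometry(0, 8, 4)
    z1 = scan_stat_zm(sums, geom, 1.0)
    assert scan_stat_zm(sums, geom, 2.0) == pytest.approx(z1 / 2, rel=1e-12)


def test_zm_matches_direct_evaluation(rng):
    cm = random_contact_map(rng, 4, density=1.0)
    summer = RegionSummer(cm, 0, 4)
    z = scan_stat_zm(summer.sums(2), RegionGeometry(0, 4, 2), 1.0)
    assert z == pytest.approx(zm_oracle(cm, 0, 4, 2, 1.0), rel=1e-10)


def test_zm_invariant_to_value_scaling(rng):
    """Scaling all cells by c scales sigma0^2 by c^2 and leaves Z_m fixed."""
    cm = random_contact_map(rng, 10)
    c = 3.7
    cm2 = ContactMap.from_coo(cm.rows, cm.cols, cm.vals * c, resolution=1,
                              n_bins=cm.n_bins)
    v1, _ = estimate_sigma0(cm, 0, 10)
    v2, _ = estimate_sigma0(cm2, 0, 10)
    assert v2 == pytest.approx(c * c * v1, rel=1e-10)
    for m in (3, 5, 7):
        z1 = scan_stat_zm(RegionSummer(cm, 0, 10).sums(m),
                          RegionGeometry(0, 10, m), v1)
        z2 = scan_stat_zm(RegionSummer(cm2, 0, 10).sums(m),
                          RegionGeometry(0, 10, m), v2)
        assert z2 == pytest.approx(z1, rel=1e-9)


class TestScanMax:
    def test_two_block_matrix_splits_at_boundary(self):
        x = np.zeros((20, 20))
        x[:10, :10] = 10.0
        x[10:, 10:] = 10.0
        cm = ContactMap.from_dense(np.triu(x) + np.triu(x, 1).T, resolution=1)
        res = scan_max(cm, 0, 20, ScanConfig(xi=3))
        assert res.m_star == 10

    def test_window_of_two_xi_has_no_split(self, rng):
        cm = random_contact_map(rng, 6)
        assert scan_max(cm, 0, 6, ScanConfig(xi=3)) is None

    def test_profile_matches_pointwise_statistic(self, rng):
        cm = random_contact_map(rng, 16)
        cfg = ScanConfig(xi=2)
        res = scan_max(cm, 0, 16, cfg)
        summer = RegionSummer(cm, 0, 16)
        for m, z in zip(res.ms, res.z):
            direct = scan_stat_zm(summer.sums(int(m)),
                                  RegionGeometry(0, 16, int(m)),
                                  res.sigma0_sq)
            assert z == pytest.approx(direct, rel=1e-10)
        assert res.z_tilde == max(res.z_values.values())
        assert res.m_star == min(m for m, z in res.z_values.items()
                                 if z == res.z_tilde)


# ---------------------------------------------------------------------------
# Monte-Carlo null
# ---------------------------------------------------------------------------

class TestNullTable:
    def test_same_seed_reproduces_table(self):
        a = simulate_null(delta=0.05, grid_n=60, n_samples=1000, seed=3)
        b = simulate_null(delta=0.05, grid_n=60, n_samples=1000, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_delta_too_large_rejected(self):
        with pytest.raises(ValueError):
            simulate_null(delta=0.5, grid_n=60, n_samples=1000, seed=0)

    def test_boundary_delta_is_legal(self):
        t = simulate_null(delta=0.49, grid_n=100, n_samples=1000, seed=0)
        assert t.samples.size == 1000 and np.all(t.samples >= 0)

    def test_gdelta_monotone_in_delta_drawwise(self):
        """With shared noise, widening the t range can only raise the max."""
        kw = dict(grid_n=80, n_samples=1000, seed=11)
        narrow = simulate_null(delta=0.2, **kw)
        wide = simulate_null(delta=0.05, **kw)
        assert np.all(wide.samples >= narrow.samples)

    def test_save_load_roundtrip(self, tmp_path):
        t = simulate_null(delta=0.05, grid_n=60, n_samples=1000, seed=3)
        t.save(tmp_path / "null.txt")
        back = NullTable.load(tmp_path / "null.txt")
        assert (back.delta, back.grid_n, back.n_samples, back.seed) == \
            (t.delta, t.grid_n, t.n_samples, t.seed)
        np.testing.assert_allclose(back.samples, t.samples, rtol=1e-9)


def test_fixed_t_doubled_is_chisquare_2df():
    """At a fixed split fraction the statistic is half a 2-df chi-square."""
    g = simulate_fixed_t(0.5, grid_n=100, n_samples=4000, seed=5)
    ks = stats.kstest(2.0 * g, stats.chi2(df=2).cdf)
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def pv_table():
    return simulate_null(delta=0.05, grid_n=60, n_samples=2000, seed=9)


class TestPvalues:

    def test_zero_statistic_gives_p_one(self, pv_table):
        table = pv_table
        assert pvalue_max(0.0, table) == 1.0

    def test_exceeding_all_samples_gives_add_one_floor(self, pv_table):
        table = pv_table
        m = table.samples.size
        assert pvalue_max(table.samples.max() + 1, table) == 1.0 / (m + 1)

    def test_median_statistic_gives_half(self, pv_table):
        table = pv_table
        med = float(np.median(table.samples))
        assert pvalue_max(med, table) == pytest.approx(0.5, abs=0.01)

    def test_monotone_in_statistic(self, pv_table):
        table = pv_table
        zs = np.linspace(0, table.samples.max() + 1, 50)
        ps = [pvalue_max(z, table) for z in zs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_fixed_location_limits(self):
        assert pvalue_fixed(0.0) == 1.0
        assert pvalue_fixed(400.0) < 1e-100
        zs = np.linspace(0, 30, 40)
        ps = [pvalue_fixed(z) for z in zs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_fixed_law_agrees_with_field_simulation(self):
        """chi2(2 df) on 2Z reproduces the empirical fixed-t field null."""
        g = simulate_fixed_t(0.4, grid_n=100, n_samples=4000, seed=13)
        for q in (0.5, 1.5, 3.0):
            emp = float(np.mean(g >= q))
            assert pvalue_fixed(q) == pytest.approx(emp, abs=0.03)


def test_null_scan_pvalues_are_conservative(small_table):
    """Pure-noise matrices yield max-statistic p-values stochastically no
    smaller than uniform (one-sided KS)."""
    rng = np.random.default_rng(99)
    cfg = ScanConfig(xi=3, null_table=small_table)
    ps = []
    for _ in range(300):
        x = np.triu(rng.normal(10.0, 2.0, (40, 40)))
        cm = ContactMap.from_coo(*np.nonzero(x), x[np.nonzero(x)],
                                 resolution=1, n_bins=40)
        ps.append(pvalue_max(scan_max(cm, 0, 40, cfg).z_tilde, small_table))
    ks = stats.ks_1samp(ps, stats.uniform.cdf, alternative="greater")
    assert ks.pvalue > 0.01


def test_glr_and_scan_profiles_agree_on_null_nb(rng):
    """The NB likelihood ratio and the distribution-free scan statistic are
    near-proportional along the split profile under the null."""
    from tadscan.glr import estimate_r_moments
    cors = []
    for _ in range(10):
        n, mu, r_true = 120, 72.0, 10.0
        x = np.triu(rng.negative_binomial(r_true, r_true / (r_true + mu),
                                          (n, n)).astype(float))
        cm = ContactMap.from_coo(*np.nonzero(x), x[np.nonzero(x)],
                                 resolution=1, n_bins=n)
        summer = RegionSummer(cm, 0, n)
        sigma0, _ = summer.sigma0_sq()
        r_hat = estimate_r_moments(cm, 0, n)
        ms = range(4, n - 2)
        g = [glr_nb(summer.sums(m), RegionGeometry(0, n, m), r_hat) for m in ms]
        z = [scan_stat_zm(summer.sums(m), RegionGeometry(0, n, m), sigma0)
             for m in ms]
        cors.append(np.corrcoef(g, z)[0, 1])
    assert np.mean(cors) > 0.95
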