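"""Change-point test statistics and their Monte-Carlo null calibration.

The boundary test asks, for a diagonal window ``A`` of the contact matrix
split at ``m``, whether the two triangular blocks and the rectangle between
them share one mean.  Under a negative-binomial model the log generalized
likelihood ratio ``GLR_NB,m`` answers this; it is asymptotically equivalent
to a distribution-free scan statistic

    Z_m = (1 / 2 sigma0^2) * [ (S_A1 - w1 * S_{A1 u R})^2 / (|A1| (1 - w1))
                             + (S_{A1 u R} - w2 * S_A)^2 / (|A1 u R| (1 - w2)) ]

with ``w1 = |A1| / |A1 u R|``, ``w2 = |A1 u R| / |A|`` and ``sigma0^2`` the
null cell variance, so detection does not depend on the count distribution.
When the split location is unknown the statistic is the maximum of ``Z_m``
over admissible splits, whose limiting law is the maximum ``g_delta`` of a
quadratic functional of a Gaussian random field on the unit upper triangle;
that law has no closed form and is tabulated here by Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hic_io import ContactMap, RegionGeometry, RegionSummer, RegionSums

__all__ = [
    "min_tad_bins",
    "glr_nb",
    "estimate_sigma0",
    "estimate_r_moments",
    "scan_stat_zm",
    "scan_max",
    "simulate_null",
    "simulate_fixed_t",
    "default_null_table",
    "pvalue_max",
    "pvalue_fixed",
    "TestConfig",
    "ScanResult",
    "NullTable",
]

#: smallest p-value reported by the fixed-location test (keeps logs finite)
P_FLOOR = 1e-300


def min_tad_bins(resolution: int, min_size_bp: int = 100_000) -> int:
    """Minimum TAD size ``xi`` in bins: ``ceil(min_size_bp / resolution)``.

    The 100-kb default reflects the observed lower end of sub-TAD sizes in
    high-resolution human Hi-C maps; e.g. at 40 kb resolution ``xi = 3``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return -(-int(min_size_bp) // int(resolution))


# ---------------------------------------------------------------------------
# GLR and scan statistics
# ---------------------------------------------------------------------------

def _nb_profile_term(s: float, size: int, r: float) -> float:
    """Profile NB log-likelihood of a region (constants dropped)."""
    lam = s / size
    if s > 0:
        return s * math.log(lam / (r + lam)) + r * size * math.log(r / (r + lam))
    return 0.0  # lam = 0: both terms vanish


def glr_nb(sums: RegionSums, geom: RegionGeometry, r: float) -> float:
    """Log generalized likelihood ratio for one split under the NB model.

    ``r`` is the NB nuisance (size) parameter shared across regions; the
    block means are profiled out at their MLEs ``S / |.|``.  Zero when the
    three region means coincide.
    """
    if r <= 0:
        raise ValueError("NB nuisance parameter r must be positive")
    if min(geom.n_a1, geom.n_a2, geom.n_r) < 1:
        raise ValueError("degenerate region geometry")
    val = (_nb_profile_term(sums.s_a1, geom.n_a1, r)
           + _nb_profile_term(sums.s_a2, geom.n_a2, r)
           + _nb_profile_term(sums.s_r, geom.n_r, r)
           - _nb_profile_term(sums.s_a, geom.n_a, r))
    return max(val, 0.0)


def estimate_sigma0(cm: ContactMap, s: int, e: int) -> tuple[float, bool]:
    """Unbiased variance of all window cells, zeros included.

    Returns ``(variance, degenerate)``; constant windows are floored at
    1e-8 and flagged degenerate.
    """
    return RegionSummer(cm, s, e).sigma0_sq()


def estimate_r_moments(cm: ContactMap, s: int, e: int, floor: float = 1e-3) -> float:
    """Method-of-moments NB size parameter ``r = mean^2 / (var - mean)``."""
    summer = RegionSummer(cm, s, e)
    var, _ = summer.sigma0_sq()
    mean = summer.mean()
    if var > mean > 0:
        return max(mean * mean / (var - mean), floor)
    return 1.0 / floor if mean > 0 else floor  # under-dispersed: near-Poisson


def _zm_terms(s_a1, s_a1r, s_a, n_a1, n_a1r, n_a, sigma0_sq):
    """Vectorised evaluation of the two orthogonal contrasts of ``Z_m``."""
    w1 = n_a1 / n_a1r
    w2 = n_a1r / n_a
    t1 = (s_a1 - w1 * s_a1r) ** 2 / (n_a1 * (1.0 - w1))
    t2 = (s_a1r - w2 * s_a) ** 2 / (n_a1r * (1.0 - w2))
    return (t1 + t2) / (2.0 * sigma0_sq)


def scan_stat_zm(sums: RegionSums, geom: RegionGeometry, sigma0_sq: float) -> float:
    """The scan statistic ``Z_m`` for a single split."""
    if sigma0_sq <= 0:
        raise ValueError("sigma0_sq must be positive")
    n_a1, n_r, n_a = geom.n_a1, geom.n_r, geom.n_a
    n_a1r = n_a1 + n_r
    if n_a1 == n_a1r or n_a1r == n_a:
        raise ValueError("degenerate geometry: empty contrast")
    return float(_zm_terms(sums.s_a1, sums.s_a1 + sums.s_r, sums.s_a,
                           n_a1, n_a1r, n_a, sigma0_sq))


@dataclass
class TestConfig:
    """Settings of the boundary test.

    ``null_mode='auto'`` uses the Monte-Carlo max null when the split is
    estimated (detection, pruning) and the fixed-location chi-square null
    when it is given (boundary re-tests, merging); ``'max'``/``'fixed'``
    force one reference everywhere.
    """

    xi: int = 3
    sigma0_sq: float | None = None
    null_table: "NullTable | None" = None
    null_mode: str = "auto"

    def __post_init__(self):
        if self.xi < 1:
            raise ValueError("xi must be >= 1")
        if self.sigma0_sq is not None and self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be positive when supplied")
        if self.null_mode not in ("auto", "max", "fixed"):
            raise ValueError("null_mode must be 'auto', 'max' or 'fixed'")

    def table(self) -> "NullTable":
        if self.null_table is None:
            self.null_table = default_null_table()
        return self.null_table


@dataclass
class ScanResult:
    """Per-split scan profile over one window and its maximiser."""

    s: int
    e: int
    ms: np.ndarray
    z: np.ndarray
    m_star: int
    z_tilde: float
    sigma0_sq: float
    degenerate: bool = False

    @property
    def z_values(self) -> dict[int, float]:
        return dict(zip(self.ms.tolist(), self.z.tolist()))


def scan_max(cm: ContactMap, s: int, e: int, cfg: TestConfig,
             summer: RegionSummer | None = None,
             include_left_edge: bool = False) -> ScanResult | None:
    """Evaluate ``Z_m`` for every admissible split of ``[s, e)`` and maximise.

    Admissible splits satisfy ``s + xi < m <= e - xi``.  Returns ``None``
    when the window admits no split (size ``<= 2 xi``).  Ties in the maximum
    are broken towards the smallest ``m``.

    ``include_left_edge`` widens the range to the symmetric ``[s + xi,
    e - xi]``; re-tests against already-fixed delimiters use it so that any
    position at least ``xi`` bins from both window ends can be reached when
    a boundary is re-estimated.
    """
    xi = cfg.xi
    lo = s + xi if include_left_edge else s + xi + 1
    ms = np.arange(lo, e - xi + 1, dtype=np.int64)
    if ms.size == 0:
        return None
    if summer is None:
        summer = RegionSummer(cm, s, e)
    if cfg.sigma0_sq is not None:
        sigma0, degen = cfg.sigma0_sq, False
    else:
        sigma0, degen = summer.sigma0_sq()
    s_a1, s_a1r, s_a = summer.sums_vector(ms)
    g = (ms - s).astype(np.float64)
    w = float(e - s)
    n_a1 = g * (g + 1) / 2.0
    n_a1r = n_a1 + g * (w - g)
    n_a = w * (w + 1) / 2.0
    z = _zm_terms(s_a1, s_a1r, s_a, n_a1, n_a1r, n_a, sigma0)
    k = int(np.argmax(z))  # argmax returns the first (smallest-m) maximiser
    return ScanResult(s=s, e=e, ms=ms, z=z, m_star=int(ms[k]),
                      z_tilde=float(z[k]), sigma0_sq=sigma0, degenerate=degen)


# ---------------------------------------------------------------------------
# Monte-Carlo null of the max statistic
# ---------------------------------------------------------------------------

@dataclass
class NullTable:
    """Sorted Monte-Carlo sample of the limiting max statistic ``g_delta``."""

    delta: float
    grid_n: int
    n_samples: int
    samples: np.ndarray
    seed: int

    def __post_init__(self):
        self.samples = np.sort(np.asarray(self.samples, dtype=np.float64))
        if not (0 < self.delta < 0.5):
            raise ValueError("delta must lie in (0, 0.5)")
        if self.n_samples < 1000:
            raise ValueError("need at least 1000 Monte-Carlo samples")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# tadscan null table delta={self.delta} grid_n={self.grid_n} "
                     f"n_samples={self.n_samples} seed={self.seed}\n")
            np.savetxt(fh, self.samples, fmt="%.10g")

    @classmethod
    def load(cls, path) -> "NullTable":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.split() if "=" in tok)
            samples = np.loadtxt(fh)
        return cls(delta=float(meta["delta"]), grid_n=int(meta["grid_n"]),
                   n_samples=int(meta["n_samples"]), samples=samples,
                   seed=int(meta["seed"]))


def _field_g_profile(rng: np.random.Generator, n_draws: int, grid_n: int,
                     chunk: int = 500):
    """Yield ``g_t`` evaluated on the full interior grid for blocks of draws.

    Each draw fills the upper-triangular cells of the unit triangle ``B``
    with iid standard normals; ``G_S = (cell sum) / grid_n`` so that
    ``Var(G_S)`` matches the area of ``S``.  Cumulative row/column sums give
    ``G`` over the split regions for every grid value of ``t`` at once.
    """
    N = grid_n
    mask = np.triu(np.ones((N, N)))
    c = np.arange(1, N, dtype=np.float64)     # cutoff index; t = c / N
    t = c / N
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        A = rng.standard_normal((m, N, N))
        A *= mask
        col_tri = A.sum(axis=1)               # (m, N): triangular column sums
        row_full = A.sum(axis=2)              # (m, N): row sums j >= i
        g_a1 = np.cumsum(col_tri, axis=1)[:, :-1] / N       # G_{A1}(t)
        g_a1r = np.cumsum(row_full, axis=1)[:, :-1] / N     # G_{A1 u R}(t)
        g_b = row_full.sum(axis=1, keepdims=True) / N       # G_B
        num1 = g_a1 - (t / (2.0 - t)) * g_a1r
        den1 = 2.0 * t * t * (1.0 - t) / (2.0 - t)
        num2 = g_a1r - t * (2.0 - t) * g_b
        den2 = t * (1.0 - t) ** 2 * (2.0 - t)
        yield t, num1 * num1 / den1 + num2 * num2 / den2
        done += m


def simulate_null(delta: float = 0.01, grid_n: int = 200,
                  n_samples: int = 20_000, seed: int = 0,
                  chunk: int = 500) -> NullTable:
    """Monte-Carlo table of ``g_delta = max_{delta < t < 1-delta} g_t``.

    The field draws are independent of ``delta``: the restriction to the
    admissible ``t`` range is applied after evaluating the full profile, so
    tables generated with the same seed but different ``delta`` share their
    underlying noise (``g_delta`` is draw-by-draw non-increasing in
    ``delta``).
    """
    if not (0 < delta < 0.5):
        raise ValueError("delta must lie in (0, 0.5)")
    if grid_n < 50:
        raise ValueError("grid_n must be at least 50")
    if n_samples < 1000:
        raise ValueError("need at least 1000 samples")
    rng = np.random.default_rng(seed)
    out = []
    for t, g in _field_g_profile(rng, n_samples, grid_n, chunk):
        sel = (t > delta) & (t < 1.0 - delta)
        if not sel.any():
            raise ValueError("empty t range for this delta/grid combination")
        out.append(g[:, sel].max(axis=1))
    return NullTable(delta=delta, grid_n=grid_n, n_samples=n_samples,
                     samples=np.concatenate(out), seed=seed)


def simulate_fixed_t(t: float, grid_n: int = 200, n_samples: int = 10_000,
                     seed: int = 0, chunk: int = 500) -> np.ndarray:
    """Draws of ``g_t`` at a fixed split fraction ``t`` (nearest grid value)."""
    if not (0 < t < 1):
        raise ValueError("t must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for tg, g in _field_g_profile(rng, n_samples, grid_n, chunk):
        k = int(np.argmin(np.abs(tg - t)))
        out.append(g[:, k])
    return np.concatenate(out)


_DEFAULT_TABLE_SEED = 186_282
_table_cache: dict[tuple, NullTable] = {}


def default_null_table(delta: float = 0.01, grid_n: int = 200,
                       n_samples: int = 20_000,
                       seed: int = _DEFAULT_TABLE_SEED) -> NullTable:
    """Shared process-cached null table.

    A single table at small ``delta`` serves all windows: restricting the
    maximum to a narrower ``t`` range only shrinks ``g``, so p-values for
    windows whose effective ``xi / n`` exceeds ``delta`` are conservative.
    """
    key = (delta, grid_n, n_samples, seed)
    if key not in _table_cache:
        _table_cache[key] = simulate_null(delta=delta, grid_n=grid_n,
                                          n_samples=n_samples, seed=seed)
    return _table_cache[key]


# ---------------------------------------------------------------------------
# P-values
# ---------------------------------------------------------------------------

def pvalue_max(z_tilde: float, table: NullTable) -> float:
    """Empirical upper-tail p-value with add-one continuity:
    ``p = (1 + #{samples >= z}) / (1 + M)``."""
    m = table.samples.size
    n_ge = m - int(np.searchsorted(table.samples, z_tilde, side="left"))
    return (1.0 + n_ge) / (1.0 + m)


def pvalue_fixed(z: float) -> float:
    """Known-location p-value: upper tail of chi-square(2) at ``2 z``.

    ``Z_m`` is half the sum of two squared orthogonal standardised
    contrasts, so ``2 Z_m`` is asymptotically chi-square with 2 df.
    """
    if z < 0:
        raise ValueError("scan statistic cannot be negative")
    return float(max(stats.chi2.sf(2.0 * z, df=2), P_FLOOR))
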