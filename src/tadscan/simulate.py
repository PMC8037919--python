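"""Synthetic contact matrices with known change-points.

Two flat designs emulate the benchmark conditions used to validate the
detector, and a nested generator provides hierarchies for the
Fowlkes-Mallows evaluation:

* **gaussian** -- 500 x 500 matrix, 31 change-points drawn uniformly with
  every block larger than 4 bins, block means ``mu_k ~ Gamma(shape 4,
  scale 18)`` (mean 72); in-block cells ``N(mu_k, sigma^2)`` and background
  cells ``max{N(0, sigma^2), 0}`` with ``sigma^2 = 72 + 72^2 nu``.
* **poisson-nb** -- same layout; in-block cells are negative binomial with
  mean ``mu_k`` and variance ``mu_k + nu mu_k^2`` (Poisson when ``nu = 0``),
  background cells a 50/50 mixture of a point mass at zero and an NB with
  the smallest block mean.  ``sqrt(nu)`` is the biological coefficient of
  variation and ranges over 0-0.16 in the study conditions.
* **nested** -- recursive block splitting with elevated sub-block means,
  NB noise, and per-level ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic_io import ContactMap

__all__ = [
    "SimScenario",
    "GroundTruth",
    "draw_changepoints",
    "gen_sim3",
    "gen_sim4",
    "gen_nested",
    "generate",
]

_GAUSS_BASE_VAR = 72.0  # variance at nu = 0; equals the Gamma(4, 18) mean


@dataclass
class SimScenario:
    """Generator parameters; defaults reproduce the study conditions."""

    family: str = "gaussian"        # gaussian | poisson-nb | nested
    n: int = 500
    K: int = 31
    min_gap: int = 5
    mean_shape: float = 4.0
    mean_scale: float = 18.0
    bcv: float = 0.0                # sqrt(nu)
    sigma_sq: float | None = None   # Gaussian variance; default 72 + 72^2 nu
    seed: int | None = None
    # nested-family knobs
    levels: int = 2
    sub_mean_ratio: float = 2.0     # child mean / parent mean per level
    split_prob: float = 1.0         # chance an eligible block is subdivided

    def __post_init__(self):
        if self.family not in ("gaussian", "poisson-nb", "nested"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.bcv < 0:
            raise ValueError("bcv must be non-negative")
        if self.K * self.min_gap >= self.n:
            raise ValueError("K * min_gap must be smaller than n")

    @property
    def nu(self) -> float:
        return self.bcv ** 2

    def gaussian_var(self) -> float:
        if self.sigma_sq is not None:
            return self.sigma_sq
        return _GAUSS_BASE_VAR + _GAUSS_BASE_VAR ** 2 * self.nu


@dataclass
class GroundTruth:
    """True change-points, block means and (optionally) nesting labels."""

    taus: np.ndarray
    block_means: np.ndarray
    hierarchy: dict[int, np.ndarray] | None = None  # level -> label per bin


def draw_changepoints(n: int, K: int, min_gap: int = 5,
                      seed=None) -> np.ndarray:
    """Uniform draw of ``K`` change-points with every block >= ``min_gap``.

    Uses the standard bijection onto combinations: with slack
    ``M = n - (K + 1) min_gap``, strictly increasing draws from
    ``{0, ..., M + K - 1}`` map to valid configurations one-to-one, so the
    draw is uniform over all of them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if K == 0:
        return np.empty(0, dtype=np.int64)
    slack = n - (K + 1) * min_gap
    if slack < 0:
        raise ValueError(f"no room: n={n} < (K+1)*min_gap={(K + 1) * min_gap}")
    v = np.sort(rng.choice(slack + K, size=K, replace=False))
    u = v - np.arange(K)
    return (u + (np.arange(K) + 1) * min_gap).astype(np.int64)


def _block_labels(n: int, taus: np.ndarray) -> np.ndarray:
    """Label each bin with its block index (0-based, K+1 blocks)."""
    return np.searchsorted(taus, np.arange(n), side="right")


def _upper_mask(n: int) -> np.ndarray:
    return np.triu(np.ones((n, n), dtype=bool))


def gen_sim3(sc: SimScenario) -> tuple[ContactMap, GroundTruth]:
    """Gaussian design: blocks ``N(mu_k, sigma^2)``, background
    ``max{N(0, sigma^2), 0}``."""
    rng = np.random.default_rng(sc.seed)
    taus = draw_changepoints(sc.n, sc.K, sc.min_gap, rng)
    mu = rng.gamma(sc.mean_shape, sc.mean_scale, size=sc.K + 1)
    labels = _block_labels(sc.n, taus)
    inblock = labels[:, None] == labels[None, :]
    mean = np.where(inblock, mu[labels][:, None], 0.0)
    sigma = np.sqrt(sc.gaussian_var())
    x = rng.normal(mean, sigma)
    x = np.where(inblock, x, np.maximum(x, 0.0))
    x = np.where(_upper_mask(sc.n), x, 0.0)
    cm = ContactMap.from_coo(*np.nonzero(x), x[np.nonzero(x)],
                             resolution=1, chrom="sim", n_bins=sc.n)
    return cm, GroundTruth(taus=taus, block_means=mu)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, nu: float) -> np.ndarray:
    """NB with mean ``mean`` and variance ``mean + nu mean^2``; Poisson at
    ``nu = 0``.  Parameterised as size ``1/nu``, success prob
    ``1/(1 + nu mean)``."""
    if nu == 0.0:
        return rng.poisson(mean).astype(np.float64)
    return rng.negative_binomial(1.0 / nu, 1.0 / (1.0 + nu * mean)).astype(np.float64)


def gen_sim4(sc: SimScenario) -> tuple[ContactMap, GroundTruth]:
    """Count design: blocks NB(mean ``mu_k``), background a 50/50 mixture of
    zero and NB with the smallest block mean."""
    rng = np.random.default_rng(sc.seed)
    taus = draw_changepoints(sc.n, sc.K, sc.min_gap, rng)
    mu = rng.gamma(sc.mean_shape, sc.mean_scale, size=sc.K + 1)
    labels = _block_labels(sc.n, taus)
    inblock = labels[:, None] == labels[None, :]
    mean = np.where(inblock, mu[labels][:, None], float(mu.min()))
    x = _nb_draw(rng, mean, sc.nu)
    dropout = rng.random(x.shape) < 0.5
    x = np.where(inblock, x, np.where(dropout, 0.0, x))
    x = np.where(_upper_mask(sc.n), x, 0.0)
    cm = ContactMap.from_coo(*np.nonzero(x), x[np.nonzero(x)],
                             resolution=1, chrom="sim", n_bins=sc.n)
    return cm, GroundTruth(taus=taus, block_means=mu)


def gen_nested(sc: SimScenario) -> tuple[ContactMap, GroundTruth]:
    """Nested design: outer blocks recursively subdivided, each nesting
    level multiplying the block mean by ``sub_mean_ratio``.

    Ground-truth hierarchy labels are emitted per level, level 1 being the
    coarsest (outer) partition; deeper levels refine it where a block was
    subdivided.  NB noise and background follow the count design.
    """
    rng = np.random.default_rng(sc.seed)
    taus_outer = draw_changepoints(sc.n, sc.K, sc.min_gap, rng)
    mu = rng.gamma(sc.mean_shape, sc.mean_scale, size=sc.K + 1)
    edges = np.concatenate(([0], taus_outer, [sc.n]))
    # intervals per level; level 1 = outer blocks
    levels: dict[int, list[tuple[int, int]]] = {
        1: [(int(edges[i]), int(edges[i + 1])) for i in range(len(edges) - 1)]}
    mean_map = {iv: mu[k] for k, iv in enumerate(levels[1])}
    for lev in range(2, sc.levels + 1):
        prev = levels[lev - 1]
        cur: list[tuple[int, int]] = []
        for (a, b) in prev:
            size = b - a
            if size >= 2 * sc.min_gap and rng.random() < sc.split_prob:
                m = int(rng.integers(a + sc.min_gap, b - sc.min_gap + 1))
                for child in ((a, m), (m, b)):
                    cur.append(child)
                    mean_map[child] = mean_map[(a, b)] * sc.sub_mean_ratio
            else:
                cur.append((a, b))
                mean_map.setdefault((a, b), mean_map[(a, b)])
        levels[lev] = cur
    # per-cell mean: deepest block containing both bins
    mean = np.full((sc.n, sc.n), float(mu.min()))
    inblock = np.zeros((sc.n, sc.n), dtype=bool)
    for lev in range(1, sc.levels + 1):
        for (a, b) in levels[lev]:
            mean[a:b, a:b] = mean_map[(a, b)]
            inblock[a:b, a:b] = True
    x = _nb_draw(rng, mean, sc.nu) if sc.nu > 0 else rng.poisson(mean).astype(float)
    dropout = rng.random(x.shape) < 0.5
    x = np.where(inblock, x, np.where(dropout, 0.0, x))
    x = np.where(_upper_mask(sc.n), x, 0.0)
    cm = ContactMap.from_coo(*np.nonzero(x), x[np.nonzero(x)],
                             resolution=1, chrom="sim", n_bins=sc.n)
    all_taus = sorted({a for ivs in levels.values() for (a, _) in ivs} - {0})
    hierarchy = {}
    for lev, ivs in levels.items():
        lab = np.zeros(sc.n, dtype=np.int64)
        for k, (a, b) in enumerate(sorted(ivs)):
            lab[a:b] = k
        hierarchy[lev] = lab
    return cm, GroundTruth(taus=np.asarray(all_taus, dtype=np.int64),
                           block_means=mu, hierarchy=hierarchy)


def generate(sc: SimScenario) -> tuple[ContactMap, GroundTruth]:
    """Dispatch on ``sc.family``."""
    if sc.family == "gaussian":
        return gen_sim3(sc)
    if sc.family == "poisson-nb":
        return gen_sim4(sc)
    return gen_nested(sc)
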