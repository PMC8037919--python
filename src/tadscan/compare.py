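"""Cross-sample boundary comparison.

Boundaries detected in two Hi-C samples are matched one-to-one within a
bin tolerance; each matched pair's per-sample p-values are combined by
Fisher's method (``chi^2_4 = -2 ln p1 - 2 ln p2``, chi-square with 4 df
under independence).  Matched pairs with a small combined p-value are
called conserved; unmatched boundaries are sample-specific.  Enrichment of
the overlap against a reference boundary set uses the upper-tail
hypergeometric test with all chromosomal bins as the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detect import DetectConfig
from .detect import _fixed_boundary_p
from .hic_io import ContactMap

__all__ = [
    "BoundaryMatch",
    "fisher_combine",
    "match_boundaries",
    "classify_boundaries",
    "enrichment_test",
    "boundary_pvalue_at",
]


@dataclass
class BoundaryMatch:
    """One boundary record in the two-sample comparison."""

    tau_a: int | None
    tau_b: int | None
    p1: float | None
    p2: float | None
    chi2_4: float | None
    p_f: float | None
    status: str                      # conserved | not-conserved | A-specific | B-specific

    @property
    def distance(self) -> int | None:
        if self.tau_a is None or self.tau_b is None:
            return None
        return abs(self.tau_a - self.tau_b)


def fisher_combine(p1: float, p2: float) -> tuple[float, float]:
    """Fisher's combination of two independent p-values.

    Returns ``(chi2_4, p_f)`` with ``chi2_4 = -2 ln p1 - 2 ln p2`` referred
    to a chi-square distribution with 4 degrees of freedom; symmetric and
    monotone decreasing in each argument.
    """
    for p in (p1, p2):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    chi2_4 = -2.0 * (np.log(p1) + np.log(p2))
    return float(chi2_4), float(stats.chi2.sf(chi2_4, df=4))


def _positions(seq) -> list[int]:
    return [b if isinstance(b, (int, np.integer)) else b.tau for b in seq]


def match_positions(pos_a, pos_b, tol: int = 2):
    """Greedy one-to-one matching of positions within ``tol`` bins.

    Candidate pairs are taken in ascending distance (ties towards the
    smaller first-sample position, then the smaller second-sample
    position); each position is used at most once.  Returns
    ``(pairs, a_only_idx, b_only_idx)`` as index lists.
    """
    pos_a, pos_b = list(pos_a), list(pos_b)
    cand = [(abs(a - b), a, b, i, j)
            for i, a in enumerate(pos_a)
            for j, b in enumerate(pos_b) if abs(a - b) <= tol]
    cand.sort()
    used_a, used_b, pairs = set(), set(), []
    for _, _, _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    a_only = [i for i in range(len(pos_a)) if i not in used_a]
    b_only = [j for j in range(len(pos_b)) if j not in used_b]
    return pairs, a_only, b_only


def match_boundaries(set_a, set_b, tol: int = 2):
    """One-to-one matching of two boundary lists (positions within ``tol``).

    Accepts :class:`~tadscan.detect.Boundary` objects or plain bin indices;
    returns ``(matches, a_only, b_only)`` where ``matches`` is a list of
    index pairs into the input sequences.
    """
    return match_positions(_positions(set_a), _positions(set_b), tol=tol)


def classify_boundaries(set_a, set_b, matches, a_only, b_only,
                        threshold: float = 0.01) -> list[BoundaryMatch]:
    """Label matched pairs as conserved when ``p_f < threshold``; unmatched
    boundaries become sample-specific records."""
    out = []
    for i, j in matches:
        ba, bb = set_a[i], set_b[j]
        chi2_4, p_f = fisher_combine(ba.p_boundary, bb.p_boundary)
        status = "conserved" if p_f < threshold else "not-conserved"
        out.append(BoundaryMatch(tau_a=ba.tau, tau_b=bb.tau,
                                 p1=ba.p_boundary, p2=bb.p_boundary,
                                 chi2_4=chi2_4, p_f=p_f, status=status))
    for i in a_only:
        b = set_a[i]
        out.append(BoundaryMatch(tau_a=b.tau, tau_b=None, p1=b.p_boundary,
                                 p2=None, chi2_4=None, p_f=None,
                                 status="A-specific"))
    for j in b_only:
        b = set_b[j]
        out.append(BoundaryMatch(tau_a=None, tau_b=b.tau, p1=None,
                                 p2=b.p_boundary, chi2_4=None, p_f=None,
                                 status="B-specific"))
    return out


def enrichment_test(n_population: int, n_success: int, n_sample: int,
                    n_overlap: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= n_overlap)``.

    Population: all chromosomal bins; successes: reference boundaries;
    sample: detected boundaries; sampled successes: the matched ones.
    """
    if not (0 <= n_success <= n_population and 0 <= n_sample <= n_population):
        raise ValueError("inconsistent hypergeometric parameters")
    if n_overlap < 0:
        raise ValueError("overlap cannot be negative")
    return float(stats.hypergeom.sf(n_overlap - 1, n_population,
                                    n_success, n_sample))


def boundary_pvalue_at(cm: ContactMap, tau: int, flank_a: int, flank_c: int,
                       cfg: DetectConfig | None = None) -> float:
    """Known-location boundary test of ``tau`` on window ``[flank_a,
    flank_c)`` of an arbitrary contact map.

    Lets a boundary found in one sample be scored at the same coordinate in
    another sample's matrix before calling it changed.
    """
    if cfg is None:
        cfg = DetectConfig()
    if not (flank_a < tau < flank_c):
        raise ValueError("need flank_a < tau < flank_c")
    return _fixed_boundary_p(cm, tau, flank_a, flank_c, cfg)
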