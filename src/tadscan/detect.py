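"""Hierarchical TAD detection: segmentation, pruning, bottom-up merging.

The pipeline has four stages:

1. **Binary segmentation** (top-down): the window with the largest scan
   statistic is split at its argmax, recursively, until windows fall below
   the ``2 xi + 1`` floor.  No testing happens here; every split is a
   candidate.
2. **Pruning** (reverse discovery order): each candidate is re-tested on the
   window delimited by its currently-surviving neighbours; insignificant
   candidates (max-null p-value above ``alpha0``) are removed, and surviving
   boundaries are re-estimated at the argmax of the re-run scan.
3. **Boundary p-values**: each survivor gets a known-location chi-square
   p-value from testing its two flanking blocks with the rectangle between
   them.
4. **Bottom-up merging**: adjacent blocks whose shared boundary p-value
   exceeds ``alpha1`` are merged greedily, largest p first; merged
   boundaries receive layer labels and the merge history becomes a forest
   of TAD nodes with root order 1.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .hic_io import ContactMap, RegionSummer
from .glr import (TestConfig, pvalue_fixed, pvalue_max, scan_max,
                  scan_stat_zm, P_FLOOR)
from .hic_io import RegionGeometry

__all__ = [
    "DetectConfig",
    "Candidate",
    "Boundary",
    "TADNode",
    "binary_segmentation",
    "prune",
    "boundary_pvalues",
    "build_hierarchy",
    "detect",
    "detect_random_first",
]


@dataclass
class DetectConfig:
    """Detection settings.

    ``alpha0`` controls how many candidate boundaries survive pruning;
    ``alpha1`` (default 1e-5) controls how aggressively blocks merge into
    hierarchies: raising it towards ``alpha0`` yields flatter output.
    """

    alpha0: float = 1e-3
    alpha1: float = 1e-5
    xi: int = 3
    test: TestConfig | None = None
    seed: int | None = None
    random_first: bool = False
    relocate: bool = True

    def __post_init__(self):
        if not (0 < self.alpha1 <= self.alpha0 <= 1):
            raise ValueError("need 0 < alpha1 <= alpha0 <= 1")
        if self.test is None:
            self.test = TestConfig(xi=self.xi)
        elif self.test.xi != self.xi:
            self.test.xi = self.xi


@dataclass
class Candidate:
    """A split recorded during segmentation, with its discovery context."""

    tau: int
    order: int          # discovery index (0 = first split of the matrix)
    window: tuple[int, int]
    z_tilde: float


@dataclass
class Boundary:
    """A detected change-point: first bin of the right-hand block."""

    tau: int
    p_detect: float = 1.0
    p_boundary: float = float("nan")
    layer: int = 0


@dataclass
class TADNode:
    """A node of the TAD hierarchy; children tile ``[start, end)`` exactly."""

    start: int
    end: int
    order: int = 0
    children: list = field(default_factory=list)
    id: int = -1
    parent_id: int | None = None


# ---------------------------------------------------------------------------
# Stage 1: binary segmentation
# ---------------------------------------------------------------------------

def binary_segmentation(cm: ContactMap, cfg: DetectConfig,
                        first_split: int | None = None) -> list[Candidate]:
    """Depth-first recursive splitting; returns candidates in discovery order.

    ``first_split`` overrides the argmax for the initial whole-matrix
    window (used by the random-initialisation robustness protocol).
    """
    candidates: list[Candidate] = []

    def recurse(s: int, e: int, forced: int | None):
        if e - s < 2 * cfg.xi + 1:
            return
        res = scan_max(cm, s, e, cfg.test)
        if res is None:
            return
        m = forced if forced is not None else res.m_star
        candidates.append(Candidate(tau=m, order=len(candidates),
                                    window=(s, e), z_tilde=res.z_tilde))
        recurse(s, m, None)
        recurse(m, e, None)

    if first_split is not None:
        lo, hi = cfg.xi + 1, cm.n_bins - cfg.xi
        if not (lo <= first_split <= hi):
            raise ValueError(f"first split {first_split} not admissible")
    recurse(0, cm.n_bins, first_split)
    return candidates


# ---------------------------------------------------------------------------
# Stage 2: pruning
# ---------------------------------------------------------------------------

def _scan_pvalue(z_tilde: float, cfg: DetectConfig) -> float:
    if cfg.test.null_mode == "fixed":
        return pvalue_fixed(z_tilde)
    return pvalue_max(z_tilde, cfg.test.table())


def prune(candidates: list[Candidate], cm: ContactMap,
          cfg: DetectConfig) -> list[Boundary]:
    """Remove insignificant candidates, testing in reverse discovery order.

    Each candidate is re-tested by the max scan over the window delimited by
    its currently-surviving neighbours (or the matrix ends); removals widen
    the neighbours' windows for subsequent re-tests.  A surviving boundary
    is re-estimated at the argmax of its re-run scan, unless that position
    coincides with another surviving boundary, in which case the original
    position is kept.
    """
    surviving: dict[int, int] = {c.order: c.tau for c in candidates}
    pvals: dict[int, float] = {}
    for cand in reversed(candidates):
        taus = sorted(t for o, t in surviving.items() if o != cand.order)
        tau = surviving[cand.order]
        k = bisect.bisect_left(taus, tau)
        left = taus[k - 1] if k > 0 else 0
        right = taus[k] if k < len(taus) else cm.n_bins
        res = scan_max(cm, left, right, cfg.test, include_left_edge=True)
        if res is None:
            del surviving[cand.order]
            continue
        p = _scan_pvalue(res.z_tilde, cfg)
        if p > cfg.alpha0:
            del surviving[cand.order]
            continue
        pvals[cand.order] = p
        if cfg.relocate and res.m_star != tau and res.m_star not in taus:
            surviving[cand.order] = res.m_star
    out = [Boundary(tau=t, p_detect=pvals[o]) for o, t in surviving.items()]
    out.sort(key=lambda b: b.tau)
    if cfg.relocate:
        out = _consolidate_tight_pairs(out, cm, cfg)
        out = _refine_to_fixed_point(out, cm, cfg)
    return out


def _refine_to_fixed_point(boundaries: list[Boundary], cm: ContactMap,
                           cfg: DetectConfig, max_sweeps: int = 5
                           ) -> list[Boundary]:
    """Re-test every surviving boundary on its final window until stable.

    During the reverse-order pass a boundary may have been re-estimated
    against a neighbour that was itself removed or moved later; one or two
    further sweeps against the settled delimiters fix such off-by-one
    placements.  Each sweep re-tests boundaries left to right, relocating
    to the window argmax and dropping any that lost significance.
    """
    for _ in range(max_sweeps):
        changed = False
        i = 0
        while i < len(boundaries):
            left = boundaries[i - 1].tau if i > 0 else 0
            right = (boundaries[i + 1].tau if i + 1 < len(boundaries)
                     else cm.n_bins)
            res = scan_max(cm, left, right, cfg.test, include_left_edge=True)
            if res is None:
                del boundaries[i]
                changed = True
                continue
            p = _scan_pvalue(res.z_tilde, cfg)
            if p > cfg.alpha0:
                del boundaries[i]
                changed = True
                continue
            if res.m_star != boundaries[i].tau:
                boundaries[i] = Boundary(tau=res.m_star, p_detect=p)
                changed = True
            else:
                boundaries[i].p_detect = p
            i += 1
        if not changed:
            break
        boundaries = _consolidate_tight_pairs(boundaries, cm, cfg)
    return boundaries


def _consolidate_tight_pairs(boundaries: list[Boundary], cm: ContactMap,
                             cfg: DetectConfig) -> list[Boundary]:
    """Collapse straddling detections left behind by sequential re-testing.

    When two surviving boundaries sit within ``2 xi`` bins of each other,
    the true change-point may lie between them yet be unreachable from
    either one's re-test window (each blocks the other).  The pair's joint
    window -- delimited by their outer neighbours -- is re-scanned: if the
    argmax falls strictly between the pair (or the pair violates the
    minimum gap ``xi``) and is significant, the pair is replaced by the
    single re-estimated boundary.  Genuine adjacent boundaries keep their
    positions because the joint scan peaks at one of them, not between.
    """
    changed, iters = True, 0
    while changed and iters < 10:
        changed, iters = False, iters + 1
        i = 0
        while i + 1 < len(boundaries):
            t1, t2 = boundaries[i].tau, boundaries[i + 1].tau
            if t2 - t1 > 2 * cfg.xi:
                i += 1
                continue
            left = boundaries[i - 1].tau if i > 0 else 0
            right = (boundaries[i + 2].tau if i + 2 < len(boundaries)
                     else cm.n_bins)
            res = scan_max(cm, left, right, cfg.test, include_left_edge=True)
            if res is None:
                i += 1
                continue
            p = _scan_pvalue(res.z_tilde, cfg)
            m = res.m_star
            collapse = p <= cfg.alpha0 and (t1 < m < t2 or t2 - t1 < cfg.xi)
            if collapse:
                boundaries[i:i + 2] = [Boundary(tau=m, p_detect=p)]
                changed = True
            else:
                i += 1
    return boundaries


# ---------------------------------------------------------------------------
# Stage 3: known-location boundary p-values
# ---------------------------------------------------------------------------

def _fixed_boundary_p(cm: ContactMap, tau: int, left: int, right: int,
                      cfg: DetectConfig) -> float:
    summer = RegionSummer(cm, left, right)
    sigma0, _ = summer.sigma0_sq()
    if cfg.test.sigma0_sq is not None:
        sigma0 = cfg.test.sigma0_sq
    z = scan_stat_zm(summer.sums(tau), RegionGeometry(left, right, tau), sigma0)
    if cfg.test.null_mode == "max":
        return pvalue_max(z, cfg.test.table())
    return pvalue_fixed(z)


def boundary_pvalues(boundaries: list[Boundary], cm: ContactMap,
                     cfg: DetectConfig) -> list[Boundary]:
    """Attach a known-location p-value to each boundary.

    Boundary ``tau_b`` is tested at its own position on the window spanned
    by its flanking boundaries (or matrix ends): the two blocks it separates
    plus the rectangle between them.
    """
    taus = [b.tau for b in boundaries]
    for i, b in enumerate(boundaries):
        left = taus[i - 1] if i > 0 else 0
        right = taus[i + 1] if i + 1 < len(taus) else cm.n_bins
        b.p_boundary = _fixed_boundary_p(cm, b.tau, left, right, cfg)
    return boundaries


# ---------------------------------------------------------------------------
# Stage 4: bottom-up hierarchy
# ---------------------------------------------------------------------------

def build_hierarchy(boundaries: list[Boundary], cm: ContactMap,
                    cfg: DetectConfig) -> tuple[list[Boundary], list[TADNode]]:
    """Merge adjacent blocks across weak boundaries into a TAD forest.

    Starting from the leaf blocks delimited by the boundaries, each round
    ranks the current inter-block boundary p-values in descending order and
    greedily merges non-conflicting adjacent pairs whose inner-boundary p
    exceeds ``alpha1`` (each block joins at most one merge per round;
    conflicts go to the larger p, ties to the left).  A merged boundary's
    layer label becomes one more than the deepest layer already interior to
    the merging blocks.  P-values of boundaries flanking newly formed
    blocks are then recomputed on the new geometry.  Iteration stops when
    no boundary satisfies the merge condition; remaining blocks become
    roots of order 1.
    """
    n = cm.n_bins
    edges = [0] + [b.tau for b in boundaries] + [n]
    leaves = [TADNode(start=edges[i], end=edges[i + 1])
              for i in range(len(edges) - 1)]
    blocks = [{"node": lv, "int_layer": 0} for lv in leaves]
    active = list(boundaries)              # active[i] separates blocks i, i+1
    p_cur = [b.p_boundary for b in active]

    while True:
        order = sorted(range(len(active)),
                       key=lambda i: (-p_cur[i], active[i].tau))
        used = [False] * len(blocks)
        merges = []
        for i in order:
            if p_cur[i] <= cfg.alpha1:
                continue
            if used[i] or used[i + 1]:
                continue
            used[i] = used[i + 1] = True
            merges.append(i)
        if not merges:
            break
        new_blocks, new_active, new_p = [], [], []
        changed = set()
        i = 0
        merge_left = set(merges)
        while i < len(blocks):
            if i in merge_left:
                L, R = blocks[i], blocks[i + 1]
                b = active[i]
                b.layer = 1 + max(L["int_layer"], R["int_layer"])
                parent = TADNode(start=L["node"].start, end=R["node"].end,
                                 children=[L["node"], R["node"]])
                new_blocks.append({"node": parent, "int_layer": b.layer})
                changed.add(len(new_blocks) - 1)
                i += 2
            else:
                new_blocks.append(blocks[i])
                i += 1
            if i < len(blocks):
                # boundary to the right of the block just emitted
                j = i - 1  # index of original boundary = index of left block
                new_active.append(active[j])
                new_p.append(p_cur[j])
        blocks, active, p_cur = new_blocks, new_active, new_p
        # recompute p-values of boundaries whose flanking geometry changed
        for k, b in enumerate(active):
            if k in changed or (k + 1) in changed:
                p_cur[k] = _fixed_boundary_p(
                    cm, b.tau, blocks[k]["node"].start,
                    blocks[k + 1]["node"].end, cfg)

    forest = [blk["node"] for blk in blocks]
    _assign_orders_ids(forest)
    return boundaries, forest


def _assign_orders_ids(forest: list[TADNode]) -> None:
    next_id = 0
    stack = [(node, 1, None) for node in reversed(forest)]
    while stack:
        node, order, parent = stack.pop()
        node.order = order
        node.id = next_id
        node.parent_id = parent
        next_id += 1
        for child in reversed(node.children):
            stack.append((child, order + 1, node.id))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def detect(cm: ContactMap, cfg: DetectConfig | None = None
           ) -> tuple[list[Boundary], list[TADNode]]:
    """Full pipeline: segment, prune, re-test, build the hierarchy."""
    if cfg is None:
        cfg = DetectConfig()
    candidates = binary_segmentation(cm, cfg)
    boundaries = prune(candidates, cm, cfg)
    boundaries = boundary_pvalues(boundaries, cm, cfg)
    return build_hierarchy(boundaries, cm, cfg)


def detect_random_first(cm: ContactMap, cfg: DetectConfig | None = None,
                        seed: int | None = None
                        ) -> tuple[list[Boundary], list[TADNode]]:
    """Like :func:`detect` but the first split of the whole matrix is drawn
    uniformly from the admissible positions; pruning may later remove or
    re-estimate it."""
    if cfg is None:
        cfg = DetectConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    lo, hi = cfg.xi + 1, cm.n_bins - cfg.xi
    if hi < lo:
        return detect(cm, cfg)
    first = int(rng.integers(lo, hi + 1))
    candidates = binary_segmentation(cm, cfg, first_split=first)
    boundaries = prune(candidates, cm, cfg)
    boundaries = boundary_pvalues(boundaries, cm, cfg)
    return build_hierarchy(boundaries, cm, cfg)
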