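"""Contact-map I/O and fast region-sum queries over diagonal windows.

A Hi-C experiment on one chromosome yields a symmetric ``n x n`` matrix of
contact counts between fixed-width genomic bins.  Only the upper-triangular
non-zeros are stored (high-resolution matrices are overwhelmingly sparse),
and the change-point scan only ever needs sums of matrix values over three
regions of a diagonal window ``[s, e)`` split at ``m``:

* ``A1`` -- the triangle ``{(i, j): s <= i <= j < m}``,
* ``A2`` -- the triangle ``{(i, j): m <= i <= j < e}``,
* ``R``  -- the rectangle ``{(i, j): s <= i < m <= j < e}`` between them.

:class:`RegionSummer` precomputes cumulative row/column sums of the window so
that the sums for every split ``m`` come out of two lookups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ContactMap",
    "RegionGeometry",
    "RegionSums",
    "RegionSummer",
    "read_contacts_list",
    "read_contacts_dense",
    "write_contacts_list",
    "write_contacts_dense",
    "build_region_summer",
    "region_sums",
    "write_boundaries",
    "trim_zero_margins",
]

#: windows up to this many bins are materialised densely for speed
DENSE_LIMIT = 2048


class HiCIOError(ValueError):
    """Raised for malformed contact-matrix input."""


# ---------------------------------------------------------------------------
# ContactMap
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Sparse symmetric per-chromosome contact matrix at fixed resolution.

    Entries are stored once, on the upper triangle (``i <= j``), with float
    values so that normalised (KR/ICE) matrices are accepted; the scan never
    requires integer counts.
    """

    chrom: str
    resolution: int
    n_bins: int
    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray
    _dense: np.ndarray | None = field(default=None, repr=False, compare=False)
    _csr: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_coo(cls, rows, cols, vals, *, resolution: int, chrom: str = "chr",
                 n_bins: int | None = None) -> "ContactMap":
        """Build a canonical map from (possibly unordered, duplicated) triples.

        Lower-triangular triples are mirrored onto the upper triangle and
        duplicate ``(i, j)`` keys are summed.  Explicit zeros are dropped.
        """
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        vals = np.asarray(vals, dtype=np.float64)
        if rows.size:
            if rows.min() < 0 or cols.min() < 0:
                raise HiCIOError("negative bin index")
            lo = np.minimum(rows, cols)
            hi = np.maximum(rows, cols)
            rows, cols = lo, hi
        if n_bins is None:
            n_bins = int(max(rows.max(initial=-1), cols.max(initial=-1)) + 1)
            n_bins = max(n_bins, 1)
        elif rows.size and cols.max() >= n_bins:
            raise HiCIOError(
                f"entry at bin {int(cols.max())} exceeds n_bins={n_bins}")
        # merge duplicates by lexicographic key
        if rows.size:
            order = np.lexsort((cols, rows))
            rows, cols, vals = rows[order], cols[order], vals[order]
            key = rows * n_bins + cols
            uniq, inv = np.unique(key, return_inverse=True)
            merged = np.zeros(uniq.size, dtype=np.float64)
            np.add.at(merged, inv, vals)
            rows = (uniq // n_bins).astype(np.int64)
            cols = (uniq % n_bins).astype(np.int64)
            vals = merged
            nz = vals != 0.0
            rows, cols, vals = rows[nz], cols[nz], vals[nz]
        return cls(chrom=chrom, resolution=int(resolution), n_bins=int(n_bins),
                   rows=rows, cols=cols, vals=vals)

    @classmethod
    def from_dense(cls, arr, *, resolution: int, chrom: str = "chr") -> "ContactMap":
        """Build from a dense symmetric matrix; keeps upper-triangular non-zeros."""
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise HiCIOError("dense contact matrix must be square")
        scale = np.abs(arr).max() if arr.size else 0.0
        if scale > 0 and np.abs(arr - arr.T).max() > 1e-6 * scale:
            raise HiCIOError("dense contact matrix is not symmetric")
        i, j = np.nonzero(np.triu(arr))
        return cls.from_coo(i, j, arr[i, j], resolution=resolution,
                            chrom=chrom, n_bins=arr.shape[0])

    # -- basic queries -----------------------------------------------------

    @property
    def total(self) -> float:
        """Sum of all upper-triangular entries."""
        return float(self.vals.sum())

    @property
    def n_nonzero(self) -> int:
        return int(self.vals.size)

    def value_at(self, i: int, j: int) -> float:
        """Value at ``(i, j)``; symmetric, absent keys read as 0."""
        if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
            raise IndexError("bin index out of range")
        if i > j:
            i, j = j, i
        lo = np.searchsorted(self.rows, i, side="left")
        hi = np.searchsorted(self.rows, i, side="right")
        k = lo + np.searchsorted(self.cols[lo:hi], j, side="left")
        if k < hi and self.cols[k] == j:
            return float(self.vals[k])
        return 0.0

    def dense_upper(self) -> np.ndarray:
        """Dense ``n x n`` array holding the upper triangle (zeros below)."""
        if self._dense is None:
            d = np.zeros((self.n_bins, self.n_bins), dtype=np.float64)
            d[self.rows, self.cols] = self.vals
            self._dense = d
        return self._dense

    def upper_csr(self) -> sp.csr_matrix:
        if self._csr is None:
            self._csr = sp.csr_matrix(
                (self.vals, (self.rows, self.cols)),
                shape=(self.n_bins, self.n_bins))
        return self._csr

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense matrix (diagonal counted once)."""
        u = self.dense_upper().copy()
        return u + np.triu(u, 1).T


# ---------------------------------------------------------------------------
# Region geometry and sums
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionGeometry:
    """Cell counts of the three regions of window ``[s, e)`` split at ``m``."""

    s: int
    e: int
    m: int

    def __post_init__(self):
        if not (self.s < self.m < self.e):
            raise ValueError(f"need s < m < e, got {(self.s, self.m, self.e)}")

    @property
    def n_a1(self) -> int:
        g = self.m - self.s
        return g * (g + 1) // 2

    @property
    def n_a2(self) -> int:
        h = self.e - self.m
        return h * (h + 1) // 2

    @property
    def n_r(self) -> int:
        return (self.m - self.s) * (self.e - self.m)

    @property
    def n_a(self) -> int:
        w = self.e - self.s
        return w * (w + 1) // 2


@dataclass(frozen=True)
class RegionSums:
    """Sums of matrix values over ``A1``, ``A2``, ``R`` and their union."""

    s_a1: float
    s_a2: float
    s_r: float

    @property
    def s_a(self) -> float:
        return self.s_a1 + self.s_a2 + self.s_r


class RegionSummer:
    """Incremental region sums over a diagonal window ``[s, e)``.

    One ``O(window)`` pass builds cumulative triangular column sums and
    cumulative row sums; every split ``m`` is then answered in constant time.
    """

    def __init__(self, cm: ContactMap, s: int, e: int):
        if not (0 <= s < e <= cm.n_bins):
            raise ValueError(f"window [{s}, {e}) out of range for n={cm.n_bins}")
        self.cm = cm
        self.s, self.e = int(s), int(e)
        w = self.e - self.s
        if cm.n_bins <= DENSE_LIMIT:
            W = cm.dense_upper()[s:e, s:e]
            col_tri = W.sum(axis=0)          # sum_{i<=c} w[i, c]
            row_full = W.sum(axis=1)         # sum_{j>=r} w[r, j]
            self._sumsq = float((W * W).sum())
        else:
            Wc = cm.upper_csr()[s:e, s:e]
            col_tri = np.asarray(Wc.sum(axis=0)).ravel()
            row_full = np.asarray(Wc.sum(axis=1)).ravel()
            self._sumsq = float(Wc.power(2).sum())
        self._cum_col = np.concatenate(([0.0], np.cumsum(col_tri)))
        self._cum_row = np.concatenate(([0.0], np.cumsum(row_full)))
        self.s_a = float(self._cum_col[-1])
        self.n_cells = w * (w + 1) // 2

    def sums(self, m: int) -> RegionSums:
        """Region sums for split ``m`` (``s < m < e``)."""
        if not (self.s < m < self.e):
            raise ValueError(f"split m={m} outside ({self.s}, {self.e})")
        k = m - self.s
        s_a1 = float(self._cum_col[k])        # columns s..m-1, triangle
        s_a1r = float(self._cum_row[k])       # rows s..m-1, all j >= i
        return RegionSums(s_a1=s_a1, s_a2=self.s_a - s_a1r, s_r=s_a1r - s_a1)

    def sums_vector(self, ms: np.ndarray):
        """Vectorised ``(S_A1, S_{A1 u R}, S_A)`` for an array of splits."""
        k = np.asarray(ms) - self.s
        return self._cum_col[k], self._cum_row[k], self.s_a

    def sigma0_sq(self, floor: float = 1e-8):
        """Unbiased variance of all window cells (zeros included).

        Returns ``(variance, degenerate)``; a constant window is flagged
        degenerate and floored so downstream ratios stay finite.
        """
        n = self.n_cells
        if n < 2:
            raise ValueError("window needs at least 2 cells to estimate variance")
        var = (self._sumsq - self.s_a ** 2 / n) / (n - 1)
        var = max(var, 0.0)
        if var <= 0.0:
            return floor, True
        return float(var), False

    def mean(self) -> float:
        return self.s_a / self.n_cells


def build_region_summer(cm: ContactMap, s: int, e: int) -> RegionSummer:
    return RegionSummer(cm, s, e)


def region_sums(rs: RegionSummer, m: int) -> RegionSums:
    return rs.sums(m)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_list_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            t = line.strip()
            if not t or t.startswith("#"):
                continue
            parts = t.split()
            if len(parts) != 3:
                raise HiCIOError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                a, b, v = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError:
                raise HiCIOError(f"{path}:{lineno}: non-numeric field") from None
            yield lineno, a, b, v


def read_contacts_list(path, resolution: int, chrom: str = "chr", *,
                       positions: str = "bp", n_bins: int | None = None) -> ContactMap:
    """Read a sparse coordinate list ``pos_i pos_j value``.

    Positions are bin-start genomic coordinates in bp (the convention of
    public intrachromosomal contact dumps) unless ``positions='bin'``, in
    which case they are already 0-based bin indices.  Lower-triangular
    records are mirrored and duplicate keys are summed.
    """
    if positions not in ("bp", "bin"):
        raise ValueError("positions must be 'bp' or 'bin'")
    rows, cols, vals = [], [], []
    for lineno, a, b, v in _parse_list_lines(path):
        if not (math.isfinite(a) and math.isfinite(b) and math.isfinite(v)):
            raise HiCIOError(f"{path}:{lineno}: non-finite field")
        if v < 0:
            raise HiCIOError(f"{path}:{lineno}: negative contact value {v}")
        if positions == "bp":
            if a % resolution or b % resolution:
                raise HiCIOError(
                    f"{path}:{lineno}: position not divisible by resolution {resolution}")
            i, j = int(a // resolution), int(b // resolution)
        else:
            if a != int(a) or b != int(b):
                raise HiCIOError(f"{path}:{lineno}: non-integer bin index")
            i, j = int(a), int(b)
        rows.append(i)
        cols.append(j)
        vals.append(v)
    return ContactMap.from_coo(rows, cols, vals, resolution=resolution,
                               chrom=chrom, n_bins=n_bins)


def read_contacts_dense(path, resolution: int, chrom: str = "chr") -> ContactMap:
    """Read a whitespace-separated square symmetric matrix."""
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            t = line.strip()
            if not t or t.startswith("#"):
                continue
            try:
                r = [float(x) for x in t.split()]
            except ValueError:
                raise HiCIOError(f"{path}:{lineno}: non-numeric field") from None
            if width is None:
                width = len(r)
            elif len(r) != width:
                raise HiCIOError(f"{path}:{lineno}: ragged row "
                                 f"({len(r)} fields, expected {width})")
            rows.append(r)
    if not rows:
        raise HiCIOError(f"{path}: empty matrix")
    arr = np.asarray(rows, dtype=np.float64)
    if arr.shape[0] != arr.shape[1]:
        raise HiCIOError(f"{path}: matrix is {arr.shape[0]}x{arr.shape[1]}, not square")
    return ContactMap.from_dense(arr, resolution=resolution, chrom=chrom)


def write_contacts_list(cm: ContactMap, path, *, positions: str = "bp") -> None:
    mult = cm.resolution if positions == "bp" else 1
    with open(path, "w") as fh:
        fh.write(f"# tadscan contacts chrom={cm.chrom} resolution={cm.resolution} "
                 f"n_bins={cm.n_bins} positions={positions}\n")
        for i, j, v in zip(cm.rows, cm.cols, cm.vals):
            fh.write(f"{i * mult}\t{j * mult}\t{v:.10g}\n")


def write_contacts_dense(cm: ContactMap, path) -> None:
    arr = cm.to_dense()
    with open(path, "w") as fh:
        for row in arr:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def write_boundaries(boundaries, tree, resolution: int, chrom: str,
                     prefix, *, header_extra: str = "") -> tuple[str, str]:
    """Write the boundary table and a BED-like TAD table.

    Returns the two file paths (``<prefix>.boundaries.tsv`` and
    ``<prefix>.tads.bed``).  Boundary table columns: chrom, bin, genomic
    position (bin * resolution), detection and boundary p-values, layer.
    TAD table columns: chrom, start, end (half-open bp), order, id, parent id.
    """
    bpath = f"{prefix}.boundaries.tsv"
    tpath = f"{prefix}.tads.bed"
    head = f"# tadscan v0.1.0 chrom={chrom} resolution={resolution}"
    if header_extra:
        head += " " + header_extra
    with open(bpath, "w") as fh:
        fh.write(head + "\n")
        fh.write("# chrom\tbin\tpos\tp_detect\tp_boundary\tlayer\n")
        for b in boundaries:
            fh.write(f"{chrom}\t{b.tau}\t{b.tau * resolution}\t"
                     f"{b.p_detect:.6g}\t{b.p_boundary:.6g}\t{b.layer}\n")
    with open(tpath, "w") as fh:
        fh.write(head + "\n")
        fh.write("# chrom\tstart\tend\torder\tid\tparent\n")
        for node in _iter_nodes(tree):
            parent = node.parent_id if node.parent_id is not None else "."
            fh.write(f"{chrom}\t{node.start * resolution}\t{node.end * resolution}\t"
                     f"{node.order}\t{node.id}\t{parent}\n")
    return bpath, tpath


def _iter_nodes(forest):
    stack = list(forest)[::-1]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def trim_zero_margins(cm: ContactMap) -> tuple[ContactMap, int]:
    """Drop all-zero leading/trailing bins; returns the trimmed map and the
    offset to add to trimmed bin indices to recover original coordinates."""
    if cm.n_nonzero == 0:
        return cm, 0
    touched = np.zeros(cm.n_bins, dtype=bool)
    touched[cm.rows] = True
    touched[cm.cols] = True
    first = int(np.argmax(touched))
    last = int(cm.n_bins - np.argmax(touched[::-1]))
    trimmed = ContactMap.from_coo(cm.rows - first, cm.cols - first, cm.vals,
                                  resolution=cm.resolution, chrom=cm.chrom,
                                  n_bins=last - first)
    return trimmed, first
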