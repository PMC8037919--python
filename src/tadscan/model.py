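"""Model/Results interface over the detection pipeline.

:class:`TADModel` holds one contact map plus the test configuration;
``fit()`` runs segmentation, pruning, boundary re-testing and hierarchy
construction and returns a :class:`TADResults` carrying the boundaries
(with p-values and layer labels), the TAD forest, and summary tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detect import (DetectConfig, TADNode, detect as _run_detect,
                     detect_random_first as _run_detect_random_first)
from .glr import TestConfig, min_tad_bins, NullTable
from .hic_io import (ContactMap, read_contacts_dense, read_contacts_list,
                     write_boundaries, _iter_nodes)

__all__ = ["TADModel", "TADResults"]


class TADModel:
    """Hierarchical change-point model of TAD structure in one contact map.

    Parameters
    ----------
    contact_map : ContactMap
        Symmetric per-chromosome matrix at fixed resolution.
    xi : int, optional
        Minimum TAD size in bins; defaults to ``ceil(min_tad_bp /
        resolution)`` when the map carries a bp resolution > 1, else 3.
    alpha0, alpha1 : float
        Pruning and merge thresholds (``alpha1 <= alpha0``).
    null_table : NullTable, optional
        Monte-Carlo table for the max-statistic null; generated (and cached
        per process) on demand.
    null_mode : str
        'auto' (max null for detection, chi-square for known-location
        re-tests), or force 'max' / 'fixed' everywhere.
    """

    def __init__(self, contact_map: ContactMap, *, xi: int | None = None,
                 alpha0: float = 1e-3, alpha1: float = 1e-5,
                 null_table: NullTable | None = None, null_mode: str = "auto",
                 min_tad_bp: int = 100_000):
        self.data = contact_map
        if xi is None:
            xi = (min_tad_bins(contact_map.resolution, min_tad_bp)
                  if contact_map.resolution > 1 else 3)
        self.config = DetectConfig(
            alpha0=alpha0, alpha1=alpha1, xi=xi,
            test=TestConfig(xi=xi, null_table=null_table, null_mode=null_mode))

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_array(cls, arr, resolution: int = 1, chrom: str = "chr",
                   **kwargs) -> "TADModel":
        return cls(ContactMap.from_dense(np.asarray(arr), resolution=resolution,
                                         chrom=chrom), **kwargs)

    @classmethod
    def from_dense_file(cls, path, resolution: int, chrom: str = "chr",
                        **kwargs) -> "TADModel":
        return cls(read_contacts_dense(path, resolution, chrom), **kwargs)

    @classmethod
    def from_list_file(cls, path, resolution: int, chrom: str = "chr",
                       positions: str = "bp", **kwargs) -> "TADModel":
        return cls(read_contacts_list(path, resolution, chrom,
                                      positions=positions), **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self, *, random_first: bool = False,
            seed: int | None = None) -> "TADResults":
        """Run the detection pipeline; deterministic unless ``random_first``."""
        if random_first:
            boundaries, forest = _run_detect_random_first(
                self.data, self.config, seed=seed)
        else:
            boundaries, forest = _run_detect(self.data, self.config)
        return TADResults(self, boundaries, forest)


class TADResults:
    """Fitted TAD hierarchy: boundaries, p-values, layers and the forest."""

    def __init__(self, model: TADModel, boundaries, forest):
        self.model = model
        self.boundaries = boundaries
        self.forest = forest

    @property
    def taus(self) -> np.ndarray:
        return np.asarray([b.tau for b in self.boundaries], dtype=np.int64)

    @property
    def n_boundaries(self) -> int:
        return len(self.boundaries)

    @property
    def n_tads(self) -> int:
        return sum(1 for _ in _iter_nodes(self.forest))

    def boundary_table(self) -> pd.DataFrame:
        cm = self.model.data
        return pd.DataFrame({
            "chrom": cm.chrom,
            "bin": self.taus,
            "pos": self.taus * cm.resolution,
            "p_detect": [b.p_detect for b in self.boundaries],
            "p_boundary": [b.p_boundary for b in self.boundaries],
            "layer": [b.layer for b in self.boundaries],
        })

    def tad_table(self) -> pd.DataFrame:
        cm = self.model.data
        rows = [(cm.chrom, node.start * cm.resolution, node.end * cm.resolution,
                 node.order, node.id,
                 node.parent_id if node.parent_id is not None else -1)
                for node in _iter_nodes(self.forest)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "order",
                                           "id", "parent"])

    def save(self, prefix, header_extra: str = "") -> tuple[str, str]:
        cm = self.model.data
        return write_boundaries(self.boundaries, self.forest, cm.resolution,
                                cm.chrom, prefix, header_extra=header_extra)

    def summary(self) -> str:
        cm = self.model.data
        cfg = self.model.config
        orders = [n.order for n in _iter_nodes(self.forest)]
        lines = [
            "Hierarchical TAD detection",
            "==========================",
            f"chrom: {cm.chrom}   bins: {cm.n_bins}   "
            f"resolution: {cm.resolution} bp   nnz: {cm.n_nonzero}",
            f"xi (min TAD size): {cfg.xi} bins   "
            f"alpha0: {cfg.alpha0:g}   alpha1: {cfg.alpha1:g}",
            f"boundaries: {self.n_boundaries}   TAD nodes: {self.n_tads}   "
            f"max order: {max(orders) if orders else 0}",
            "",
            self.boundary_table().to_string(index=False, max_rows=20),
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<TADResults: {self.n_boundaries} boundaries, "
                f"{self.n_tads} TAD nodes>")
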