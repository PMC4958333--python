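"""Whole-mount quantification statistics: clone calling, densities, fractions.

Clone calling groups labelled cells into putative clones under the rule that
all members of a clone lie within a characteristic dermal distance D of each
other (every within-clone pairwise distance <= D; by Jung's theorem such a
set fits in a circle of diameter <= 2D/sqrt(3)).  Cells are first split into
connected components of the distance-threshold graph; within each component
the partition is the exact minimum-clique-cover of the threshold graph
("maximal merging": fewest clones), with deterministic tie-breaks — smallest
total within-clone pairwise distance, then lexicographically smallest
canonical form by cell id.  Components larger than ``exact_max_n`` fall back
to complete-linkage agglomerative clustering cut at D (scipy), which also
guarantees the pairwise constraint but may occasionally produce one clone
more than the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .morphometry import COMPARTMENTS

_DIST_DECIMALS = 6  # tie-break distance sums are compared after rounding


@dataclass(frozen=True)
class CloneCallingParams:
    """Distance-cutoff clone-calling parameters.

    cutoff_um is the characteristic distance D (260 µm by default).  With
    cutoff_mode="diameter", D itself bounds every within-clone pairwise
    distance; with "radius" the effective bound is 2*D.  tolerance_um is the
    ±band for sensitivity sweeps (the criterion is quoted as 260±50 µm).
    Distances are computed in the horizontal whole-mount plane ("xy") by
    default; "xyz" is selectable.
    """

    cutoff_um: float = 260.0
    cutoff_mode: str = "diameter"
    tolerance_um: float = 50.0
    projection: str = "xy"

    def __post_init__(self) -> None:
        if self.cutoff_um <= 0:
            raise ValueError("cutoff_um must be positive")
        if self.tolerance_um < 0:
            raise ValueError("tolerance_um must be non-negative")
        if self.cutoff_mode not in ("diameter", "radius"):
            raise ValueError("cutoff_mode must be 'diameter' or 'radius'")
        if self.projection not in ("xy", "xyz"):
            raise ValueError("projection must be 'xy' or 'xyz'")

    def effective_cutoff_um(self) -> float:
        return self.cutoff_um if self.cutoff_mode == "diameter" else 2.0 * self.cutoff_um


@dataclass
class CloneTable:
    """Clone-call assignments plus per-compartment size counts.

    assignments maps cell_id -> clone-call id (the smallest member cell_id);
    sizes holds cells per clone per compartment and a 'total' column.
    """

    assignments: pd.Series
    members: pd.DataFrame
    sizes: pd.DataFrame

    @property
    def n_clones(self) -> int:
        return int(self.assignments.nunique()) if len(self.assignments) else 0

    def clone_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


# ---------------------------------------------------------------------------
# exact minimum-diameter-constrained partition
# ---------------------------------------------------------------------------

def _cliques_containing_lowest(
    mask: int, adj: Sequence[int], n: int
) -> List[Tuple[int, Tuple[int, ...]]]:
    """All cliques within ``mask`` that contain its lowest set bit."""
    low = (mask & -mask).bit_length() - 1
    out: List[Tuple[int, Tuple[int, ...]]] = []

    def rec(cmask: int, members: Tuple[int, ...], allowed: int) -> None:
        out.append((cmask, members))
        a = allowed
        while a:
            v = (a & -a).bit_length() - 1
            a &= a - 1
            rec(cmask | (1 << v), members + (v,), allowed & adj[v] & ~((1 << (v + 1)) - 1))

    rec(1 << low, (low,), mask & adj[low] & ~((1 << (low + 1)) - 1))
    return out


def _min_diameter_partition(
    dmat: np.ndarray, cutoff: float
) -> List[Tuple[int, ...]]:
    """Exact maximal-merging partition of one component (indices 0..n-1).

    Minimises (number of blocks, total within-block pairwise distance rounded
    to 1e-6, lexicographic canonical form).  Every block satisfies
    max pairwise distance <= cutoff.  Exponential in n; callers cap n.
    """
    n = dmat.shape[0]
    ok = dmat <= cutoff
    adj = [0] * n
    for i in range(n):
        m = 0
        for j in range(n):
            if i != j and ok[i, j]:
                m |= 1 << j
        adj[i] = m

    def block_dist(members: Tuple[int, ...]) -> float:
        s = 0.0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                s += dmat[members[a], members[b]]
        return s

    value_memo: Dict[int, Tuple[int, float]] = {0: (0, 0.0)}
    choice_memo: Dict[int, Tuple[int, ...]] = {}

    def best(mask: int) -> Tuple[int, float]:
        cached = value_memo.get(mask)
        if cached is not None:
            return cached
        best_val: Optional[Tuple[int, float]] = None
        best_members: Optional[Tuple[int, ...]] = None
        for cmask, members in _cliques_containing_lowest(mask, adj, n):
            rest_n, rest_d = best(mask & ~cmask)
            val = (1 + rest_n, round(block_dist(members) + rest_d, _DIST_DECIMALS))
            if best_val is None or val < best_val or (
                val == best_val and members < best_members  # type: ignore[operator]
            ):
                best_val, best_members = val, members
        assert best_val is not None and best_members is not None
        value_memo[mask] = best_val
        choice_memo[mask] = best_members
        return best_val

    full = (1 << n) - 1
    best(full)
    blocks: List[Tuple[int, ...]] = []
    mask = full
    while mask:
        members = choice_memo[mask]
        blocks.append(members)
        for v in members:
            mask &= ~(1 << v)
    return blocks


class CloneCaller(ClusterMixin, BaseEstimator):
    """Distance-cutoff clone calling as a scikit-learn clusterer.

    Parameters mirror :class:`CloneCallingParams`.  ``fit`` takes an (n, 2) or
    (n, 3) coordinate array in µm (rows in cell-id order for deterministic
    tie-breaking) and exposes ``labels_`` with clusters numbered by the order
    of their smallest member row.
    """

    def __init__(
        self,
        cutoff_um: float = 260.0,
        cutoff_mode: str = "diameter",
        tolerance_um: float = 50.0,
        projection: str = "xy",
        exact_max_n: int = 12,
    ):
        self.cutoff_um = cutoff_um
        self.cutoff_mode = cutoff_mode
        self.tolerance_um = tolerance_um
        self.projection = projection
        self.exact_max_n = exact_max_n

    def _params(self) -> CloneCallingParams:
        return CloneCallingParams(
            cutoff_um=self.cutoff_um,
            cutoff_mode=self.cutoff_mode,
            tolerance_um=self.tolerance_um,
            projection=self.projection,
        )

    def fit(self, X, y=None):
        params = self._params()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] not in (2, 3):
            raise ValueError("X must be an (n, 2) or (n, 3) coordinate array")
        if not np.isfinite(X).all():
            raise ValueError("coordinates must be finite (NaN/inf found)")
        if params.projection == "xy":
            X = X[:, :2]
        n = X.shape[0]
        cutoff = params.effective_cutoff_um()
        self.effective_cutoff_um_ = cutoff
        if n == 0:
            self.labels_ = np.array([], dtype=int)
            self.n_clusters_ = 0
            return self
        if n == 1:
            self.labels_ = np.zeros(1, dtype=int)
            self.n_clusters_ = 1
            return self
        dmat = squareform(pdist(X))
        graph = csr_matrix(dmat <= cutoff)
        n_comp, comp = connected_components(graph, directed=False)
        labels = np.full(n, -1, dtype=int)
        next_label = 0
        for c in range(n_comp):
            idx = np.flatnonzero(comp == c)  # ascending row order == id order
            if len(idx) == 1:
                labels[idx] = next_label
                next_label += 1
                continue
            sub = dmat[np.ix_(idx, idx)]
            if len(idx) <= self.exact_max_n:
                blocks = _min_diameter_partition(sub, cutoff)
            else:
                z = linkage(squareform(sub, checks=False), method="complete")
                fl = fcluster(z, t=cutoff, criterion="distance")
                blocks = [
                    tuple(np.flatnonzero(fl == lab)) for lab in np.unique(fl)
                ]
            # number blocks by smallest member (global row order)
            for members in sorted(blocks, key=lambda b: min(b)):
                labels[idx[list(members)]] = next_label
                next_label += 1
        # renumber clusters by order of smallest member row
        order = {}
        for row in range(n):
            order.setdefault(labels[row], len(order))
        self.labels_ = np.array([order[l] for l in labels], dtype=int)
        self.n_clusters_ = len(order)
        return self


def call_clones(
    cells: pd.DataFrame, params: Optional[CloneCallingParams] = None
) -> CloneTable:
    """Partition labelled cells into clone calls under the distance cutoff.

    ``cells`` needs columns cell_id, x_um, y_um (z_um for projection="xyz");
    a ``layer`` column, if present, feeds the per-compartment size table.
    Clone-call ids are the smallest member cell_id; the result is invariant
    to row order.
    """
    if params is None:
        params = CloneCallingParams()
    required = {"cell_id", "x_um", "y_um"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table missing columns: {sorted(missing)}")
    if cells.empty:
        empty = pd.Series(dtype=np.int64, name="clone_call")
        return CloneTable(
            assignments=empty,
            members=cells.copy(),
            sizes=pd.DataFrame(columns=list(COMPARTMENTS) + ["total"]),
        )
    cells = cells.sort_values("cell_id").reset_index(drop=True)
    if cells["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique")
    cols = ["x_um", "y_um"] + (["z_um"] if params.projection == "xyz" else [])
    if params.projection == "xyz" and "z_um" not in cells.columns:
        raise ValueError("projection='xyz' requires a z_um column")
    coords = cells[cols].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite (NaN/inf found)")
    caller = CloneCaller(
        cutoff_um=params.cutoff_um,
        cutoff_mode=params.cutoff_mode,
        tolerance_um=params.tolerance_um,
        projection=params.projection,
    )
    labels = caller.fit(coords).labels_
    ids = cells["cell_id"].to_numpy()
    call_id = np.empty(len(ids), dtype=np.int64)
    for lab in np.unique(labels):
        members = labels == lab
        call_id[members] = ids[members].min()
    assignments = pd.Series(call_id, index=pd.Index(ids, name="cell_id"), name="clone_call")
    members = cells.copy()
    members["clone_call"] = call_id
    sizes = _sizes_by_compartment(members)
    table = CloneTable(assignments=assignments, members=members, sizes=sizes)
    # every labelled cell assigned exactly once; sizes sum to member count
    assert table.sizes["total"].sum() == len(members)
    return table


def _sizes_by_compartment(members: pd.DataFrame) -> pd.DataFrame:
    calls = pd.Index(np.unique(members["clone_call"]), name="clone_call")
    sizes = pd.DataFrame(0, index=calls, columns=list(COMPARTMENTS))
    if "layer" in members.columns:
        counts = members.groupby(["clone_call", "layer"]).size().unstack(fill_value=0)
        for col in counts.columns:
            if col in sizes.columns:
                sizes[col] = counts[col].reindex(calls, fill_value=0)
    sizes["total"] = members.groupby("clone_call").size().reindex(calls, fill_value=0)
    return sizes


def clone_sizes_by_compartment(clone_table: CloneTable) -> pd.DataFrame:
    """Mean ± sd of cells per clone, per compartment (zeros counted).

    Every clone contributes its count in every compartment (0 when absent),
    matching per-clone-per-compartment quantification; 'total' is the overall
    cells-per-clone statistic.  Unknown layer labels are a data error.
    """
    members = clone_table.members
    if "layer" not in members.columns:
        raise ValueError("cells table has no layer column")
    known = set(COMPARTMENTS)
    bad = set(members["layer"].unique()) - known
    if bad:
        raise ValueError(f"unknown layer labels: {sorted(bad)} (expected {sorted(known)})")
    sizes = clone_table.sizes
    if sizes.empty:
        raise ValueError("no clones to summarise")
    out = pd.DataFrame(
        {
            "mean_cells_per_clone": sizes.mean(axis=0),
            "sd_cells_per_clone": sizes.std(axis=0, ddof=1),
            "n_clones": len(sizes),
        }
    )
    out.index.name = "compartment"
    return out


def clone_size_summary(
    cells: pd.DataFrame, params: Optional[CloneCallingParams] = None
) -> pd.Series:
    """Mean cells-per-clone-call per compartment (+ total) for labelled cells."""
    labelled = cells[cells["labelled"]] if "labelled" in cells.columns else cells
    table = call_clones(labelled, params)
    return clone_sizes_by_compartment(table)["mean_cells_per_clone"]


# ---------------------------------------------------------------------------
# densities, fractions, intensities, wound sections
# ---------------------------------------------------------------------------

def density_per_layer(
    cells: pd.DataFrame,
    regions_um: Sequence[Tuple[float, float, float, float]],
    layers: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Areal fibroblast density per layer, averaged over inter-HF regions.

    ``regions_um`` is a sequence of (xmin, ymin, xmax, ymax) rectangles in µm.
    Returns rho_per_mm2 per layer plus a 'total' row, with the number of
    regions and the mean region area (mm²).
    """
    if len(regions_um) == 0:
        raise ValueError("at least one region is required")
    if layers is None:
        layers = sorted(cells["layer"].unique()) if "layer" in cells.columns else []
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    layer_col = cells["layer"].to_numpy() if "layer" in cells.columns else None
    rows = {layer: [] for layer in layers}
    totals = []
    areas = []
    for xmin, ymin, xmax, ymax in regions_um:
        area_mm2 = (xmax - xmin) * (ymax - ymin) / 1e6
        if area_mm2 <= 0:
            raise ValueError("region areas must be positive")
        areas.append(area_mm2)
        inside = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
        totals.append(inside.sum() / area_mm2)
        for layer in layers:
            n = (inside & (layer_col == layer)).sum() if layer_col is not None else 0
            rows[layer].append(n / area_mm2)
    data = {layer: float(np.mean(v)) for layer, v in rows.items()}
    data["total"] = float(np.mean(totals))
    out = pd.DataFrame(
        {
            "rho_per_mm2": pd.Series(data),
            "n_regions": len(regions_um),
            "region_area_mm2": float(np.mean(areas)),
        }
    )
    out.index.name = "layer"
    return out


def snapshot_areal_density(snapshot, section_thickness_um: float = 60.0) -> float:
    """Cells/mm² of a fixed-thickness horizontal section through a snapshot.

    Emulates whole-mount quantification: only cells within one optical-section
    thickness of the surface are counted, so the measure is comparable across
    ages even as the dermis thickens.
    """
    if section_thickness_um <= 0:
        raise ValueError("section thickness must be positive")
    depth = snapshot.layer_bounds_um[-1][2]
    t = min(section_thickness_um, depth)
    n = int((snapshot.cells["z_um"] < t).sum())
    return n / snapshot.area_mm2()


def fraction_positive(cells: pd.DataFrame, marker: str) -> float:
    """Percentage of cells positive for a boolean marker column.

    Returns NaN (the explicit not-a-value result) for an empty table; NaN in
    the marker column is a data error (the marker must be defined for all
    cells).
    """
    if marker not in cells.columns:
        raise ValueError(f"marker column {marker!r} not present")
    col = cells[marker]
    if col.isna().any():
        raise ValueError(f"marker {marker!r} undefined (NaN) for some cells")
    if len(col) == 0:
        return float("nan")
    return 100.0 * float(col.astype(bool).mean())


def normalized_mean_intensity(
    signal: Sequence[float], background: Sequence[float], mode: str = "ratio"
) -> float:
    """Mean fluorescence normalised to background (ratio or subtraction)."""
    signal = np.asarray(signal, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be non-empty")
    if signal.size == 0:
        raise ValueError("signal must be non-empty")
    bg = float(background.mean())
    sig = float(signal.mean())
    if mode == "ratio":
        if bg <= 0:
            raise ValueError("background mean must be positive in ratio mode")
        return sig / bg
    if mode == "subtract":
        return sig - bg
    raise ValueError("mode must be 'ratio' or 'subtract'")


@dataclass(frozen=True)
class WoundSectionRecord:
    """New-hair-follicle count in one wound-bed section."""

    wound_id: int
    section_id: int
    n_new_hfs: int
    section_thickness_um: float = 60.0

    def __post_init__(self) -> None:
        if self.n_new_hfs < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class HfCountSummary:
    per_wound: pd.DataFrame
    group_mean: float
    group_sd: float


def mean_hfs_per_section(records: pd.DataFrame, min_sections: int = 8) -> HfCountSummary:
    """Per-wound mean ± sd of new HFs per section, plus the group mean.

    Warns when a wound has fewer than ``min_sections`` sections (the scoring
    protocol requires at least eight 60 µm sections covering the wound bed).
    """
    if records.empty:
        raise ValueError("no wound sections provided")
    if (records["n_new_hfs"] < 0).any():
        raise ValueError("counts must be non-negative")
    grouped = records.groupby("wound_id")["n_new_hfs"]
    per_wound = grouped.agg(mean_hfs="mean", sd_hfs="std", n_sections="size")
    short = per_wound[per_wound["n_sections"] < min_sections]
    if not short.empty:
        warnings.warn(
            f"wounds with fewer than {min_sections} sections: "
            f"{list(short.index)}",
            stacklevel=2,
        )
    return HfCountSummary(
        per_wound=per_wound,
        group_mean=float(per_wound["mean_hfs"].mean()),
        group_sd=float(per_wound["mean_hfs"].std(ddof=1)) if len(per_wound) > 1 else 0.0,
    )
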