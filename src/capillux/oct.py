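"""Graph-based OCT retinal layer segmentation and thickness maps.

Each B-scan is treated as a graph whose nodes are pixels and whose edges
connect 8-neighbors.  Edge weights favor pixels with a strong axial
intensity gradient of the requested polarity:

    w(a, b) = 2 - (g_a + g_b) + w_min

where ``g`` is the polarity-signed axial gradient min-max normalized to
[0, 1] per B-scan and ``w_min`` a small positive constant keeping Dijkstra
valid.  Two virtual terminal columns whose edges cost ``w_min`` let the
minimum-cost left-to-right path start and end at any row; that path traces
the boundary.  The vitreous–ILM boundary is segmented first over the whole
image (dark-to-bright polarity), then the OS–RPE boundary with the
admissible rows restricted to strictly below the ILM path.  Total retinal
thickness is the row distance between the two boundaries times the axial
pixel pitch; repeated cubes from one imaging session are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "BScan",
    "BoundaryGraph",
    "LayerSegmentation",
    "SegmentationError",
    "build_boundary_graph",
    "segment_boundary",
    "segment_bscan",
    "total_retinal_thickness",
    "thickness_map",
    "session_thickness",
    "review_segmentation",
]


class SegmentationError(RuntimeError):
    """Raised when a B-scan carries no usable boundary evidence."""


@dataclass
class BScan:
    """One OCT cross-section: rows are axial pixels (row 0 = vitreous side)."""

    image: np.ndarray
    axial_pitch_um: float = 2.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or min(self.image.shape) < 2:
            raise ValueError("B-scan must be 2-D with >= 2 rows and columns")
        if self.axial_pitch_um <= 0:
            raise ValueError("axial_pitch_um must be positive")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("B-scan intensities must be finite")


@dataclass
class BoundaryGraph:
    """Normalized gradient field plus the edge-weight parameters."""

    gradient: np.ndarray  # (n_rows, n_cols), in [0, 1]
    polarity: str = "dark_to_bright"
    w_min: float = 1e-5

    @property
    def shape(self) -> tuple[int, int]:
        return self.gradient.shape


@dataclass
class LayerSegmentation:
    """Per-column boundary rows; ``flags`` marks manually corrected columns."""

    ilm_row: np.ndarray
    rpe_row: np.ndarray
    flags: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        self.ilm_row = np.asarray(self.ilm_row, dtype=float)
        self.rpe_row = np.asarray(self.rpe_row, dtype=float)
        if self.flags.size == 0:
            self.flags = np.zeros(self.ilm_row.size, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.ilm_row.shape != self.rpe_row.shape:
            raise ValueError("boundary arrays must have equal length")
        if np.any(self.ilm_row >= self.rpe_row):
            raise ValueError("ILM must lie strictly above the OS-RPE boundary")
        if np.any(self.ilm_row < 0):
            raise ValueError("boundary rows must be non-negative")

    @property
    def n_cols(self) -> int:
        return int(self.ilm_row.size)


def build_boundary_graph(
    bscan: "BScan | np.ndarray",
    polarity: str = "dark_to_bright",
    w_min: float = 1e-5,
) -> BoundaryGraph:
    """Compute the normalized, polarity-signed axial gradient field.

    The gradient is a centered first difference along the axial (row) axis;
    ``dark_to_bright`` keeps intensity increases downward, ``bright_to_dark``
    the opposite.  Min-max normalization per B-scan makes the segmentation
    invariant to affine intensity rescaling.  A constant image yields an
    all-zero gradient (every edge then costs ``2 + w_min``); the graph is
    still valid.
    """
    if polarity not in ("dark_to_bright", "bright_to_dark"):
        raise ValueError("polarity must be 'dark_to_bright' or 'bright_to_dark'")
    if w_min <= 0:
        raise ValueError("w_min must be positive (Dijkstra validity)")
    image = bscan.image if isinstance(bscan, BScan) else np.asarray(bscan, float)
    grad = np.gradient(image.astype(float), axis=0)
    if polarity == "bright_to_dark":
        grad = -grad
    lo, hi = grad.min(), grad.max()
    g = np.zeros_like(grad) if hi == lo else (grad - lo) / (hi - lo)
    return BoundaryGraph(gradient=g, polarity=polarity, w_min=w_min)


def _neighbor_edges(n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Undirected 8-neighbor edge list as (node_a, node_b) flat indices."""
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    pairs_a, pairs_b = [], []
    # rightward, down, down-right, up-right cover all 8-neighbor pairs once
    pairs_a.append(idx[:, :-1].ravel()); pairs_b.append(idx[:, 1:].ravel())
    pairs_a.append(idx[:-1, :].ravel()); pairs_b.append(idx[1:, :].ravel())
    pairs_a.append(idx[:-1, :-1].ravel()); pairs_b.append(idx[1:, 1:].ravel())
    pairs_a.append(idx[1:, :-1].ravel()); pairs_b.append(idx[:-1, 1:].ravel())
    return np.concatenate(pairs_a), np.concatenate(pairs_b)


def segment_boundary(
    graph: BoundaryGraph,
    row_band: "tuple | None" = None,
    return_cost: bool = False,
):
    """Minimum-cost left-to-right path through the gradient graph.

    ``row_band`` optionally restricts admissible rows, either as a global
    ``(lo, hi)`` pair (half-open, ``hi`` exclusive) or as per-column arrays.
    Returns the per-column boundary row (mean row of path pixels in that
    column; a path may occupy up to two rows per column under
    8-connectivity), optionally with the total path cost.
    """
    g = graph.gradient
    n_rows, n_cols = g.shape
    valid = np.ones((n_rows, n_cols), dtype=bool)
    if row_band is not None:
        lo, hi = row_band
        lo = np.broadcast_to(np.asarray(lo), (n_cols,))
        hi = np.broadcast_to(np.asarray(hi), (n_cols,))
        rows = np.arange(n_rows)[:, None]
        valid = (rows >= lo[None, :]) & (rows < hi[None, :])
        if not valid.any(axis=0).all():
            bad = int(np.nonzero(~valid.any(axis=0))[0][0])
            raise ValueError(f"row band excludes every row in column {bad}")

    a, b = _neighbor_edges(n_rows, n_cols)
    flat_valid = valid.ravel()
    keep = flat_valid[a] & flat_valid[b]
    a, b = a[keep], b[keep]
    gflat = g.ravel()
    w = 2.0 - (gflat[a] + gflat[b]) + graph.w_min

    n_px = n_rows * n_cols
    source, sink = n_px, n_px + 1
    left = np.nonzero(valid[:, 0])[0] * n_cols  # flat ids in column 0
    right = np.nonzero(valid[:, -1])[0] * n_cols + (n_cols - 1)
    rows_idx = np.concatenate([a, b, np.full(left.size, source), right])
    cols_idx = np.concatenate([b, a, left, np.full(right.size, sink)])
    data = np.concatenate(
        [w, w, np.full(left.size, graph.w_min), np.full(right.size, graph.w_min)]
    )
    mat = coo_matrix((data, (rows_idx, cols_idx)), shape=(n_px + 2, n_px + 2)).tocsr()
    dist, pred = dijkstra(
        mat, directed=True, indices=source, return_predecessors=True
    )
    if not np.isfinite(dist[sink]):
        raise SegmentationError("no admissible path across the B-scan")

    # walk back from sink to source collecting pixel nodes
    path = []
    node = int(pred[sink])
    while node != source and node >= 0:
        path.append(node)
        node = int(pred[node])
    path = np.asarray(path[::-1])
    rows_on_path = path // n_cols
    cols_on_path = path % n_cols
    boundary = np.full(n_cols, np.nan)
    for c in range(n_cols):
        sel = cols_on_path == c
        if not sel.any():  # unreachable: moves change column by at most 1
            raise SegmentationError(f"path skipped column {c}")
        boundary[c] = rows_on_path[sel].mean()
    if return_cost:
        return boundary, float(dist[sink])
    return boundary


def segment_bscan(
    bscan: BScan,
    w_min: float = 1e-5,
    rpe_margin_px: int = 3,
) -> LayerSegmentation:
    """Segment the vitreous-ILM and OS-RPE boundaries of one B-scan.

    The ILM (strongest dark-to-bright transition) is found first over the
    full image; the OS-RPE search is then restricted to rows at least
    ``rpe_margin_px`` below the ILM path, which prevents the two shortest
    paths from collapsing onto the same edge.  A constant image (no boundary
    evidence) raises :class:`SegmentationError` rather than returning a
    silent result.
    """
    if np.ptp(bscan.image) == 0:
        raise SegmentationError("constant B-scan carries no boundary evidence")
    graph = build_boundary_graph(bscan, "dark_to_bright", w_min=w_min)
    ilm = segment_boundary(graph)
    n_rows = bscan.image.shape[0]
    lo = np.floor(ilm).astype(int) + rpe_margin_px
    if np.any(lo >= n_rows):
        raise SegmentationError("ILM at image bottom leaves no room for the RPE")
    rpe = segment_boundary(graph, row_band=(lo, np.full_like(lo, n_rows)))
    return LayerSegmentation(ilm_row=ilm, rpe_row=rpe)


def total_retinal_thickness(
    seg: LayerSegmentation, axial_pitch_um: float
) -> np.ndarray:
    """Per-column total retinal thickness in um: (rpe - ilm) * pitch."""
    if axial_pitch_um <= 0:
        raise ValueError("axial_pitch_um must be positive")
    return (seg.rpe_row - seg.ilm_row) * axial_pitch_um


def thickness_map(
    segs: "list[LayerSegmentation]", axial_pitch_um: float
) -> np.ndarray:
    """En-face thickness map of one cube: B-scans stacked as rows."""
    return np.vstack(
        [total_retinal_thickness(s, axial_pitch_um) for s in segs]
    )


def session_thickness(cube_means: "np.ndarray | list[float]") -> float:
    """Session value: mean over the repeated cubes of one imaging session."""
    values = np.atleast_1d(np.asarray(cube_means, dtype=float))
    if values.size == 0:
        raise ValueError("session requires at least one cube")
    return float(values.mean())


def review_segmentation(
    seg: LayerSegmentation,
    corrections: "dict[int, dict[str, float]] | None",
) -> LayerSegmentation:
    """Apply expert per-column overrides, flagging corrected columns.

    ``corrections`` maps column index to ``{"ilm": row}`` and/or
    ``{"rpe": row}``.  Overrides violating ilm < rpe are rejected.
    """
    ilm = seg.ilm_row.copy()
    rpe = seg.rpe_row.copy()
    flags = seg.flags.copy()
    if corrections:
        for col, fix in corrections.items():
            if not (0 <= col < seg.n_cols):
                raise ValueError(f"correction column {col} out of range")
            if "ilm" in fix:
                ilm[col] = fix["ilm"]
            if "rpe" in fix:
                rpe[col] = fix["rpe"]
            flags[col] = True
    return LayerSegmentation(ilm_row=ilm, rpe_row=rpe, flags=flags)
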