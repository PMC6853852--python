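"""Sequential shortest-path extraction of the 8 retinal boundaries.

Dijkstra's algorithm finds one minimum-weight lateral path at a time, so
the boundaries are extracted sequentially, each later search constrained
between previously found boundaries (anatomical prior: the interfaces are
weakly ordered in depth and span the full width of the scan):

1. ILM          dark->bright, whole image (strongest transition: vitreous->NFL)
2. IS-OS        dark->bright, below the first path; the two paths are then
                labeled by mean row (the ILM lies above the IS-OS)
3. RPE-Choroid  bright->dark, whole image (strongest bright->dark drop)
4. NFL-GCL      bright->dark, between ILM and IS-OS
5. OS-RPE       dark->bright, between IS-OS and RPE-Choroid
6. INL-OPL      dark->bright, between NFL-GCL and IS-OS
7. IPL-INL      bright->dark, between NFL-GCL and INL-OPL
8. OPL-ONL      bright->dark, between INL-OPL and IS-OS

Region limitation is by node masking with a small margin so a delimiting
boundary cannot be re-found. The result carries the 8 boundaries in
anatomical order plus the 7 layer masks between consecutive boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .errors import (
    BoundaryOrderError,
    NoPathError,
    RegionEmptyError,
    SegmentationStageError,
)
from .fhh import FhhConfig
from .graph import (
    GraphConfig,
    PixelGraph,
    add_endpoint_columns,
    build_adjacency,
    fuzzify_weights,
    vertical_gradient,
)
from .image import BScanImage

__all__ = [
    "BOUNDARY_LABELS",
    "LAYER_NAMES",
    "Boundary",
    "SearchRegion",
    "SegmentConfig",
    "SegmentationResult",
    "shortest_path_boundary",
    "limit_region",
    "disambiguate_by_mean_row",
    "segment_all",
]

logger = logging.getLogger(__name__)

#: The 8 interfaces, ordered from the vitreous (top) to the choroid (bottom).
BOUNDARY_LABELS = (
    "ILM",
    "NFL-GCL",
    "IPL-INL",
    "INL-OPL",
    "OPL-ONL",
    "IS-OS",
    "OS-RPE",
    "RPE-Choroid",
)

#: The 7 layers delimited by consecutive boundaries.
LAYER_NAMES = ("NFL", "GCL+IPL", "INL", "OPL", "ONL+IS", "OS", "RPE")


@dataclass
class Boundary:
    """Per-column row position of one retinal interface."""

    label: str
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.rows.ndim != 1:
            raise ValueError("boundary rows must be a 1D per-column vector")

    @property
    def mean_row(self) -> float:
        return float(self.rows.mean())

    def __len__(self) -> int:
        return int(self.rows.size)


@dataclass
class SearchRegion:
    """Admissible rows per column, inclusive on both ends."""

    lo: np.ndarray  # first admissible row per column
    hi: np.ndarray  # last admissible row per column
    height: int

    def mask(self) -> np.ndarray:
        rows = np.arange(self.height)[:, None]
        return (rows >= self.lo[None, :]) & (rows <= self.hi[None, :])


@dataclass
class SegmentConfig:
    """Segmentation-stage parameters on top of the graph weights.

    margin is the number of rows excluded next to each delimiting boundary
    when a search region is limited (so the delimiter itself cannot be
    re-found). rpe_below_isos optionally restricts the RPE-Choroid search
    to below the IS-OS instead of the whole image, which can help on very
    noisy scans.
    """

    graph: GraphConfig = field(default_factory=GraphConfig)
    margin: int = 1
    rpe_below_isos: bool = False


@dataclass
class SegmentationResult:
    """The 8 extracted boundaries plus bookkeeping.

    ``boundaries`` maps label -> Boundary in anatomical (top-to-bottom)
    order. ``ordering_ok`` records whether the weak top-to-bottom ordering
    held on every column; violations are flagged here, never repaired.
    Rows refer to the frame of the image that was segmented; ``row_offset``
    rows were cropped from the top of the original scan.
    """

    boundaries: dict[str, Boundary]
    shape: tuple[int, int]
    order_of_extraction: list[str]
    path_costs: dict[str, float]
    ordering_ok: bool = True
    row_offset: int = 0

    def rows_matrix(self) -> np.ndarray:
        """(8, W) array of boundary rows in anatomical order."""
        return np.stack([self.boundaries[lb].rows for lb in BOUNDARY_LABELS])

    def layer_mask(self, name: str) -> np.ndarray:
        """Binary mask of one layer: rows in [upper boundary, lower boundary)."""
        i = LAYER_NAMES.index(name)
        upper = self.boundaries[BOUNDARY_LABELS[i]].rows
        lower = self.boundaries[BOUNDARY_LABELS[i + 1]].rows
        rows = np.arange(self.shape[0])[:, None]
        return (rows >= upper[None, :]) & (rows < lower[None, :])

    def layer_masks(self) -> dict[str, np.ndarray]:
        return {name: self.layer_mask(name) for name in LAYER_NAMES}

    def in_original_frame(self) -> "SegmentationResult":
        """Shift rows back into pre-crop coordinates."""
        if self.row_offset == 0:
            return self
        off = self.row_offset
        bds = {
            lb: Boundary(lb, b.rows + off) for lb, b in self.boundaries.items()
        }
        return SegmentationResult(
            boundaries=bds,
            shape=(self.shape[0] + off, self.shape[1]),
            order_of_extraction=list(self.order_of_extraction),
            path_costs=dict(self.path_costs),
            ordering_ok=self.ordering_ok,
            row_offset=0,
        )


def check_ordering(rows: np.ndarray) -> bool:
    """Weak top-to-bottom ordering of an (8, W) row matrix."""
    return bool(np.all(np.diff(rows, axis=0) >= 0))


def limit_region(
    upper: Boundary | None,
    lower: Boundary | None,
    margin: int,
    shape: tuple[int, int],
) -> SearchRegion:
    """Rows strictly between two reference boundaries, with a margin.

    ``None`` means the image top (for ``upper``) or bottom (for ``lower``),
    to which no margin is applied. With both references given, column c
    admits rows ``upper[c] + margin + 1 .. lower[c] - margin - 1``.
    """
    h, w = shape
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    if upper is not None and lower is not None:
        if np.any(upper.rows > lower.rows):
            bad = int(np.argmax(upper.rows > lower.rows))
            raise BoundaryOrderError(
                f"reference boundaries cross at column {bad}: "
                f"{upper.label}={upper.rows[bad]} > {lower.label}={lower.rows[bad]}"
            )
    lo = np.zeros(w, dtype=np.int64) if upper is None else upper.rows + margin + 1
    hi = np.full(w, h - 1, dtype=np.int64) if lower is None else lower.rows - margin - 1
    if np.any(lo > hi):
        bad = np.nonzero(lo > hi)[0]
        raise RegionEmptyError(
            f"search region empty in {bad.size} column(s), first at column {bad[0]}"
        )
    return SearchRegion(lo=lo, hi=hi, height=h)


def shortest_path_boundary(
    graph: PixelGraph, region: SearchRegion | None = None, label: str = ""
) -> tuple[Boundary, float]:
    """Minimum-weight lateral path through the graph, as a per-column boundary.

    Runs Dijkstra from the top of the left virtual column to the top of the
    right one, restricted to nodes inside ``region``. The path is converted
    to a single row per image column; when 8-connectivity lets the path
    visit several rows of one column, the last-visited row is kept, which
    yields a single-valued boundary. Node ordering is row-major and fixed,
    so the result is deterministic for identical inputs.
    """
    h, w = graph.shape
    valid = region.mask() if region is not None else None
    mat, source, sink = graph.to_sparse(valid)
    dist, pred = dijkstra(
        mat, directed=True, indices=source, return_predecessors=True
    )
    if not np.isfinite(dist[sink]):
        raise NoPathError("no admissible path between the virtual columns")
    # walk predecessors sink -> source, then reverse
    path = []
    node = sink
    while node != -9999 and node != source:
        path.append(node)
        node = pred[node]
    path.append(source)
    path.reverse()

    wa = w + 2
    rows = np.full(w, -1, dtype=np.int64)
    for node in path:
        r, c = divmod(node, wa)
        if 1 <= c <= w:
            rows[c - 1] = r
    if np.any(rows < 0):  # pragma: no cover - cannot happen on a connected path
        raise NoPathError("path skipped image columns")
    return Boundary(label, rows), float(dist[sink])


def disambiguate_by_mean_row(
    path_a: Boundary, path_b: Boundary
) -> tuple[Boundary, Boundary]:
    """Order two candidate paths anatomically by their mean row.

    The path with the smaller mean row is the upper boundary. Equal means
    are logged and the input order kept.
    """
    if path_a.mean_row == path_b.mean_row:
        logger.warning(
            "mean-row tie between %r and %r; keeping input order",
            path_a.label,
            path_b.label,
        )
        return path_a, path_b
    if path_a.mean_row < path_b.mean_row:
        return path_a, path_b
    return path_b, path_a


def _relabel(boundary: Boundary, label: str) -> Boundary:
    return Boundary(label, boundary.rows)


def segment_all(
    image: BScanImage, config: SegmentConfig | None = None
) -> SegmentationResult:
    """Extract all 8 boundaries from an (already enhanced) B-scan.

    Builds the two polarity graphs and runs the sequential searches in the
    order ILM, IS-OS, RPE-Choroid, NFL-GCL, OS-RPE, INL-OPL, IPL-INL,
    OPL-ONL. A stage failure (empty region, no path) aborts with the stage
    name; a violated top-to-bottom ordering is flagged on the result, never
    silently repaired.
    """
    config = config or SegmentConfig()
    gcfg = config.graph
    m = config.margin
    shape = image.shape

    graphs: dict[str, PixelGraph] = {}
    for pol in ("dark_to_bright", "bright_to_dark"):
        grad = vertical_gradient(image, pol)  # type: ignore[arg-type]
        g = build_adjacency(grad, gcfg.w_min, gcfg.connectivity)
        g = fuzzify_weights(g, gcfg.beta_w)
        graphs[pol] = add_endpoint_columns(g)

    costs: dict[str, float] = {}
    order: list[str] = []

    def run(stage: str, pol: str, region: SearchRegion | None) -> Boundary:
        try:
            b, cost = shortest_path_boundary(graphs[pol], region, label=stage)
        except (RegionEmptyError, NoPathError) as exc:
            raise SegmentationStageError(stage, str(exc)) from exc
        costs[stage] = cost
        order.append(stage)
        logger.info("stage %s: path cost %.6f", stage, cost)
        return b

    def limit(stage: str, upper: Boundary | None, lower: Boundary | None,
              margin: int) -> SearchRegion:
        try:
            return limit_region(upper, lower, margin, shape)
        except (RegionEmptyError, BoundaryOrderError) as exc:
            raise SegmentationStageError(stage, str(exc)) from exc

    # 1-2: the two strongest dark->bright paths, labeled by mean row
    first = run("ILM", "dark_to_bright", None)
    below_first = limit("IS-OS", first, None, m)
    second = run("IS-OS", "dark_to_bright", below_first)
    ilm, isos = disambiguate_by_mean_row(first, second)
    ilm, isos = _relabel(ilm, "ILM"), _relabel(isos, "IS-OS")

    # 3: strongest bright->dark drop
    rpe_region = (
        limit("RPE-Choroid", isos, None, m) if config.rpe_below_isos else None
    )
    rpech = run("RPE-Choroid", "bright_to_dark", rpe_region)

    # 4-8: constrained searches between established boundaries
    nflgcl = run("NFL-GCL", "bright_to_dark", limit("NFL-GCL", ilm, isos, m))
    osrpe = run("OS-RPE", "dark_to_bright", limit("OS-RPE", isos, rpech, m))
    inlopl = run("INL-OPL", "dark_to_bright", limit("INL-OPL", nflgcl, isos, m))
    iplinl = run("IPL-INL", "bright_to_dark", limit("IPL-INL", nflgcl, inlopl, m))
    oplonl = run("OPL-ONL", "bright_to_dark", limit("OPL-ONL", inlopl, isos, m))

    found = {
        "ILM": ilm,
        "NFL-GCL": nflgcl,
        "IPL-INL": iplinl,
        "INL-OPL": inlopl,
        "OPL-ONL": oplonl,
        "IS-OS": isos,
        "OS-RPE": osrpe,
        "RPE-Choroid": rpech,
    }
    boundaries = {lb: found[lb] for lb in BOUNDARY_LABELS}
    result = SegmentationResult(
        boundaries=boundaries,
        shape=shape,
        order_of_extraction=order,
        path_costs=costs,
        row_offset=image.crop_offset,
    )
    result.ordering_ok = check_ordering(result.rows_matrix())
    if not result.ordering_ok:
        logger.warning("boundary ordering violated; result flagged, not repaired")
    return result
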