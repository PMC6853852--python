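"""Gradient-polarity pixel graphs for shortest-path boundary tracing.

Every retinal interface is an axial intensity transition: either
dark-to-bright (e.g. vitreous -> NFL at the ILM) or bright-to-dark
(e.g. RPE -> choroid). Two graphs are therefore built over the pixel grid,
one per transition polarity, with edge weights

    w_ab = 2 - g_a - g_b + w_min

where g is the min–max normalized vertical gradient of the matching
polarity. Edges lying along an interface of that polarity get weights near
w_min, so the minimum-weight lateral path traces the interface.

The weights are then "fuzzified": normalized to [0, 1] over the whole graph
and raised to a constant power beta_w. The map is monotone, so the ranking
of edges is untouched, but low-cost boundary edges are pushed further down
relative to interior edges, which discourages short-cuts through noise.

Finally one virtual column is appended on each lateral side whose edges all
cost w_min, so a path may enter and leave the image at any row essentially
for free (retinal layers span the full width of a B-scan).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal
import warnings

import numpy as np
import scipy.sparse as sp

from .errors import DegenerateImageError, ParameterError
from .image import BScanImage

__all__ = [
    "Polarity",
    "GradientMap",
    "PixelGraph",
    "GraphConfig",
    "vertical_gradient",
    "build_adjacency",
    "fuzzify_weights",
    "add_endpoint_columns",
]

Polarity = Literal["dark_to_bright", "bright_to_dark"]

_OFFSETS_4 = ((0, 1), (1, 0))
_OFFSETS_8 = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class GraphConfig:
    """Weight-assignment parameters.

    w_min stabilizes the graph: it is the floor added to every edge and the
    exact cost of virtual-column edges, and must be positive for Dijkstra.
    beta_w is the constant fuzzifier applied to the normalized weights;
    connectivity selects 4- or 8-neighbourhoods (8 allows diagonal steps so
    sloped boundaries cost no vertical detours).
    """

    w_min: float = 1e-5
    beta_w: float = 2.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.w_min <= 0:
            raise ParameterError(f"w_min must be positive, got {self.w_min}")
        if self.beta_w <= 0:
            raise ParameterError(f"beta_w must be positive, got {self.beta_w}")
        if self.connectivity not in (4, 8):
            raise ParameterError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass
class GradientMap:
    """Normalized vertical gradient of one polarity, same shape as the image."""

    values: np.ndarray
    polarity: Polarity


@dataclass
class PixelGraph:
    """Sparse undirected weighted graph over the pixels of one B-scan.

    Interior edges are stored as parallel arrays of flat (row-major) pixel
    indices plus weights. Virtual endpoint columns are represented by the
    ``has_endpoints`` flag and materialized in :meth:`to_sparse`, where a
    per-pixel validity mask can additionally restrict the search region.
    """

    shape: tuple[int, int]
    edges_a: np.ndarray
    edges_b: np.ndarray
    weights: np.ndarray
    w_min: float
    polarity: Polarity
    connectivity: int
    fuzzified: bool = False
    has_endpoints: bool = False

    @property
    def n_nodes(self) -> int:
        h, w = self.shape
        return h * (w + 2) if self.has_endpoints else h * w

    @property
    def n_edges(self) -> int:
        return int(self.edges_a.size)

    def aug_index(self, row: np.ndarray | int, col: np.ndarray | int) -> np.ndarray | int:
        """Node id in the augmented grid; image column c sits at lateral c+1."""
        return row * (self.shape[1] + 2) + col + 1

    def to_sparse(
        self, valid: np.ndarray | None = None
    ) -> tuple[sp.csr_matrix, int, int]:
        """Assemble the CSR adjacency over the augmented grid.

        ``valid`` is an optional H x W boolean mask; interior edges touching
        an excluded pixel are dropped (region limitation by node masking).
        Returns (matrix, source, sink) with source/sink at the top of the
        left/right virtual column. Virtual columns are always fully valid.
        """
        if not self.has_endpoints:
            raise ParameterError("add_endpoint_columns must be applied before search")
        h, w = self.shape
        wa = w + 2
        a, b, wt = self.edges_a, self.edges_b, self.weights
        if valid is not None:
            keep = valid.ravel()[a] & valid.ravel()[b]
            a, b, wt = a[keep], b[keep], wt[keep]
        ra, ca = a // w, a % w
        rb, cb = b // w, b % w
        ua = ra * wa + ca + 1
        ub = rb * wa + cb + 1

        rows_v = np.arange(h - 1)
        left_top = rows_v * wa
        right_top = rows_v * wa + (wa - 1)
        vert_u = np.concatenate([left_top, right_top])
        vert_v = vert_u + wa  # node one row down, same virtual column

        rows_h = np.arange(h)
        if valid is None:
            left_ok = right_ok = np.ones(h, dtype=bool)
        else:
            left_ok, right_ok = valid[:, 0], valid[:, -1]
        horiz_u = np.concatenate([rows_h[left_ok] * wa, rows_h[right_ok] * wa + (wa - 1)])
        horiz_v = np.concatenate(
            [rows_h[left_ok] * wa + 1, rows_h[right_ok] * wa + (wa - 2)]
        )

        u = np.concatenate([ua, vert_u, horiz_u])
        v = np.concatenate([ub, vert_v, horiz_v])
        wgt = np.concatenate(
            [wt, np.full(vert_u.size + horiz_u.size, self.w_min)]
        )
        # symmetric: store both directions explicitly
        mat = sp.coo_matrix(
            (np.concatenate([wgt, wgt]), (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(h * wa, h * wa),
        ).tocsr()
        source = 0  # top of left virtual column
        sink = wa - 1  # top of right virtual column
        return mat, source, sink


def vertical_gradient(image: BScanImage, polarity: Polarity) -> GradientMap:
    """Min–max normalized first difference along depth.

    The raw gradient is D(r, c) = I(r, c) - I(r-1, c), positive where the
    image gets brighter with depth; the top row, which has no predecessor,
    is assigned a raw difference of 0. The dark_to_bright map is the min–max
    rescale of D to [0, 1]; bright_to_dark is its pointwise complement.
    A constant image yields a flat 0.5 map and a warning.
    """
    if polarity not in ("dark_to_bright", "bright_to_dark"):
        raise ParameterError(f"unknown polarity {polarity!r}")
    g = image.pixels
    raw = np.zeros_like(g)
    raw[1:] = g[1:] - g[:-1]
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("constant image: gradient map degenerate, returning 0.5")
        values = np.full_like(g, 0.5)
    else:
        values = (raw - lo) / (hi - lo)
    if polarity == "bright_to_dark":
        values = 1.0 - values
    return GradientMap(values, polarity)


def build_adjacency(
    grad: GradientMap, w_min: float = 1e-5, connectivity: int = 8
) -> PixelGraph:
    """Edge weights w_ab = 2 - g_a - g_b + w_min over neighbouring pixels.

    All weights lie in [w_min, 2 + w_min]; edges whose endpoints both sit on
    a strong transition of the graph's polarity approach the lower bound.
    """
    if w_min <= 0:
        raise ParameterError(f"w_min must be positive, got {w_min}")
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    g = grad.values
    h, w = g.shape
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4
    idx = np.arange(h * w).reshape(h, w)
    ea, eb, wt = [], [], []
    for dr, dc in offsets:
        ra = slice(0, h - dr)
        rb = slice(dr, h)
        if dc >= 0:
            ca, cb = slice(0, w - dc), slice(dc, w)
        else:
            ca, cb = slice(-dc, w), slice(0, w + dc)
        a = idx[ra, ca].ravel()
        b = idx[rb, cb].ravel()
        ea.append(a)
        eb.append(b)
        wt.append(2.0 - g.ravel()[a] - g.ravel()[b] + w_min)
    return PixelGraph(
        shape=(h, w),
        edges_a=np.concatenate(ea),
        edges_b=np.concatenate(eb),
        weights=np.concatenate(wt),
        w_min=w_min,
        polarity=grad.polarity,
        connectivity=connectivity,
    )


def fuzzify_weights(graph: PixelGraph, beta_w: float = 2.0) -> PixelGraph:
    """Reassign edge weights by min–max normalization and a power map.

    w' = (w - min) / (max - min), w'' = w'^beta_w + w_min. The power map is
    monotone on [0, 1] so the relative order of edges is preserved; the
    w_min floor keeps the globally cheapest edge strictly positive (a zero
    weight would let paths wander through the interior for free).
    """
    if beta_w <= 0:
        raise ParameterError(f"beta_w must be positive, got {beta_w}")
    w = graph.weights
    lo, hi = w.min(), w.max()
    if hi == lo:
        raise DegenerateImageError("all edge weights equal: fuzzification undefined")
    w2 = np.power((w - lo) / (hi - lo), beta_w) + graph.w_min
    return replace(graph, weights=w2, fuzzified=True)


def add_endpoint_columns(graph: PixelGraph) -> PixelGraph:
    """Append one virtual minimum-weight column on each lateral side.

    Every edge incident to a virtual node — vertical steps inside the
    column and horizontal steps into the image — costs exactly w_min, so
    traversing a whole virtual column costs (H-1) * w_min, negligible
    against any interior edge. The search source and sink are the tops of
    the left and right virtual columns.
    """
    return replace(graph, has_endpoints=True)
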