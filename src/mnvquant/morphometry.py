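"""OCTA vascular morphometry of macular neovascularization (MNV).

Four descriptors of an en-face MNV lesion, computed from a pair of binary
masks on a common pixel grid:

* **area** (mm^2) — lesion foreground pixel count times the squared pixel
  size;
* **flow density** (%) — fraction of lesion pixels carrying a flow signal;
* **total vessel length** sumL (mm) — summed centerline length of the
  skeletonized flow mask, counting orthogonal steps as one pixel and
  diagonal steps as sqrt(2) pixels;
* **fractal dimension** FD — box-counting dimension of the skeleton
  (optionally of the binarized flow mask), describing branching complexity;
  1 for a line, 2 for a plane-filling structure.

The default pixel scale is 0.012 mm (a 6 mm field of view sampled by 500
A-scan positions). Coordinates are 0-based (row, col), row 0 at top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import imageio.v3 as iio
import networkx as nx
import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_MM = 6.0 / 500  # 0.012 mm

__all__ = [
    "MnvMaskPair",
    "MorphometrySet",
    "DEFAULT_PIXEL_SIZE_MM",
    "load_mask_pair",
    "compute_area",
    "compute_flow_density",
    "skeletonize",
    "skeleton_to_graph",
    "total_vessel_length",
    "box_counting_dimension",
    "fractal_dimension",
    "quantify",
]


@dataclass
class MnvMaskPair:
    """Binary lesion-region mask and flow-pixel mask on a shared grid.

    The flow mask is intersected with the lesion mask on construction:
    flow outside the outlined lesion is not part of the MNV.
    """

    lesion_mask: np.ndarray
    flow_mask: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self) -> None:
        self.lesion_mask = np.asarray(self.lesion_mask).astype(bool)
        self.flow_mask = np.asarray(self.flow_mask).astype(bool)
        if self.lesion_mask.shape != self.flow_mask.shape:
            raise ValueError(
                f"mask size mismatch: lesion {self.lesion_mask.shape} "
                f"vs flow {self.flow_mask.shape}"
            )
        if self.lesion_mask.ndim != 2:
            raise ValueError("masks must be 2-D")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")
        if not self.lesion_mask.any():
            raise ValueError("empty lesion mask")
        outside = self.flow_mask & ~self.lesion_mask
        if outside.any():
            logger.warning(
                "%d flow pixels outside the lesion mask were dropped",
                int(outside.sum()),
            )
            self.flow_mask = self.flow_mask & self.lesion_mask


@dataclass(frozen=True)
class MorphometrySet:
    """The four per-eye OCTA descriptors."""

    area_mm2: float
    flow_density_pct: float
    fractal_dimension: float
    suml_mm: float


def _read_binary(path) -> np.ndarray:
    try:
        img = iio.imread(path)
    except OSError as exc:
        raise OSError(f"unreadable mask image {path}: {exc}") from exc
    if img.ndim == 3:  # collapse any channel axis; masks are single-channel
        img = img[..., 0]
    return np.asarray(img) != 0


def load_mask_pair(lesion_path, flow_path, pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM) -> MnvMaskPair:
    """Load a lesion/flow mask pair from images; nonzero = foreground."""
    lesion = _read_binary(lesion_path)
    flow = _read_binary(flow_path)
    pair = MnvMaskPair(lesion, flow, pixel_size_mm)
    logger.info(
        "loaded masks: %d lesion px, %d flow px",
        int(pair.lesion_mask.sum()),
        int(pair.flow_mask.sum()),
    )
    return pair


def compute_area(m: MnvMaskPair) -> float:
    """Lesion area in mm^2: foreground pixel count times pixel area."""
    return float(m.lesion_mask.sum()) * m.pixel_size_mm**2


def compute_flow_density(m: MnvMaskPair) -> float:
    """Percentage of lesion pixels carrying a flow signal."""
    n_lesion = int(m.lesion_mask.sum())
    if n_lesion == 0:
        raise ValueError("empty lesion mask")
    return 100.0 * float(m.flow_mask.sum()) / n_lesion


def skeleton_to_graph(skeleton: np.ndarray) -> nx.Graph:
    """Build the 8-connected pixel graph of a binary skeleton image.

    Nodes are (row, col) tuples of skeleton pixels; each pair of 8-adjacent
    skeleton pixels contributes one edge, labelled ``kind`` = "orthogonal"
    or "diagonal".
    """
    skeleton = np.asarray(skeleton).astype(bool)
    g = nx.Graph()
    coords = np.argwhere(skeleton)
    g.add_nodes_from(map(tuple, coords))
    nrows, ncols = skeleton.shape
    # scan only forward-pointing offsets so each edge is seen once
    for dr, dc, kind in ((0, 1, "orthogonal"), (1, 0, "orthogonal"),
                         (1, 1, "diagonal"), (1, -1, "diagonal")):
        for r, c in coords:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nrows and 0 <= c2 < ncols and skeleton[r2, c2]:
                g.add_edge((int(r), int(c)), (int(r2), int(c2)), kind=kind)
    return g


def skeletonize(m: MnvMaskPair) -> nx.Graph:
    """Thin the flow mask to a 1-pixel-wide 8-connected centerline graph.

    Topology-preserving morphological thinning; connected components of the
    skeleton match those of the flow mask (tiny components reduce to single
    nodes). An empty flow mask yields an empty graph.
    """
    if not m.flow_mask.any():
        return nx.Graph()
    return skeleton_to_graph(_sk_skeletonize(m.flow_mask))


def total_vessel_length(g: nx.Graph, pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM) -> float:
    """Summed centerline length in mm (orthogonal edge = 1 px, diagonal = sqrt(2))."""
    n_diag = sum(1 for _, _, k in g.edges(data="kind") if k == "diagonal")
    n_orth = g.number_of_edges() - n_diag
    return (n_orth + np.sqrt(2.0) * n_diag) * pixel_size_mm


def box_counting_dimension(binary: np.ndarray) -> float:
    """Box-counting dimension of a binary raster.

    Counts occupied boxes for box sizes 2, 4, 8, ... up to half the shorter
    frame side (grid anchored at the origin, no offset averaging) and
    returns minus the least-squares slope of log N(eps) vs log eps.
    A structure occupying a single box at every size has dimension 0.
    """
    binary = np.asarray(binary).astype(bool)
    if not binary.any():
        raise ValueError("no structure")
    max_eps = min(binary.shape) // 2
    sizes, counts = [], []
    eps = 2
    while eps <= max_eps:
        nr = -(-binary.shape[0] // eps)
        nc = -(-binary.shape[1] // eps)
        padded = np.zeros((nr * eps, nc * eps), dtype=bool)
        padded[: binary.shape[0], : binary.shape[1]] = binary
        boxes = padded.reshape(nr, eps, nc, eps).any(axis=(1, 3))
        sizes.append(eps)
        counts.append(int(boxes.sum()))
        eps *= 2
    if len(sizes) < 2:
        return 0.0
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(max(-slope, 0.0))


def fractal_dimension(g: nx.Graph, frame_shape: tuple[int, int]) -> float:
    """Box-counting FD of a skeleton graph rasterized into ``frame_shape``."""
    if g.number_of_nodes() == 0:
        raise ValueError("no structure")
    raster = np.zeros(frame_shape, dtype=bool)
    rows, cols = zip(*g.nodes)
    raster[list(rows), list(cols)] = True
    return box_counting_dimension(raster)


def quantify(m: MnvMaskPair, fd_substrate: str = "skeleton") -> MorphometrySet:
    """Compute all four descriptors for one eye.

    ``fd_substrate`` selects whether the fractal dimension is measured on
    the skeletonized centerline (default, consistent with cohort-scale FD
    values around 1.3) or on the binarized flow mask.
    """
    if fd_substrate not in ("skeleton", "binarized"):
        raise ValueError("fd_substrate must be 'skeleton' or 'binarized'")
    area = compute_area(m)
    density = compute_flow_density(m)
    g = skeletonize(m)
    suml = total_vessel_length(g, m.pixel_size_mm)
    if not m.flow_mask.any():
        fd = 0.0
    elif fd_substrate == "skeleton":
        fd = fractal_dimension(g, m.flow_mask.shape)
    else:
        fd = box_counting_dimension(m.flow_mask)
    return MorphometrySet(
        area_mm2=area,
        flow_density_pct=density,
        fractal_dimension=fd,
        suml_mm=suml,
    )
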