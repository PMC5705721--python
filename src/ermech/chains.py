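"""Fibre-backbone containers shared across the pipeline.

A traced (or synthesised) tubule backbone is an ordered polyline with
near-uniform segment spacing, in micrometres.  Networks add degree-3
junction points on top of a set of chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FiberChain:
    """Ordered 2D (or 3D) vertex list with uniform segment length.

    Parameters
    ----------
    vertices : (n, d) array, d in {2, 3}
        Vertex coordinates in micrometres.
    segment_length : float
        Nominal spacing between consecutive vertices [um].
    source_image_id : str
        Identifier of the image (or generator) the chain came from.
    """

    vertices: np.ndarray
    segment_length: float
    source_image_id: str = ""
    chain_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2:
            raise ValueError("a chain needs at least 2 vertices of equal dimension")
        if self.vertices.shape[1] not in (2, 3):
            raise ValueError("vertices must be 2D or 3D coordinates")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def segment_vectors(self) -> np.ndarray:
        return np.diff(self.vertices, axis=0)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors, axis=1)

    def contour_length(self) -> float:
        """Total arc length [um]."""
        return float(self.segment_lengths.sum())

    def end_to_end(self) -> float:
        """Euclidean distance between first and last vertex [um]."""
        return float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0 [um]."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])


@dataclass
class FiberNetwork:
    """A set of chains plus junction points (degree >= 3 nodes)."""

    chains: list[FiberChain]
    #: each junction is (x_um, y_um, degree)
    junctions: list[tuple[float, float, int]] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def junction_coords(self) -> np.ndarray:
        if not self.junctions:
            return np.empty((0, 2))
        return np.array([(x, y) for x, y, _ in self.junctions], dtype=float)


def polyline_arclength(vertices: np.ndarray) -> np.ndarray:
    """Cumulative arc length of a polyline, starting at 0."""
    vertices = np.asarray(vertices, dtype=float)
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(vertices: np.ndarray, segment_length: float) -> np.ndarray:
    """Resample a polyline to (near-)uniform arc-length spacing.

    The output runs from the first to the last input vertex; the actual
    spacing is the total length divided by the nearest integer number of
    segments, so total contour length is preserved to the polyline chord
    approximation.
    """
    vertices = np.asarray(vertices, dtype=float)
    s = polyline_arclength(vertices)
    total = s[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    n_seg = max(1, int(round(total / segment_length)))
    s_new = np.linspace(0.0, total, n_seg + 1)
    out = np.empty((n_seg + 1, vertices.shape[1]))
    for d in range(vertices.shape[1]):
        out[:, d] = np.interp(s_new, s, vertices[:, d])
    return out
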