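"""Signed torso-to-brace displacement fields and the 12-segment partition.

For every torso vertex the closest point on the brace surface is found;
the distance is signed positive where that point lies inside the torso
solid (the brace presses into the torso — pressure zone) and negative
where it lies outside (the torso has room to move — expansion zone).
The torso is split into 12 anatomical segments — anterior/posterior ×
patient-left/right × upper/mid/lower — and the peak positive and
negative displacement is reported per segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mesh import (
    ON_SURFACE_TOL_MM,
    InvalidMeshError,
    Plane,
    SurfaceMesh,
    nearest_points_on_surface,
    winding_number,
)

#: Canonical segment order used by all tables: peak rows run ALU..PRL.
SEGMENT_CODES = (
    "ALU", "ARU", "ALM", "ARM", "ALL", "ARL",
    "PLU", "PRU", "PLM", "PRM", "PLL", "PRL",
)


@dataclass
class DisplacementField:
    """Per-torso-vertex signed distances (mm) to the brace surface."""

    values: np.ndarray
    torso: SurfaceMesh

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class SegmentPeaks:
    """Peak positive / negative displacement (mm) and vertex count per segment."""

    peak_positive: dict[str, float]
    peak_negative: dict[str, float]
    counts: dict[str, int]
    empty_segments: tuple[str, ...] = ()

    def feature(self, name: str) -> float:
        """Look up e.g. ``peak_negative_PLM``."""
        kind, code = name.rsplit("_", 1)
        if kind == "peak_positive":
            return self.peak_positive[code]
        if kind == "peak_negative":
            return self.peak_negative[code]
        raise KeyError(name)

    def as_rows(self) -> list[dict]:
        return [
            {
                "segment": c,
                "peak_positive_mm": self.peak_positive[c],
                "peak_negative_mm": self.peak_negative[c],
                "n_vertices": self.counts[c],
            }
            for c in SEGMENT_CODES
        ]


def signed_displacement_field(torso: SurfaceMesh, brace: SurfaceMesh) -> DisplacementField:
    """Closest-distance field from torso vertices to the brace surface, signed
    by an inside/outside (winding-number) test of the closest brace point
    against the torso solid.  Assumes both models already share a frame."""
    if len(brace.faces) == 0:
        raise InvalidMeshError("brace mesh is empty")
    if not torso.is_watertight:
        raise InvalidMeshError(
            f"torso must be watertight for the sign test "
            f"({torso.open_edge_count} open edges)"
        )
    closest, dist, _ = nearest_points_on_surface(brace, torso.vertices)
    w = winding_number(torso, closest)
    sign = np.where(np.abs(w) > 0.5, 1.0, -1.0)
    sign[dist <= ON_SURFACE_TOL_MM] = 0.0
    return DisplacementField(values=sign * dist, torso=torso)


def partition_12_segments(
    torso: SurfaceMesh, sagittal: Optional[Plane] = None
) -> np.ndarray:
    """Label every torso vertex with one of the 12 segment codes.

    The z-range is split into equal-height upper/mid/lower thirds; a
    coronal midplane through the centroid (normal +y) splits anterior
    from posterior and a sagittal midplane (given, or +x through the
    centroid) splits patient-left from right.  Boundaries follow a
    half-open convention (lower / posterior / right side).
    """
    if len(torso.vertices) == 0:
        raise InvalidMeshError("empty torso mesh")
    v = torso.vertices
    centroid = v.mean(axis=0)
    zmin, zmax = torso.z_range
    height = zmax - zmin
    t = (v[:, 2] - zmin) / height if height > 0 else np.zeros(len(v))
    band = np.where(t > 2.0 / 3.0, "U", np.where(t > 1.0 / 3.0, "M", "L"))
    coronal = Plane(centroid, np.array([0.0, 1.0, 0.0]))
    ap = np.where(coronal.signed_distance(v) > 0, "A", "P")
    if sagittal is None:
        sagittal = Plane(centroid, np.array([1.0, 0.0, 0.0]))
    lr = np.where(sagittal.signed_distance(v) > 0, "L", "R")
    return np.char.add(np.char.add(ap, lr), band)


def segment_peaks(field: DisplacementField, labels: np.ndarray) -> SegmentPeaks:
    """Per-segment extrema of the signed field; empty sides contribute 0."""
    if len(field.values) != len(labels):
        raise ValueError("field and labels refer to different vertex sets")
    pos: dict[str, float] = {}
    neg: dict[str, float] = {}
    counts: dict[str, int] = {}
    empty = []
    for code in SEGMENT_CODES:
        mask = labels == code
        counts[code] = int(mask.sum())
        if counts[code] == 0:
            pos[code] = 0.0
            neg[code] = 0.0
            empty.append(code)
            continue
        vals = field.values[mask]
        p = vals[vals > 0]
        n = vals[vals < 0]
        pos[code] = float(p.max()) if len(p) else 0.0
        neg[code] = float(n.min()) if len(n) else 0.0
    return SegmentPeaks(
        peak_positive=pos, peak_negative=neg, counts=counts,
        empty_segments=tuple(empty),
    )
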