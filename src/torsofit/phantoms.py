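"""Synthetic torso phantoms, brace models and cohorts.

Real torso scans and CAD brace models are patient data and are not
redistributable, so every pipeline stage is exercised against parametric
phantoms instead: smooth generalized cylinders (elliptical cross-section
swept along z) with controllable mirror asymmetry — a laterally offset
centreline emulating curve convexity and an azimuthally Gaussian rib
hump.  Braces are derived from a torso by displacing the surface along
inward normals under Gaussian "pad" (pressure) and "relief" (expansion)
profiles, which mirrors how a CAD brace reshapes the captured torso.
Cohorts plant a known monotone segment-feature → in-brace-correction
effect so the statistical pipeline can be validated end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .displacement import (
    SEGMENT_CODES,
    partition_12_segments,
    segment_peaks,
    signed_displacement_field,
)
from .mesh import InvalidMeshError, SurfaceMesh, write_mesh
from .stats import PatientRecord, compute_ibc


def default_taper(t: np.ndarray) -> np.ndarray:
    """Mild waist: unit scale at the ends, 15% narrower mid-torso."""
    return 1.0 - 0.15 * np.sin(np.pi * t)


@dataclass(frozen=True)
class TorsoParams:
    """Parameters of the generalized-cylinder torso phantom (mm).

    With ``lateral_offset_amplitude = hump_amplitude = 0`` the phantom is
    exactly mirror-symmetric about x = 0 by construction.
    ``apex_z`` places the peak of the lateral centreline offset as a
    fraction of height (thoracic curves high, lumbar curves low);
    ``hump_azimuth`` is measured from +x (patient left) towards +y
    (anterior), so a posterior patient-right rib hump sits near -3π/4.
    """

    height: float = 450.0
    a_x: float = 140.0
    a_y: float = 110.0
    taper: Callable[[np.ndarray], np.ndarray] = default_taper
    lateral_offset_amplitude: float = 0.0
    apex_z: float = 0.5
    hump_amplitude: float = 0.0
    hump_center_z: float = 0.7
    hump_azimuth: float = -3.0 * math.pi / 4.0
    hump_width: float = 60.0
    n_rings: int = 48
    n_points: int = 48
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.a_x <= 0 or self.a_y <= 0:
            raise ValueError("height and half-axes must be positive")
        if self.n_rings < 24 or self.n_points < 24:
            raise ValueError("resolution must be at least 24 x 24")
        if self.n_points % 2:
            raise ValueError("n_points must be even (mirror-symmetric sampling)")
        if not 0.0 < self.apex_z < 1.0:
            raise ValueError("apex_z must lie in (0, 1)")


def _apex_warp(t: np.ndarray, apex: float) -> np.ndarray:
    """Monotone [0,1]→[0,1] warp sending ``apex`` to 1/2, so that
    sin(π·warp) peaks at the requested apex height."""
    expo = math.log(0.5) / math.log(apex)
    return np.clip(t, 0.0, 1.0) ** expo


def generate_torso(params: TorsoParams) -> SurfaceMesh:
    """Build a watertight capped torso phantom; deterministic for fixed params."""
    nr, na = params.n_rings, params.n_points
    z = np.linspace(0.0, params.height, nr)
    t = z / params.height
    scale = np.asarray(params.taper(t), dtype=np.float64)
    if np.any(scale <= 0):
        raise ValueError("taper must stay positive on [0, 1]")
    cx = params.lateral_offset_amplitude * np.sin(
        np.pi * _apex_warp(t, params.apex_z)
    )
    theta = 2.0 * np.pi * np.arange(na) / na

    X = cx[:, None] + (params.a_x * scale)[:, None] * np.cos(theta)[None, :]
    Y = (params.a_y * scale)[:, None] * np.sin(theta)[None, :]
    Z = np.repeat(z[:, None], na, axis=1)

    if params.hump_amplitude != 0.0:
        mean_r = 0.5 * (params.a_x + params.a_y)
        dtheta = np.angle(np.exp(1j * (theta - params.hump_azimuth)))
        arc = mean_r * dtheta
        dz = Z - params.hump_center_z * params.height
        bump = params.hump_amplitude * np.exp(
            -(arc[None, :] ** 2 + dz**2) / (2.0 * params.hump_width**2)
        )
        X += bump * np.cos(theta)[None, :]
        Y += bump * np.sin(theta)[None, :]

    vertices = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    faces = []
    for k in range(nr - 1):
        j = np.arange(na)
        j1 = (j + 1) % na
        v00 = k * na + j
        v01 = k * na + j1
        v10 = (k + 1) * na + j
        v11 = (k + 1) * na + j1
        faces.append(np.stack([v00, v01, v11], axis=1))
        faces.append(np.stack([v00, v11, v10], axis=1))
    bottom = len(vertices)
    top = bottom + 1
    vertices = np.concatenate(
        [vertices, [[cx[0], 0.0, 0.0]], [[cx[-1], 0.0, params.height]]]
    )
    j = np.arange(na)
    j1 = (j + 1) % na
    faces.append(np.stack([np.full(na, bottom), j1, j], axis=1))
    base = (nr - 1) * na
    faces.append(np.stack([np.full(na, top), base + j, base + j1], axis=1))
    mesh = SurfaceMesh(vertices, np.concatenate(faces))
    if mesh.trimesh.volume < 0:
        mesh = SurfaceMesh(vertices, np.concatenate(faces)[:, ::-1])
    return mesh


@dataclass(frozen=True)
class PadSpec:
    """One brace modification: a Gaussian pad pressed into (depth > 0,
    pressure) or relieved out of (depth < 0, expansion) a target segment."""

    segment: str
    depth: float
    width: float = 45.0

    def __post_init__(self):
        if self.segment not in SEGMENT_CODES:
            raise ValueError(f"unknown segment code {self.segment!r}")
        if self.width <= 0:
            raise ValueError("pad width must be positive")


_BAND_CENTER = {"U": 5.0 / 6.0, "M": 0.5, "L": 1.0 / 6.0}
_QUADRANT_AZIMUTH = {
    ("A", "L"): math.pi / 4.0,
    ("A", "R"): 3.0 * math.pi / 4.0,
    ("P", "R"): -3.0 * math.pi / 4.0,
    ("P", "L"): -math.pi / 4.0,
}


def generate_brace(torso: SurfaceMesh, pads: Sequence[PadSpec]) -> SurfaceMesh:
    """Derive a brace model by displacing the torso surface along inward
    vertex normals under summed Gaussian pad profiles.

    Each pad is centred on an actual torso vertex (the one closest to the
    nominal centre of its target segment in (z, azimuth) coordinates), so
    the planted peak depth is realised exactly at a sample point.
    """
    if not torso.is_watertight:
        raise InvalidMeshError("torso must be watertight")
    v = torso.vertices
    centroid = v.mean(axis=0)
    theta = np.arctan2(v[:, 1] - centroid[1], v[:, 0] - centroid[0])
    radius = np.hypot(v[:, 0] - centroid[0], v[:, 1] - centroid[1])
    mean_r = float(radius.mean())
    zmin, zmax = torso.z_range
    labels = partition_12_segments(torso)

    profile = np.zeros(len(v))
    for pad in pads:
        ap, lr, band = pad.segment[0], pad.segment[1], pad.segment[2]
        z_c = zmin + _BAND_CENTER[band] * (zmax - zmin)
        th_c = _QUADRANT_AZIMUTH[(ap, lr)]
        in_seg = labels == pad.segment
        if not in_seg.any():
            raise InvalidMeshError(f"segment {pad.segment} has no torso vertices")
        darc = mean_r * np.angle(np.exp(1j * (theta - th_c)))
        d2 = (v[:, 2] - z_c) ** 2 + darc**2
        center = np.flatnonzero(in_seg)[np.argmin(d2[in_seg])]
        darc_c = mean_r * np.angle(np.exp(1j * (theta - theta[center])))
        dist2 = (v[:, 2] - v[center, 2]) ** 2 + darc_c**2
        profile += pad.depth * np.exp(-dist2 / (2.0 * pad.width**2))

    # robust smallest half-axis estimate: ignore near-axis vertices (cap centres)
    ring_r = radius[radius > 1e-6]
    limit = 0.5 * float(np.percentile(ring_r, 5)) if len(ring_r) else 0.0
    if np.abs(profile).max() >= limit:
        raise InvalidMeshError(
            f"pad depth {np.abs(profile).max():.1f} mm risks self-intersection "
            f"(limit {limit:.1f} mm)"
        )
    normals = np.asarray(torso.trimesh.vertex_normals)
    return SurfaceMesh(v - normals * profile[:, None], torso.faces.copy())


@dataclass(frozen=True)
class CohortModel:
    """Generative model for a synthetic study cohort.

    Pre-brace Cobb-angle distributions default to the study-population
    values for main-thoracic (Lenke 1) and thoracolumbar/lumbar (Lenke 5)
    curves; draws are truncated at the 20° inclusion threshold (5° on the
    lateral view).  In-brace correction is generated top-down as
    ``IBC% = intercept + Σ coef · feature + ε`` over segment-peak
    features measured by the real geometry pipeline; the default single
    negative coefficient on the posterior-left-mid (PLM) peak-negative
    displacement, with noise SD 3.0, yields a population Spearman
    correlation of about -0.85 between that feature and IBC.
    """

    n_lenke1: int = 11
    n_lenke5: int = 14
    pre_ca_ap_mean_sd: dict = field(
        default_factory=lambda: {1: (38.4, 14.8), 5: (30.5, 5.8)}
    )
    pre_ca_lat_mean_sd: dict = field(
        default_factory=lambda: {1: (21.2, 15.0), 5: (48.3, 11.9)}
    )
    effects: dict = field(default_factory=lambda: {"peak_negative_PLM": -2.0})
    intercept: float = 25.0
    noise_sd: float = 3.0
    effects_lat: dict = field(default_factory=dict)
    intercept_lat: float = 10.0
    noise_sd_lat: float = 5.0
    pressure_depth_range: tuple[float, float] = (4.0, 10.0)
    relief_depth_range: tuple[float, float] = (2.0, 10.0)
    pad_width: float = 45.0
    resolution: tuple[int, int] = (32, 32)
    seed: int = 0

    def __post_init__(self):
        if self.n_lenke1 + self.n_lenke5 < 3:
            raise ValueError("cohort needs at least 3 patients")
        if self.noise_sd < 0 or self.noise_sd_lat < 0:
            raise ValueError("noise SD must be >= 0")


#: Pressure-pad target per curve type (3/4-point principle: push on the
#: convexity) and the relief segment carrying the planted effect.
_PRESSURE_SEGMENT = {1: "PRU", 5: "ARM"}
_RELIEF_SEGMENT = {1: "PLM", 5: "PLM"}


def _truncated_normal(rng, mean, sd, lower, tries=200):
    for _ in range(tries):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    return float(lower)


@dataclass
class SimulatedPatient:
    record: PatientRecord
    torso: SurfaceMesh
    brace: SurfaceMesh
    pads: tuple[PadSpec, ...]
    torso_params: TorsoParams


def generate_cohort(
    model: CohortModel,
    out_dir: Optional[Path] = None,
    keep_meshes: bool = False,
) -> tuple[list[PatientRecord], dict]:
    """Simulate a cohort through the real geometry pipeline.

    Per patient: draw curve angles and torso-shape parameters, build the
    torso and a brace with one pressure pad (on the curve convexity) and
    one relief pad (PLM), measure segment peaks from the signed
    displacement field, then set IBC from the planted effect model and
    back-compute the in-brace Cobb angle.  Fully deterministic per seed.
    Returns the records and a ground-truth dictionary (pad depths,
    planted effects, noise draws).  With ``out_dir`` set, writes PLY
    meshes, a manifest CSV and the ground truth JSON.
    """
    ss = np.random.SeedSequence(model.seed)
    groups = [(1, model.n_lenke1), (5, model.n_lenke5)]
    total = model.n_lenke1 + model.n_lenke5
    child_seeds = ss.spawn(total)
    records: list[PatientRecord] = []
    patients: list[SimulatedPatient] = []
    truth: dict = {
        "seed": model.seed,
        "effects": dict(model.effects),
        "intercept": model.intercept,
        "noise_sd": model.noise_sd,
        "patients": {},
    }
    nr, na = model.resolution
    idx = 0
    for lenke, n in groups:
        mu_ap, sd_ap = model.pre_ca_ap_mean_sd[lenke]
        mu_lat, sd_lat = model.pre_ca_lat_mean_sd[lenke]
        for k in range(n):
            rng = np.random.default_rng(child_seeds[idx])
            idx += 1
            pid = f"L{lenke}-{k + 1:02d}"
            pre_ap = _truncated_normal(rng, mu_ap, sd_ap, 20.0)
            pre_lat = _truncated_normal(rng, mu_lat, sd_lat, 5.0)

            sim = None
            for _ in range(10):
                params = TorsoParams(
                    height=float(rng.uniform(400.0, 500.0)),
                    a_x=float(rng.uniform(120.0, 160.0)),
                    a_y=float(rng.uniform(90.0, 120.0)),
                    lateral_offset_amplitude=float(rng.uniform(5.0, 20.0)),
                    apex_z=0.7 if lenke == 1 else 0.35,
                    hump_amplitude=float(rng.uniform(2.0, 10.0)),
                    hump_center_z=0.7 if lenke == 1 else 0.35,
                    hump_azimuth=(-3.0 * math.pi / 4.0)
                    if lenke == 1
                    else (-math.pi / 4.0),
                    n_rings=nr,
                    n_points=na,
                )
                pads = (
                    PadSpec(
                        _PRESSURE_SEGMENT[lenke],
                        float(rng.uniform(*model.pressure_depth_range)),
                        model.pad_width,
                    ),
                    PadSpec(
                        _RELIEF_SEGMENT[lenke],
                        -float(rng.uniform(*model.relief_depth_range)),
                        model.pad_width,
                    ),
                )
                try:
                    torso = generate_torso(params)
                    brace = generate_brace(torso, pads)
                except (InvalidMeshError, ValueError):
                    continue
                sim = (params, pads, torso, brace)
                break
            if sim is None:
                raise InvalidMeshError(f"could not build geometry for {pid}")
            params, pads, torso, brace = sim

            fld = signed_displacement_field(torso, brace)
            labels = partition_12_segments(torso)
            peaks = segment_peaks(fld, labels)

            eps = float(rng.normal(0.0, model.noise_sd)) if model.noise_sd else 0.0
            ibc_ap = model.intercept + sum(
                coef * peaks.feature(name) for name, coef in model.effects.items()
            ) + eps
            eps_lat = (
                float(rng.normal(0.0, model.noise_sd_lat)) if model.noise_sd_lat else 0.0
            )
            ibc_lat = model.intercept_lat + sum(
                coef * peaks.feature(name)
                for name, coef in model.effects_lat.items()
            ) + eps_lat
            ibc_ap = min(ibc_ap, 100.0)
            ibc_lat = min(ibc_lat, 100.0)

            record = PatientRecord(
                patient_id=pid,
                lenke_type=lenke,
                pre_ca_ap=pre_ap,
                inbrace_ca_ap=pre_ap * (1.0 - ibc_ap / 100.0),
                pre_ca_lat=pre_lat,
                inbrace_ca_lat=pre_lat * (1.0 - ibc_lat / 100.0),
                segment_peaks=peaks,
            )
            records.append(record)
            truth["patients"][pid] = {
                "pads": [
                    {"segment": p.segment, "depth_mm": p.depth, "width_mm": p.width}
                    for p in pads
                ],
                "ibc_ap_percent": ibc_ap,
                "ibc_lat_percent": ibc_lat,
                "noise_ap": eps,
                "noise_lat": eps_lat,
                "measured_peak_negative_PLM": peaks.feature("peak_negative_PLM"),
            }
            if keep_meshes or out_dir is not None:
                patients.append(
                    SimulatedPatient(record, torso, brace, pads, params)
                )

    if out_dir is not None:
        _write_cohort(Path(out_dir), patients, truth)
    if keep_meshes:
        truth["_patients"] = patients
    return records, truth


def _write_cohort(out_dir: Path, patients: list[SimulatedPatient], truth: dict):
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        torso_path = out_dir / f"{p.record.patient_id}_torso.ply"
        brace_path = out_dir / f"{p.record.patient_id}_brace.ply"
        write_mesh(p.torso, torso_path)
        write_mesh(p.brace, brace_path)
        rows.append(
            {
                "patient_id": p.record.patient_id,
                "torso_path": torso_path.name,
                "brace_path": brace_path.name,
                "lenke_type": p.record.lenke_type,
                "pre_ca_ap": round(p.record.pre_ca_ap, 6),
                "inbrace_ca_ap": round(p.record.inbrace_ca_ap, 6),
                "pre_ca_lat": round(p.record.pre_ca_lat, 6),
                "inbrace_ca_lat": round(p.record.inbrace_ca_lat, 6),
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
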