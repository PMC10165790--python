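"""End-to-end orchestration: per-patient metrics and cohort tables.

``run_patient`` turns one torso/brace mesh pair plus radiographic angles
into a :class:`~torsofit.stats.PatientRecord` (asymmetry indices, signed
displacement field, 12-segment peaks, in-brace correction).
``run_cohort`` maps a manifest CSV over patients — one failing patient
never aborts the cohort — and emits the standard table set: a cohort
summary, an asymmetry table (per-group mean ± SD and correlations with
curve angles / correction), and four segment-peak correlation tables
(Lenke 1 / 5 × AP / lateral outcome).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import IcpConfig, asymmetry_index
from .displacement import partition_12_segments, segment_peaks, signed_displacement_field
from .mesh import Plane, read_mesh
from .stats import (
    PEAK_FEATURES,
    PatientRecord,
    classify_strength,
    correlation_table,
    spearman_rho,
    summarize_cohort,
)

log = logging.getLogger("torsofit")

MANIFEST_COLUMNS = [
    "patient_id",
    "torso_path",
    "brace_path",
    "lenke_type",
    "pre_ca_ap",
    "inbrace_ca_ap",
    "pre_ca_lat",
    "inbrace_ca_lat",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a cohort run; hashed into outputs for provenance."""

    manifest: Path
    out_dir: Path
    voxel_pitch: float = 2.0
    icp: IcpConfig = field(default_factory=IcpConfig)
    sagittal_plane: Optional[Plane] = None
    outcomes: tuple[str, ...] = ("IBC_AP", "IBC_LAT")
    seed: int = 0

    def __post_init__(self):
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be > 0")
        object.__setattr__(self, "manifest", Path(self.manifest))
        object.__setattr__(self, "out_dir", Path(self.out_dir))

    def config_hash(self) -> str:
        payload = {
            "voxel_pitch": self.voxel_pitch,
            "icp": [
                self.icp.max_iterations,
                self.icp.convergence_tol,
                self.icp.sample_size,
                self.icp.seed,
            ],
            "sagittal_plane": None
            if self.sagittal_plane is None
            else self.sagittal_plane.point.tolist()
            + self.sagittal_plane.normal.tolist(),
            "outcomes": list(self.outcomes),
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_patient(
    torso_path,
    brace_path,
    patient_id: str,
    lenke_type: int,
    pre_ca_ap: float,
    inbrace_ca_ap: float,
    pre_ca_lat: float,
    inbrace_ca_lat: float,
    config: RunConfig,
    out_path: Optional[Path] = None,
) -> PatientRecord:
    """Full single-patient analysis; optionally writes a JSON result file."""
    torso = read_mesh(torso_path)
    brace = read_mesh(brace_path)
    icp_cfg = IcpConfig(
        max_iterations=config.icp.max_iterations,
        convergence_tol=config.icp.convergence_tol,
        sample_size=config.icp.sample_size,
        seed=config.icp.seed + config.seed,
    )
    asym_torso = asymmetry_index(
        torso, icp_cfg, config.voxel_pitch, config.sagittal_plane
    )
    asym_brace = asymmetry_index(
        brace, icp_cfg, config.voxel_pitch, config.sagittal_plane
    )
    fld = signed_displacement_field(torso, brace)
    labels = partition_12_segments(torso, config.sagittal_plane)
    peaks = segment_peaks(fld, labels)
    record = PatientRecord(
        patient_id=str(patient_id),
        lenke_type=int(lenke_type),
        pre_ca_ap=float(pre_ca_ap),
        inbrace_ca_ap=float(inbrace_ca_ap),
        pre_ca_lat=float(pre_ca_lat),
        inbrace_ca_lat=float(inbrace_ca_lat),
        segment_peaks=peaks,
        asymmetry_torso=asym_torso.asymmetry_percent,
        asymmetry_brace=asym_brace.asymmetry_percent,
    )
    if out_path is not None:
        payload = {
            "patient_id": record.patient_id,
            "lenke_type": record.lenke_type,
            "ibc_ap_percent": record.ibc_ap_percent,
            "ibc_lat_percent": record.ibc_lat_percent,
            "asymmetry_torso": asym_torso.as_dict(),
            "asymmetry_brace": asym_brace.as_dict(),
            "segment_peaks": peaks.as_rows(),
            "config_hash": config.config_hash(),
            "version": __version__,
        }
        Path(out_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return record


def _asymmetry_table(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for lenke in (1, 5):
        group = [r for r in records if r.lenke_type == lenke]
        if len(group) < 3:
            continue
        asym = np.array([r.asymmetry_torso for r in group], dtype=float)
        asym_b = np.array([r.asymmetry_brace for r in group], dtype=float)
        rows.append(
            {
                "lenke_type": lenke,
                "n": len(group),
                "torso_asymmetry_mean": asym.mean(),
                "torso_asymmetry_sd": asym.std(ddof=1),
                "brace_asymmetry_mean": asym_b.mean(),
                "brace_asymmetry_sd": asym_b.std(ddof=1),
            }
        )
        for name, values in [
            ("pre_ca_ap", [r.pre_ca_ap for r in group]),
            ("ibc_ap_percent", [r.ibc_ap_percent for r in group]),
            ("pre_ca_lat", [r.pre_ca_lat for r in group]),
            ("ibc_lat_percent", [r.ibc_lat_percent for r in group]),
        ]:
            rho = spearman_rho(asym, values)
            rows[-1][f"rho_torso_asymmetry_vs_{name}"] = rho
            rows[-1][f"category_vs_{name}"] = classify_strength(rho)
    return pd.DataFrame(rows)


def run_cohort(config: RunConfig) -> dict:
    """Run every manifest patient and write the table files and run report.

    Returns the report dictionary (also written as ``run_report.json``).
    """
    manifest = pd.read_csv(config.manifest)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    base = config.manifest.parent

    records: list[PatientRecord] = []
    status: dict[str, str] = {}
    for row in manifest.itertuples(index=False):
        pid = str(row.patient_id)
        try:
            rec = run_patient(
                base / row.torso_path,
                base / row.brace_path,
                pid,
                row.lenke_type,
                row.pre_ca_ap,
                row.inbrace_ca_ap,
                row.pre_ca_lat,
                row.inbrace_ca_lat,
                config,
                out_path=out / f"patient_{pid}.json",
            )
            records.append(rec)
            status[pid] = "ok"
            log.info("patient %s: ok", pid)
        except Exception as exc:  # per-patient isolation
            status[pid] = f"failed: {exc}"
            log.warning("patient %s failed: %s", pid, exc)

    tables: list[str] = []
    skipped: dict[str, str] = {}
    if records:
        summarize_cohort(records).to_csv(
            out / "cohort_summary.csv", index=False, float_format="%.6f"
        )
        tables.append("cohort_summary.csv")
        asym_tab = _asymmetry_table(records)
        asym_tab.to_csv(out / "asymmetry_table.csv", index=False, float_format="%.6f")
        tables.append("asymmetry_table.csv")
    for lenke in (1, 5):
        for outcome in config.outcomes:
            name = f"correlations_lenke{lenke}_{outcome.split('_')[1].lower()}.csv"
            try:
                tab = correlation_table(records, lenke, outcome, PEAK_FEATURES)
                tab.to_csv(out / name)
                tables.append(name)
            except ValueError as exc:
                skipped[name] = str(exc)
    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_manifest": int(len(manifest)),
        "n_succeeded": sum(1 for s in status.values() if s == "ok"),
        "n_failed": sum(1 for s in status.values() if s != "ok"),
        "patients": status,
        "tables": tables,
        "skipped_tables": skipped,
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
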