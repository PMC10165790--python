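"""Cohort-level statistics: in-brace correction, Spearman correlations
between shape features and correction, and the standard summary tables.

In-brace correction (IBC) is the percentage reduction of the major-curve
Cobb angle when the brace is first worn:
``IBC = 100 * (CA_pre - CA_inbrace) / CA_pre``.  Correlations are
Spearman rank correlations, reported with the conventional strength
bins: |rho| in [0.90, 1.00] very strong, [0.70, 0.90) strong,
[0.50, 0.70) moderate, (0.25, 0.50) weak, [0, 0.25] little if any.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .displacement import SEGMENT_CODES, SegmentPeaks

#: Feature order used by the correlation tables: all peak-positive rows
#: ALU..PRL, then all peak-negative rows ALU..PRL.
PEAK_FEATURES = tuple(
    [f"peak_positive_{c}" for c in SEGMENT_CODES]
    + [f"peak_negative_{c}" for c in SEGMENT_CODES]
)

STRENGTH_BINS = (
    (0.90, "very strong"),
    (0.70, "strong"),
    (0.50, "moderate"),
    # (0.25, 0.50) weak; [0, 0.25] little if any — handled below
)


@dataclass
class PatientRecord:
    """One patient: curve measurements plus pipeline-derived shape features."""

    patient_id: str
    lenke_type: int
    pre_ca_ap: float
    inbrace_ca_ap: float
    pre_ca_lat: float
    inbrace_ca_lat: float
    segment_peaks: Optional[SegmentPeaks] = None
    asymmetry_torso: Optional[float] = None
    asymmetry_brace: Optional[float] = None

    def __post_init__(self):
        if self.lenke_type not in (1, 5):
            raise ValueError("lenke_type must be 1 or 5")
        for name in ("pre_ca_ap", "inbrace_ca_ap", "pre_ca_lat", "inbrace_ca_lat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 degrees")

    @property
    def ibc_ap_percent(self) -> float:
        return compute_ibc(self.pre_ca_ap, self.inbrace_ca_ap)

    @property
    def ibc_lat_percent(self) -> float:
        return compute_ibc(self.pre_ca_lat, self.inbrace_ca_lat)

    def feature(self, name: str) -> float:
        if name == "asymmetry_torso":
            return float(self.asymmetry_torso)
        if name == "asymmetry_brace":
            return float(self.asymmetry_brace)
        if self.segment_peaks is None:
            raise KeyError(f"record {self.patient_id} has no segment peaks")
        return self.segment_peaks.feature(name)


def compute_ibc(pre_ca: float, inbrace_ca: float) -> float:
    """Initial in-brace correction in % (negative = in-brace worsening)."""
    if pre_ca <= 0:
        raise ValueError("pre-brace Cobb angle must be > 0 degrees")
    return 100.0 * (pre_ca - inbrace_ca) / pre_ca


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Returns NaN (an undefined correlation, not an error) when either
    vector is constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(sps.spearmanr(x, y).statistic)


def classify_strength(rho: float) -> str:
    """Conventional interpretation bin for |rho| ('undefined' for NaN)."""
    if math.isnan(rho):
        return "undefined"
    mag = abs(rho)
    if mag > 1.0 + 1e-12:
        raise ValueError(f"|rho| = {mag} exceeds 1")
    for lo, name in STRENGTH_BINS:
        if mag >= lo:
            return name
    return "weak" if mag > 0.25 else "little if any"


@dataclass
class CorrelationTable:
    """Per-feature Spearman rho against one outcome within one Lenke group."""

    lenke_type: int
    outcome: str
    rows: pd.DataFrame  # columns: feature, rho, category, n

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6f")


def correlation_table(
    records: Iterable[PatientRecord],
    lenke_type: int,
    outcome: str = "IBC_AP",
    features: Sequence[str] = PEAK_FEATURES,
) -> CorrelationTable:
    """Spearman rho of each feature against IBC for one curve-type group."""
    if outcome not in ("IBC_AP", "IBC_LAT"):
        raise ValueError("outcome must be IBC_AP or IBC_LAT")
    group = [r for r in records if r.lenke_type == lenke_type]
    if len(group) < 3:
        raise ValueError(
            f"need >= 3 records of Lenke type {lenke_type}, got {len(group)}"
        )
    y = np.array(
        [r.ibc_ap_percent if outcome == "IBC_AP" else r.ibc_lat_percent for r in group]
    )
    rows = []
    for name in features:
        x = np.array([r.feature(name) for r in group])
        rho = spearman_rho(x, y)
        rows.append(
            {
                "feature": name,
                "rho": rho,
                "category": classify_strength(rho),
                "n": len(group),
            }
        )
    return CorrelationTable(
        lenke_type=lenke_type, outcome=outcome, rows=pd.DataFrame(rows)
    )


def summarize_cohort(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Mean ± sample SD of curve and shape variables per Lenke group.

    SD uses the n-1 denominator and is NaN (flagged undefined) for
    single-record groups.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    rows = []
    for r in records:
        row = {
            "lenke_type": r.lenke_type,
            "pre_ca_ap": r.pre_ca_ap,
            "ibc_ap_deg": r.pre_ca_ap - r.inbrace_ca_ap,
            "ibc_ap_percent": r.ibc_ap_percent,
            "pre_ca_lat": r.pre_ca_lat,
            "ibc_lat_deg": r.pre_ca_lat - r.inbrace_ca_lat,
            "ibc_lat_percent": r.ibc_lat_percent,
        }
        if r.asymmetry_torso is not None:
            row["asymmetry_torso_percent"] = r.asymmetry_torso
        if r.asymmetry_brace is not None:
            row["asymmetry_brace_percent"] = r.asymmetry_brace
        rows.append(row)
    df = pd.DataFrame(rows)
    agg = df.groupby("lenke_type").agg(["mean", "std", "count"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
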