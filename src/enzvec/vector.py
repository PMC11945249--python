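"""Enzyme-stoichiometry vector analysis.

Five terminal hydrolase activities are grouped into carbon- (BG + CBH),
nitrogen- (NAG + LAP) and phosphorus-acquisition (AP) totals. Two unitless
proportions

    x = C / (C + P)        y = C / (C + N)

locate a sample in the unit square. The vector from the origin to (x, y)
summarises metabolic limitation: its length ``sqrt(x**2 + y**2)`` indexes
carbon limitation, and its angle from the positive x-axis (degrees)
separates nitrogen limitation (< 45°) from phosphorus limitation (> 45°).
For P limitation, severity grows with the angle; for N limitation it grows
as the angle shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .errors import DomainError

__all__ = [
    "Limitation",
    "EnzymeActivities",
    "EnzymeRatios",
    "VectorStats",
    "group_activities",
    "enzyme_ratios",
    "vector_length",
    "vector_angle",
    "classify_limitation",
    "limitation_severity",
    "mml_from_activities",
    "mml_table",
    "ACTIVITY_COLUMNS",
]

ACTIVITY_COLUMNS = ["bg", "cbh", "nag", "lap", "ap"]

MML_COLUMNS = [
    "sample_id",
    "x",
    "y",
    "vector_length",
    "vector_angle_deg",
    "limitation_class",
]


class Limitation(str, Enum):
    """N/P limitation class from the 45° rule."""

    N_LIMITED = "N_LIMITED"
    P_LIMITED = "P_LIMITED"
    BALANCED = "BALANCED"


@dataclass(frozen=True)
class EnzymeActivities:
    """Per-sample activities of the five hydrolases, nmol g⁻¹ h⁻¹."""

    bg: float
    cbh: float
    nag: float
    lap: float
    ap: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name in ACTIVITY_COLUMNS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(
                    f"activity {name!r} must be finite and >= 0, got {v}"
                )


@dataclass(frozen=True)
class EnzymeRatios:
    """Stoichiometric proportions, both strictly inside (0, 1)."""

    x: float  # C vs P acquisition
    y: float  # C vs N acquisition

    def __post_init__(self) -> None:
        if not (0.0 < self.x < 1.0 and 0.0 < self.y < 1.0):
            raise DomainError(f"ratios must lie in (0, 1), got x={self.x}, y={self.y}")


@dataclass(frozen=True)
class VectorStats:
    """Limitation summary for one sample."""

    length: float
    angle_deg: float
    limitation_class: Limitation
    x: float
    y: float
    sample_id: str = ""


def group_activities(
    acts: EnzymeActivities, include_cbh: bool = True
) -> tuple[float, float, float]:
    """Sum activities into (C, N, P) acquisition totals.

    ``include_cbh=False`` restricts the C group to BG alone (a convention
    used by some studies); the default includes both cellulolytic enzymes.
    Raises :class:`DomainError` naming the first group whose total is zero.
    """
    c_total = acts.bg + (acts.cbh if include_cbh else 0.0)
    n_total = acts.nag + acts.lap
    p_total = acts.ap
    for name, total in (("C", c_total), ("N", n_total), ("P", p_total)):
        if total <= 0:
            raise DomainError(f"{name} group zero for sample {acts.sample_id!r}")
    return c_total, n_total, p_total


def enzyme_ratios(c_total: float, n_total: float, p_total: float) -> EnzymeRatios:
    """x = C/(C+P), y = C/(C+N); all totals must be > 0."""
    if min(c_total, n_total, p_total) <= 0:
        raise DomainError("all group totals must be positive")
    return EnzymeRatios(
        x=c_total / (c_total + p_total),
        y=c_total / (c_total + n_total),
    )


def vector_length(r: EnzymeRatios) -> float:
    """Euclidean length of (x, y); indexes microbial C limitation."""
    return math.hypot(r.x, r.y)


def vector_angle(r: EnzymeRatios) -> float:
    """Angle of point (x, y) from the positive x-axis, in degrees.

    Exactly 45.0 when x == y, so the balanced boundary is representable.
    """
    if r.x <= 0:
        raise DomainError("x must be positive")
    if r.x == r.y:
        return 45.0
    return math.degrees(math.atan2(r.y, r.x))


def classify_limitation(angle_deg: float) -> Limitation:
    """Apply the 45° rule; angle must lie strictly inside (0, 90)."""
    if not 0.0 < angle_deg < 90.0:
        raise DomainError(f"angle must be in (0, 90) degrees, got {angle_deg}")
    if angle_deg > 45.0:
        return Limitation.P_LIMITED
    if angle_deg < 45.0:
        return Limitation.N_LIMITED
    return Limitation.BALANCED


def limitation_severity(angle_deg: float) -> float:
    """Signed distance from the balanced boundary, degrees.

    Positive values mean P limitation whose severity grows with the angle;
    negative values mean N limitation whose severity grows as the angle
    falls below 45°.
    """
    if not 0.0 < angle_deg < 90.0:
        raise DomainError(f"angle must be in (0, 90) degrees, got {angle_deg}")
    return angle_deg - 45.0


def _log_transform_totals(totals: tuple[float, float, float]) -> tuple[float, float, float]:
    # log1p keeps totals positive for small activities; documented variant only
    return tuple(math.log1p(t) for t in totals)  # type: ignore[return-value]


def mml_from_activities(
    acts: EnzymeActivities,
    include_cbh: bool = True,
    log_ratios: bool = False,
) -> VectorStats:
    """Full deterministic chain: activities → ratios → length/angle/class.

    ``log_ratios=True`` computes the proportions on log1p-transformed group
    totals (a documented variant, off by default); the primary definition
    uses the untransformed activities.
    """
    totals = group_activities(acts, include_cbh=include_cbh)
    if log_ratios:
        totals = _log_transform_totals(totals)
    r = enzyme_ratios(*totals)
    angle = vector_angle(r)
    return VectorStats(
        length=vector_length(r),
        angle_deg=angle,
        limitation_class=classify_limitation(angle),
        x=r.x,
        y=r.y,
        sample_id=acts.sample_id,
    )


def mml_table(
    activities: pd.DataFrame,
    include_cbh: bool = True,
    log_ratios: bool = False,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Table version of :func:`mml_from_activities`.

    Expects columns ``sample_id,bg,cbh,nag,lap,ap``; returns
    ``(mml_table, error_table)``. With ``on_error="raise"`` (default) the
    first invalid row raises :class:`DomainError`; with ``"collect"``
    invalid rows are reported in the error table (``sample_id,error``)
    instead.
    """
    if on_error not in ("raise", "collect"):
        raise ValueError("on_error must be 'raise' or 'collect'")
    missing = [c for c in ["sample_id", *ACTIVITY_COLUMNS] if c not in activities.columns]
    if missing:
        raise DomainError(f"activity table missing columns: {missing}")
    rows, errors = [], []
    for rec in activities.itertuples(index=False):
        try:
            acts = EnzymeActivities(
                bg=float(rec.bg),
                cbh=float(rec.cbh),
                nag=float(rec.nag),
                lap=float(rec.lap),
                ap=float(rec.ap),
                sample_id=str(rec.sample_id),
            )
            st = mml_from_activities(acts, include_cbh=include_cbh, log_ratios=log_ratios)
        except DomainError as exc:
            if on_error == "raise":
                raise
            errors.append({"sample_id": str(rec.sample_id), "error": str(exc)})
            continue
        rows.append(
            {
                "sample_id": st.sample_id,
                "x": st.x,
                "y": st.y,
                "vector_length": st.length,
                "vector_angle_deg": st.angle_deg,
                "limitation_class": st.limitation_class.value,
            }
        )
    return (
        pd.DataFrame(rows, columns=MML_COLUMNS),
        pd.DataFrame(errors, columns=["sample_id", "error"]),
    )
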