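"""Reduction of fluorimetric microplate readings to enzyme activities.

Sediment suspensions quench fluorophore emission to a degree that varies
sample by sample, so every sample carries its own quenched standard. The
reduction chain per (sample, enzyme) plate group is

    q   = (mean quench standard − mean homogenate control) / mean reference standard
    e   = mean reference standard / standard amount            [RFU per nmol]
    net = (mean assay − mean homogenate control) / q − mean substrate control
          [− (mean abiotic control − mean substrate control) when present]
    activity = net / e × (suspension volume / well aliquot)
               / (dry mass × incubation time)                  [nmol g⁻¹ h⁻¹]

Negative net activities are clamped to zero and flagged.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import AssayError, InputError

__all__ = [
    "AssayParams",
    "PlateReading",
    "ActivityResult",
    "ENZYMES",
    "WELL_ROLES",
    "quench_coefficient",
    "emission_coefficient",
    "net_fluorescence",
    "activity",
    "reduce_plate_set",
    "read_plate_csv",
    "qc_table",
]

logger = logging.getLogger(__name__)

ENZYMES = ("BG", "CBH", "NAG", "LAP", "AP")

WELL_ROLES = (
    "assay",
    "quench_standard",
    "substrate_control",
    "reference_standard",
    "homogenate_control",
    "abiotic_control",
)

#: QC conventions, not measured values; override per call where needed.
DEFAULT_CV_THRESHOLD = 0.3
DEFAULT_LOW_QUENCH_THRESHOLD = 0.2


@dataclass(frozen=True)
class AssayParams:
    """Physical parameters of the incubation and the standard wells.

    Defaults follow a 1 g / 10 mL sediment suspension incubated 0.5 h with
    0.2 mM substrate. ``standard_amount`` is the nmol of free fluorophore
    (4-MUB or 7-AMC) in a standard well. Buffer identity, temperature and
    excitation/emission wavelengths are metadata only.
    """

    sediment_dry_mass: float = 1.0  # g
    suspension_volume: float = 10.0  # mL
    well_aliquot_volume: float = 0.2  # mL
    incubation_time: float = 0.5  # h
    substrate_final_conc: float = 0.2  # mM
    standard_amount: float = 10.0  # nmol
    temperature_c: float = 15.0
    fluorophore: str = "MUB"
    excitation_emission: tuple[float, float] = (365.0, 455.0)

    def __post_init__(self) -> None:
        for name in (
            "sediment_dry_mass",
            "suspension_volume",
            "well_aliquot_volume",
            "incubation_time",
            "substrate_final_conc",
            "standard_amount",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"assay parameter {name!r} must be > 0")


@dataclass(frozen=True)
class PlateReading:
    """All wells for one (sample, enzyme) combination, RFU."""

    sample_id: str
    enzyme: str
    assay_wells: tuple[float, ...]
    quench_standard_wells: tuple[float, ...]
    substrate_control_wells: tuple[float, ...]
    reference_standard_wells: tuple[float, ...]
    homogenate_control_wells: tuple[float, ...] = ()
    abiotic_control_wells: tuple[float, ...] = ()
    params: AssayParams = field(default_factory=AssayParams)

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise InputError(f"unknown enzyme {self.enzyme!r}")
        if len(self.assay_wells) < 3:
            raise InputError(
                f"{self.sample_id}/{self.enzyme}: need >= 3 assay replicates, "
                f"got {len(self.assay_wells)}"
            )
        for role in ("assay_wells", "quench_standard_wells",
                     "substrate_control_wells", "reference_standard_wells",
                     "homogenate_control_wells", "abiotic_control_wells"):
            if any(v < 0 for v in getattr(self, role)):
                raise InputError(f"{self.sample_id}/{self.enzyme}: negative RFU in {role}")


@dataclass(frozen=True)
class ActivityResult:
    sample_id: str
    enzyme: str
    activity: float  # nmol g⁻¹ h⁻¹, >= 0
    quench_coefficient: float
    replicate_cv: float
    qc_flags: frozenset[str] = frozenset()


def _mean(wells: Sequence[float], what: str) -> float:
    if not wells:
        raise AssayError(f"no wells for {what}")
    return sum(wells) / len(wells)


def quench_coefficient(reading: PlateReading) -> float:
    """Per-sample matrix quench coefficient q.

    q = (mean quench standard − mean homogenate control) / mean reference
    standard. Raises :class:`AssayError` when the standard is fully
    quenched (q ≤ 0) or the reference mean is nonpositive.
    """
    ref = _mean(reading.reference_standard_wells, "reference standard")
    if ref <= 0:
        raise AssayError(f"{reading.sample_id}/{reading.enzyme}: reference standard mean <= 0")
    homog = (
        _mean(reading.homogenate_control_wells, "homogenate control")
        if reading.homogenate_control_wells
        else 0.0
    )
    q = (_mean(reading.quench_standard_wells, "quench standard") - homog) / ref
    if q <= 0:
        raise AssayError(
            f"{reading.sample_id}/{reading.enzyme}: quench coefficient {q:.4g} <= 0 "
            "(standard fully quenched or wells mislabelled)"
        )
    return q


def emission_coefficient(reading: PlateReading) -> float:
    """Reference-standard scaling, RFU per nmol of free fluorophore."""
    ref = _mean(reading.reference_standard_wells, "reference standard")
    if ref <= 0:
        raise AssayError(f"{reading.sample_id}/{reading.enzyme}: reference standard mean <= 0")
    return ref / reading.params.standard_amount


def net_fluorescence(reading: PlateReading) -> float:
    """Quench-corrected, control-subtracted fluorescence. May be negative."""
    q = quench_coefficient(reading)
    homog = (
        _mean(reading.homogenate_control_wells, "homogenate control")
        if reading.homogenate_control_wells
        else 0.0
    )
    substrate = _mean(reading.substrate_control_wells, "substrate control")
    net = (_mean(reading.assay_wells, "assay") - homog) / q - substrate
    if reading.abiotic_control_wells:
        net -= _mean(reading.abiotic_control_wells, "abiotic control") - substrate
    return net


def activity(
    reading: PlateReading,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    low_quench_threshold: float = DEFAULT_LOW_QUENCH_THRESHOLD,
) -> ActivityResult:
    """Reduce one plate group to an activity in nmol g⁻¹ h⁻¹."""
    p = reading.params
    q = quench_coefficient(reading)
    e = emission_coefficient(reading)
    net = net_fluorescence(reading)

    a = (
        net
        / e
        * (p.suspension_volume / p.well_aliquot_volume)
        / (p.sediment_dry_mass * p.incubation_time)
    )

    flags: set[str] = set()
    if a < 0:
        a = 0.0
        flags.add("NEGATIVE_CLAMPED")
    if q < low_quench_threshold:
        flags.add("LOW_QUENCH")

    mean_assay = _mean(reading.assay_wells, "assay")
    cv = (
        statistics.stdev(reading.assay_wells) / mean_assay
        if mean_assay > 0 and len(reading.assay_wells) > 1
        else 0.0
    )
    if cv > cv_threshold:
        flags.add("HIGH_CV")

    return ActivityResult(
        sample_id=reading.sample_id,
        enzyme=reading.enzyme,
        activity=a,
        quench_coefficient=q,
        replicate_cv=cv,
        qc_flags=frozenset(flags),
    )


def reduce_plate_set(
    readings: Iterable[PlateReading],
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    low_quench_threshold: float = DEFAULT_LOW_QUENCH_THRESHOLD,
) -> tuple[list[ActivityResult], pd.DataFrame]:
    """Reduce every reading and assemble the per-sample activity table.

    Returns ``(results, activity_table)``. Only samples with all five
    enzymes present appear in the table; incomplete samples are logged and
    excluded. Duplicate (sample, enzyme) pairs raise :class:`InputError`.
    """
    seen: set[tuple[str, str]] = set()
    results: list[ActivityResult] = []
    for reading in readings:
        key = (reading.sample_id, reading.enzyme)
        if key in seen:
            raise InputError(f"duplicate plate group for {key}")
        seen.add(key)
        results.append(
            activity(reading, cv_threshold=cv_threshold,
                     low_quench_threshold=low_quench_threshold)
        )

    by_sample: dict[str, dict[str, float]] = {}
    for r in results:
        by_sample.setdefault(r.sample_id, {})[r.enzyme.lower()] = r.activity

    rows = []
    for sample_id, enzymes in by_sample.items():
        if len(enzymes) == len(ENZYMES):
            rows.append({"sample_id": sample_id, **enzymes})
        else:
            missing = sorted(e.lower() for e in ENZYMES if e.lower() not in enzymes)
            logger.warning("sample %s missing enzymes %s; excluded from activity table",
                           sample_id, missing)
    table = pd.DataFrame(rows, columns=["sample_id", "bg", "cbh", "nag", "lap", "ap"])
    return results, table


def qc_table(results: Sequence[ActivityResult]) -> pd.DataFrame:
    """QC report with one row per (sample, enzyme)."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "enzyme": r.enzyme,
                "activity": r.activity,
                "quench_coefficient": r.quench_coefficient,
                "replicate_cv": r.replicate_cv,
                "qc_flags": ";".join(sorted(r.qc_flags)),
            }
            for r in results
        ],
        columns=["sample_id", "enzyme", "activity", "quench_coefficient",
                 "replicate_cv", "qc_flags"],
    )


def read_plate_csv(path, params: AssayParams | None = None) -> list[PlateReading]:
    """Parse the long-format plate CSV ``sample_id,enzyme,well_role,rfu``."""
    params = params or AssayParams()
    df = pd.read_csv(path, dtype={"sample_id": str, "enzyme": str, "well_role": str})
    required = {"sample_id", "enzyme", "well_role", "rfu"}
    if not required.issubset(df.columns):
        raise InputError(f"plate CSV must have columns {sorted(required)}")
    bad_roles = set(df["well_role"]) - set(WELL_ROLES)
    if bad_roles:
        raise InputError(f"unknown well_role values: {sorted(bad_roles)}")
    if df["rfu"].isna().any():
        raise InputError("plate CSV contains missing RFU values")

    readings = []
    for (sample_id, enzyme), grp in df.groupby(["sample_id", "enzyme"], sort=True):
        wells = {role: tuple(grp.loc[grp["well_role"] == role, "rfu"].astype(float))
                 for role in WELL_ROLES}
        readings.append(
            PlateReading(
                sample_id=str(sample_id),
                enzyme=str(enzyme),
                assay_wells=wells["assay"],
                quench_standard_wells=wells["quench_standard"],
                substrate_control_wells=wells["substrate_control"],
                reference_standard_wells=wells["reference_standard"],
                homogenate_control_wells=wells["homogenate_control"],
                abiotic_control_wells=wells["abiotic_control"],
                params=params,
            )
        )
    return readings
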