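"""Synthetic lake-sediment cohort generator.

Produces site-level records over a 25-lake salinity gradient whose summary
statistics are calibrated, not hand-tuned: a standardized Gaussian latent
system is solved so that, at scale, the log-log regressions of vector
length and angle on salinity, and the marginal/partial couplings of
sediment organic carbon (SOC) with vector length, recover the configured
targets.

Latent system (s = standardized ln-salinity across sites; u, v iid N(0,1)):

    L = α·s + sqrt(1 − α²)·u            α = sqrt(r²_salinity_length)
    S = β·s + γ·u + sqrt(1 − β² − γ²)·v

with (β, γ) solved so that corr(S, L)² equals the marginal SOC–length R²
(negative branch: SOC falls as C limitation rises) and γ²/(1 − β²) equals
the partial R² after controlling salinity. ln(length) is affine in L and
ln(SOC) affine in S, so the calibration carries through the log-log fits.
The vector angle is drawn linearly in s around the configured mean with the
configured R² split.

Sites whose implied (x, y) ratios leave the unit square (or whose angle
leaves (5°, 85°)) are redrawn — truncation by resampling, with the count
recorded — rather than clipped.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .assay import ENZYMES, AssayParams, PlateReading
from .errors import ConfigError, DomainError
from .stats import SALINITY_THRESHOLDS, SalinityClass, classify_salinity
from .vector import EnzymeActivities, mml_from_activities

__all__ = [
    "GradientConfig",
    "solve_covariance",
    "generate_cohort",
    "latent_to_activities",
    "simulate_plate",
    "simulate_cohort_plates",
    "COHORT_COLUMNS",
]

#: draw bands (‰) per class, kept slightly inside the classification
#: thresholds so site-level jitter cannot cross a class boundary
_DRAW_BANDS = {
    SalinityClass.FRESHWATER: (0.13, 0.47),
    SalinityClass.SUBSALINE: (0.53, 2.85),
    SalinityClass.HYPOSALINE: (3.15, 19.0),
    SalinityClass.MESOSALINE: (21.0, 31.06),
}

_CLASS_BANDS = {
    SalinityClass.FRESHWATER: (1e-6, SALINITY_THRESHOLDS[0] * (1 - 1e-9)),
    SalinityClass.SUBSALINE: (SALINITY_THRESHOLDS[0], SALINITY_THRESHOLDS[1] * (1 - 1e-9)),
    SalinityClass.HYPOSALINE: (SALINITY_THRESHOLDS[1], SALINITY_THRESHOLDS[2] * (1 - 1e-9)),
    SalinityClass.MESOSALINE: (SALINITY_THRESHOLDS[2], 1e6),
}

_CLASS_ORDER = (
    SalinityClass.FRESHWATER,
    SalinityClass.SUBSALINE,
    SalinityClass.HYPOSALINE,
    SalinityClass.MESOSALINE,
)

#: default per-lake site counts (1–4 sites, more in larger lakes),
#: totalling 44 sites over 9 + 8 + 6 + 2 lakes
_DEFAULT_SITES = (
    (3, 2, 2, 2, 2, 2, 1, 1, 1),  # freshwater, 16 sites
    (3, 2, 2, 2, 2, 1, 1, 1),     # subsaline, 14 sites
    (2, 2, 2, 2, 1, 1),           # hyposaline, 10 sites
    (2, 2),                       # mesosaline, 4 sites
)

COHORT_COLUMNS = [
    "sample_id", "lake_id", "salinity", "salinity_class", "ph",
    "soc", "tn", "tp", "doc", "nh4", "no3", "no2", "dip",
    "soc_tn", "soc_tp", "tn_tp",
    "water_tn", "water_tp", "water_tn_tp", "chla",
    "bacterial_richness", "fungal_richness", "bacterial_dca1", "fungal_dca1",
    "bg", "cbh", "nag", "lap", "ap",
    "x", "y", "vector_length", "vector_angle_deg", "limitation_class",
]


@dataclass(frozen=True)
class GradientConfig:
    """All generator knobs; defaults reproduce the study-scale cohort."""

    lakes_per_class: tuple[int, int, int, int] = (9, 8, 6, 2)
    sites_per_lake: tuple[tuple[int, ...], ...] = _DEFAULT_SITES
    salinity_anchor: tuple[float, float] = (0.13, 31.06)
    anchor: bool = True
    salinity_jitter_sd: float = 0.02  # sd of site-level ln-salinity jitter

    # calibration targets (adjusted R² at scale, plus the cohort mean angle)
    r2_salinity_length: float = 0.23
    r2_salinity_angle: float = 0.44
    r2_soc_length_marginal: float = 0.21
    r2_soc_length_partial: float = 0.09
    mean_angle_deg: float = 39.40
    angle_sd_deg: float = 8.0
    mean_length: float = 1.0  # geometric mean; an assumption, not a measured value
    length_sigma: float = 0.04  # sd of ln(vector length); kept small so
    # truncation-resampling stays rare and does not erode the calibration
    angle_bounds: tuple[float, float] = (5.0, 85.0)

    # enzyme activity scales
    c_activity_scale: float = 100.0  # geometric mean of C-group total, nmol g⁻¹ h⁻¹
    c_activity_sigma: float = 0.4
    c_salinity_coef: float = 0.3
    bg_share_beta: tuple[float, float] = (8.0, 8.0)
    nag_share_beta: tuple[float, float] = (8.0, 8.0)

    # environment
    ph_mean: float = 8.8
    ph_sd: float = 0.5
    ph_salinity_corr: float = 0.7
    soc_mean: float = 42.7  # g kg⁻¹, geometric mean
    soc_sigma: float = 0.5
    #: ln-space trend coefficient on standardized ln-salinity and ln-noise sd
    nutrient_trends: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # name: (geometric mean, trend on s, noise sd)
            "tn": (4.81, -0.08, 0.30),
            "tp": (0.56, 0.08, 0.30),
            "doc": (5.0, 0.0, 0.35),
            "nh4": (0.05, 0.40, 0.35),
            "no3": (0.08, 0.40, 0.35),
            "no2": (0.01, 0.40, 0.35),
            "dip": (0.02, 0.40, 0.35),
            "water_tn": (1.05, 0.30, 0.30),
            "water_tp": (0.368, 0.35, 0.30),
            "chla": (1.33, 0.0, 0.40),
            "bacterial_richness": (3000.0, -0.30, 0.20),
            "fungal_richness": (500.0, -0.25, 0.25),
        }
    )

    # plate simulation
    plate_noise_sd: float = 2.0
    quench_range: tuple[float, float] = (0.5, 0.95)
    reference_rfu: float = 1000.0
    substrate_blank_rfu: float = 50.0
    n_assay_replicates: int = 3

    seed: int = 0

    # ---- construction helpers -------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "GradientConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for k, v in data.items():
            if isinstance(v, list):
                v = tuple(tuple(i) if isinstance(i, list) else i for i in v)
            coerced[k] = v
        cfg = cls(**coerced)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "GradientConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("r2_salinity_length", "r2_salinity_angle",
                     "r2_soc_length_marginal", "r2_soc_length_partial"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if self.r2_soc_length_partial > self.r2_soc_length_marginal:
            raise ConfigError(
                "r2_soc_length_partial must not exceed r2_soc_length_marginal "
                f"({self.r2_soc_length_partial} > {self.r2_soc_length_marginal})"
            )
        if len(self.lakes_per_class) != 4 or any(n < 0 for n in self.lakes_per_class):
            raise ConfigError("lakes_per_class must be four nonnegative counts")
        if len(self.sites_per_lake) != 4:
            raise ConfigError("sites_per_lake must list one tuple per class")
        for n_lakes, sites in zip(self.lakes_per_class, self.sites_per_lake):
            if len(sites) != n_lakes:
                raise ConfigError("sites_per_lake shape must match lakes_per_class")
            if any(s < 1 for s in sites):
                raise ConfigError("each lake needs >= 1 site")
        if not 0 < self.angle_bounds[0] < self.angle_bounds[1] < 90:
            raise ConfigError("angle_bounds must be inside (0, 90)")
        if self.salinity_anchor[0] >= self.salinity_anchor[1]:
            raise ConfigError("salinity_anchor must be increasing")
        if not -1.0 < self.ph_salinity_corr < 1.0:
            raise ConfigError("ph_salinity_corr must be in (-1, 1)")
        solve_covariance(self)  # raises ConfigError when targets are infeasible

    @property
    def n_lakes(self) -> int:
        return sum(self.lakes_per_class)

    @property
    def n_sites(self) -> int:
        return sum(sum(s) for s in self.sites_per_lake)


def solve_covariance(config: GradientConfig) -> tuple[float, float, float]:
    """Solve (α, β, γ) of the latent system from the four R² targets.

    α = sqrt(r²_salinity_length). (β, γ) solve, on the negative branch,

        (αβ + γ·sqrt(1 − α²))² = r²_soc_length_marginal
        γ² / (1 − β²)          = r²_soc_length_partial

    Raises :class:`ConfigError` when no real solution with β² + γ² ≤ 1
    exists.
    """
    alpha = math.sqrt(config.r2_salinity_length)
    r2m = config.r2_soc_length_marginal
    r2p = config.r2_soc_length_partial
    if r2m == 0.0 and r2p == 0.0:
        return alpha, 0.0, 0.0
    sq = math.sqrt(max(1.0 - alpha * alpha, 0.0))

    def f(beta: float) -> float:
        gamma = -math.sqrt(r2p * (1.0 - beta * beta))
        return alpha * beta + gamma * sq + math.sqrt(r2m)

    lo, hi = -1.0 + 1e-12, 1.0 - 1e-12
    if f(lo) * f(hi) > 0:
        raise ConfigError(
            "infeasible calibration targets: no β in (-1, 1) satisfies the "
            "marginal/partial SOC moment equations "
            f"(marginal={r2m}, partial={r2p}, α²={config.r2_salinity_length})"
        )
    beta = brentq(f, lo, hi, xtol=1e-14)
    gamma = -math.sqrt(r2p * (1.0 - beta * beta))
    if beta * beta + gamma * gamma > 1.0:
        raise ConfigError(
            f"infeasible calibration targets: β² + γ² = {beta**2 + gamma**2:.4f} > 1"
        )
    return alpha, beta, gamma


# ---------------------------------------------------------------------------
# cohort structure


def _site_allocation(config: GradientConfig, n_sites: int | None) -> list[tuple[str, SalinityClass, int]]:
    """(lake_id, class, sites) triples; optionally scaled to ~n_sites total."""
    if n_sites is None or n_sites == config.n_sites:
        out = []
        for ci, cls in enumerate(_CLASS_ORDER):
            for li, count in enumerate(config.sites_per_lake[ci]):
                out.append((f"L{ci + 1}{li + 1:02d}", cls, count))
        return out

    # scaled cohort: preserve per-class site and lake proportions
    default_sites = [sum(s) for s in config.sites_per_lake]
    total = sum(default_sites)
    targets = [n_sites * s / total for s in default_sites]
    site_counts = [int(t) for t in targets]
    # largest-remainder rounding to hit n_sites exactly
    order = sorted(range(4), key=lambda i: targets[i] - site_counts[i], reverse=True)
    for i in order[: n_sites - sum(site_counts)]:
        site_counts[i] += 1

    out = []
    for ci, cls in enumerate(_CLASS_ORDER):
        n_class_sites = site_counts[ci]
        if n_class_sites == 0:
            continue
        mean_per_lake = default_sites[ci] / config.lakes_per_class[ci]
        n_lakes = max(1, round(n_class_sites / mean_per_lake))
        base, extra = divmod(n_class_sites, n_lakes)
        for li in range(n_lakes):
            out.append((f"L{ci + 1}{li + 1:04d}", cls, base + (1 if li < extra else 0)))
    return out


def _lake_salinities(config: GradientConfig, structure, rng) -> dict[str, float]:
    by_class: dict[SalinityClass, list[str]] = {}
    for lake_id, cls, _ in structure:
        by_class.setdefault(cls, []).append(lake_id)

    sal: dict[str, float] = {}
    for cls, lakes in by_class.items():
        lo, hi = _DRAW_BANDS[cls]
        draws = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(lakes)))
        if config.anchor:
            log_d = np.log(draws)
            if cls is _CLASS_ORDER[0] and len(draws) > 0:
                # monotone log-affine rescale: class minimum → lower anchor
                tgt_lo = math.log(config.salinity_anchor[0])
                if len(draws) > 1 and log_d.max() > log_d.min():
                    log_d = tgt_lo + (log_d - log_d.min()) * (
                        (log_d.max() - tgt_lo) / (log_d.max() - log_d.min())
                    )
                else:
                    log_d[:] = tgt_lo
            if cls is _CLASS_ORDER[3] and len(draws) > 0:
                tgt_hi = math.log(config.salinity_anchor[1])
                if len(draws) > 1 and log_d.max() > log_d.min():
                    log_d = log_d.min() + (log_d - log_d.min()) * (
                        (tgt_hi - log_d.min()) / (log_d.max() - log_d.min())
                    )
                else:
                    log_d[:] = tgt_hi
            draws = np.exp(log_d)
        for lake_id, s in zip(lakes, draws):
            sal[lake_id] = float(s)
    return sal


def _site_salinities(config, structure, lake_sal, rng) -> tuple[np.ndarray, list[str], list[SalinityClass]]:
    lake_ids, classes, logs = [], [], []
    for lake_id, cls, count in structure:
        jitter = rng.normal(0.0, config.salinity_jitter_sd, size=count)
        for j in jitter:
            lake_ids.append(lake_id)
            classes.append(cls)
            logs.append(math.log(lake_sal[lake_id]) + j)
    logs = np.asarray(logs)

    if config.anchor and len(logs) > 1:
        # global monotone rescale so the site extremes hit the anchors exactly
        tgt_lo, tgt_hi = (math.log(a) for a in config.salinity_anchor)
        lo, hi = logs.min(), logs.max()
        if hi > lo:
            logs = tgt_lo + (logs - lo) * (tgt_hi - tgt_lo) / (hi - lo)

    sal = np.exp(logs)
    # keep every site inside its lake's class band (jitter + rescale are small)
    for i, cls in enumerate(classes):
        lo, hi = _CLASS_BANDS[cls]
        sal[i] = min(max(sal[i], lo), hi)

    if config.anchor and len(sal) > 1:
        # pin the extremes to the anchors exactly (exp/log round-trip drifts
        # by ~1 ulp) provided the anchor sits inside the site's class band
        for idx, anchor in ((int(np.argmin(sal)), config.salinity_anchor[0]),
                            (int(np.argmax(sal)), config.salinity_anchor[1])):
            lo, hi = _CLASS_BANDS[classes[idx]]
            if lo <= anchor <= hi:
                sal[idx] = anchor
    return sal, lake_ids, classes


# ---------------------------------------------------------------------------
# latent draws → activities


def latent_to_activities(
    length: float,
    angle_deg: float,
    c_total: float,
    bg_share: float = 0.5,
    nag_share: float = 0.5,
    sample_id: str = "",
) -> EnzymeActivities:
    """Invert the vector statistics into a consistent activity vector.

    x = length·cos(angle), y = length·sin(angle) must both land in (0, 1);
    otherwise a :class:`DomainError` signals the caller to redraw.
    """
    if not 0.0 < angle_deg < 90.0:
        raise DomainError(f"angle must be in (0, 90), got {angle_deg}")
    if c_total <= 0:
        raise DomainError("c_total must be positive")
    if not (0.0 < bg_share < 1.0 and 0.0 < nag_share < 1.0):
        raise DomainError("shares must be in (0, 1)")
    rad = math.radians(angle_deg)
    x = length * math.cos(rad)
    y = length * math.sin(rad)
    if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
        raise DomainError(f"implied ratios outside (0,1): x={x:.4f}, y={y:.4f}")
    ap = c_total * (1.0 - x) / x
    n_total = c_total * (1.0 - y) / y
    return EnzymeActivities(
        bg=bg_share * c_total,
        cbh=(1.0 - bg_share) * c_total,
        nag=nag_share * n_total,
        lap=(1.0 - nag_share) * n_total,
        ap=ap,
        sample_id=sample_id,
    )


def generate_cohort(
    config: GradientConfig | None = None,
    seed: int | None = None,
    n_sites: int | None = None,
) -> pd.DataFrame:
    """Generate one cohort as a site-level table.

    Deterministic given (config, seed). ``n_sites`` scales the cohort while
    preserving per-class lake and site proportions (used for calibration
    checks at n ≫ 44). The returned frame carries ``attrs`` with the seed,
    config hash and truncation-resample count.
    """
    config = config or GradientConfig()
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    alpha, beta, gamma = solve_covariance(config)
    structure = _site_allocation(config, n_sites)
    lake_sal = _lake_salinities(config, structure, rng)
    sal, lake_ids, classes = _site_salinities(config, structure, lake_sal, rng)
    n = len(sal)
    if n < 2:
        raise ConfigError("cohort must contain at least 2 sites")

    log_sal = np.log(sal)
    s = (log_sal - log_sal.mean()) / log_sal.std()

    # --- accepted latent draws (u drives length; eps drives angle) -------
    a_coef = math.sqrt(config.r2_salinity_angle) * config.angle_sd_deg
    a_noise = math.sqrt(1.0 - config.r2_salinity_angle) * config.angle_sd_deg
    u = np.empty(n)
    angle = np.empty(n)
    length = np.empty(n)
    pending = np.arange(n)
    resamples = 0
    for _ in range(1000):
        if len(pending) == 0:
            break
        u_try = rng.standard_normal(len(pending))
        eps_try = rng.standard_normal(len(pending))
        L_try = alpha * s[pending] + math.sqrt(1.0 - alpha * alpha) * u_try
        len_try = config.mean_length * np.exp(config.length_sigma * L_try)
        ang_try = config.mean_angle_deg + a_coef * (-s[pending]) + a_noise * eps_try
        rad = np.radians(ang_try)
        x_try = len_try * np.cos(rad)
        y_try = len_try * np.sin(rad)
        ok = (
            (ang_try > config.angle_bounds[0])
            & (ang_try < config.angle_bounds[1])
            & (x_try > 0.0) & (x_try < 1.0)
            & (y_try > 0.0) & (y_try < 1.0)
            & (len_try < math.sqrt(2.0))
        )
        idx = pending[ok]
        u[idx] = u_try[ok]
        angle[idx] = ang_try[ok]
        length[idx] = len_try[ok]
        resamples += int((~ok).sum())
        pending = pending[~ok]
    if len(pending) > 0:
        raise ConfigError("latent resampling failed to converge; widen angle/length settings")

    # --- SOC from the solved covariance (uses the accepted u) ------------
    v = rng.standard_normal(n)
    resid = 1.0 - beta * beta - gamma * gamma
    S = beta * s + gamma * u + math.sqrt(max(resid, 0.0)) * v
    soc = config.soc_mean * np.exp(config.soc_sigma * S)

    # --- pH and the nutrient/diversity blocks ---------------------------
    rho = config.ph_salinity_corr
    ph = config.ph_mean + config.ph_sd * (
        rho * s + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    )

    env: dict[str, np.ndarray] = {}
    for name, (gmean, trend, noise_sd) in config.nutrient_trends.items():
        env[name] = gmean * np.exp(trend * s + noise_sd * rng.standard_normal(n))

    z_ph = (ph - ph.mean()) / ph.std()
    env["bacterial_dca1"] = 0.6 * z_ph + 0.5 * s + 0.4 * rng.standard_normal(n)
    env["fungal_dca1"] = 0.4 * z_ph + 0.6 * s + 0.5 * rng.standard_normal(n)

    # --- activities ------------------------------------------------------
    c_total = config.c_activity_scale * np.exp(
        config.c_salinity_coef * s + config.c_activity_sigma * rng.standard_normal(n)
    )
    bg_share = rng.beta(*config.bg_share_beta, size=n)
    nag_share = rng.beta(*config.nag_share_beta, size=n)

    rows = []
    for i in range(n):
        sample_id = f"S{i + 1:05d}" if n > 9999 else f"S{i + 1:03d}"
        acts = latent_to_activities(
            length=float(length[i]),
            angle_deg=float(angle[i]),
            c_total=float(c_total[i]),
            bg_share=float(bg_share[i]),
            nag_share=float(nag_share[i]),
            sample_id=sample_id,
        )
        mml = mml_from_activities(acts)
        rows.append({
            "sample_id": sample_id,
            "lake_id": lake_ids[i],
            "salinity": float(sal[i]),
            "salinity_class": classes[i].value,
            "ph": float(ph[i]),
            "soc": float(soc[i]),
            "tn": float(env["tn"][i]),
            "tp": float(env["tp"][i]),
            "doc": float(env["doc"][i]),
            "nh4": float(env["nh4"][i]),
            "no3": float(env["no3"][i]),
            "no2": float(env["no2"][i]),
            "dip": float(env["dip"][i]),
            "soc_tn": float(soc[i] / env["tn"][i]),
            "soc_tp": float(soc[i] / env["tp"][i]),
            "tn_tp": float(env["tn"][i] / env["tp"][i]),
            "water_tn": float(env["water_tn"][i]),
            "water_tp": float(env["water_tp"][i]),
            "water_tn_tp": float(env["water_tn"][i] / env["water_tp"][i]),
            "chla": float(env["chla"][i]),
            "bacterial_richness": float(env["bacterial_richness"][i]),
            "fungal_richness": float(env["fungal_richness"][i]),
            "bacterial_dca1": float(env["bacterial_dca1"][i]),
            "fungal_dca1": float(env["fungal_dca1"][i]),
            "bg": acts.bg, "cbh": acts.cbh, "nag": acts.nag,
            "lap": acts.lap, "ap": acts.ap,
            "x": mml.x, "y": mml.y,
            "vector_length": mml.length,
            "vector_angle_deg": mml.angle_deg,
            "limitation_class": mml.limitation_class.value,
        })

    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    # consistency guard: declared class must match the thresholds
    for sal_v, cls_v in zip(df["salinity"], df["salinity_class"]):
        assert classify_salinity(sal_v).value == cls_v
    df.attrs["seed"] = seed
    df.attrs["config_hash"] = config.config_hash()
    df.attrs["resample_count"] = resamples
    return df


# ---------------------------------------------------------------------------
# plate simulation (inverse of the assay reduction)


def simulate_plate(
    acts: EnzymeActivities,
    params: AssayParams | None = None,
    quench_q: float = 0.8,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    reference_rfu: float = 1000.0,
    substrate_blank_rfu: float = 50.0,
) -> list[PlateReading]:
    """Construct plate readings whose noise-free reduction returns ``acts``.

    The assay wells are set to q·(net + substrate blank) with
    net = activity · e · mass · time / (suspension/aliquot); Gaussian RFU
    noise (sd ``noise_sd``) is added to every well when positive.
    """
    params = params or AssayParams()
    if not 0.0 < quench_q <= 1.5:
        raise DomainError(f"quench_q must be in (0, 1.5], got {quench_q}")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if n_replicates < 3:
        raise DomainError("need >= 3 assay replicates")
    rng = np.random.default_rng(seed)
    e = reference_rfu / params.standard_amount
    dilution = params.suspension_volume / params.well_aliquot_volume

    def wells(level: float, count: int) -> tuple[float, ...]:
        vals = np.full(count, level)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=count)
        return tuple(float(max(v, 0.0)) for v in vals)

    readings = []
    for enzyme in ENZYMES:
        target = getattr(acts, enzyme.lower())
        net = target * e * params.sediment_dry_mass * params.incubation_time / dilution
        assay_level = quench_q * (net + substrate_blank_rfu)
        readings.append(
            PlateReading(
                sample_id=acts.sample_id,
                enzyme=enzyme,
                assay_wells=wells(assay_level, n_replicates),
                quench_standard_wells=wells(reference_rfu * quench_q, n_replicates),
                substrate_control_wells=wells(substrate_blank_rfu, n_replicates),
                reference_standard_wells=wells(reference_rfu, n_replicates),
                params=params,
            )
        )
    return readings


def simulate_cohort_plates(
    cohort: pd.DataFrame,
    config: GradientConfig | None = None,
    params: AssayParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format plate table for every sample in a cohort.

    Per-sample quench coefficients are drawn uniformly from the configured
    range; noise follows ``config.plate_noise_sd``.
    """
    config = config or GradientConfig()
    params = params or AssayParams()
    rng = np.random.default_rng(seed)
    rows = []
    for rec in cohort.itertuples(index=False):
        acts = EnzymeActivities(
            bg=rec.bg, cbh=rec.cbh, nag=rec.nag, lap=rec.lap, ap=rec.ap,
            sample_id=rec.sample_id,
        )
        q = float(rng.uniform(*config.quench_range))
        plate_seed = int(rng.integers(0, 2**31 - 1))
        for reading in simulate_plate(
            acts, params=params, quench_q=q,
            noise_sd=config.plate_noise_sd, seed=plate_seed,
            n_replicates=config.n_assay_replicates,
            reference_rfu=config.reference_rfu,
            substrate_blank_rfu=config.substrate_blank_rfu,
        ):
            for role, wells in (
                ("assay", reading.assay_wells),
                ("quench_standard", reading.quench_standard_wells),
                ("substrate_control", reading.substrate_control_wells),
                ("reference_standard", reading.reference_standard_wells),
            ):
                for rfu in wells:
                    rows.append({"sample_id": reading.sample_id,
                                 "enzyme": reading.enzyme,
                                 "well_role": role, "rfu": rfu})
    return pd.DataFrame(rows, columns=["sample_id", "enzyme", "well_role", "rfu"])
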