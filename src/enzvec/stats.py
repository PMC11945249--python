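"""Gradient statistics: log-linear fits, class comparisons, partial
regression, variance partitioning, distance-matrix regression, and
collinearity filtering.

All regressions on measured quantities operate on natural-log transformed
values; residual-on-residual fits are performed on the (already
transformed) residuals directly. Adjusted R² uses the usual
``1 − (1 − R²)(n − 1)/(n − 1 − p)`` with p the effective number of
predictors (matrix rank for multi-predictor fits).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, InputError

__all__ = [
    "SalinityClass",
    "RegressionResult",
    "AnovaResult",
    "VpaResult",
    "MrmResult",
    "classify_salinity",
    "loglinear_fit",
    "class_anova",
    "partial_regression",
    "variance_partition",
    "mrm",
    "vif_filter",
    "zscore",
    "SALINITY_THRESHOLDS",
]

#: Class boundaries in ‰; intervals are left-closed ([0.5, 3) etc.).
SALINITY_THRESHOLDS = (0.5, 3.0, 20.0)


class SalinityClass(str, Enum):
    FRESHWATER = "FRESHWATER"
    SUBSALINE = "SUBSALINE"
    HYPOSALINE = "HYPOSALINE"
    MESOSALINE = "MESOSALINE"


_CLASS_ORDER = [
    SalinityClass.FRESHWATER,
    SalinityClass.SUBSALINE,
    SalinityClass.HYPOSALINE,
    SalinityClass.MESOSALINE,
]


def classify_salinity(salinity: float) -> SalinityClass:
    """Map salinity (‰, must be > 0) onto the four-level class scale."""
    if not salinity > 0:
        raise DomainError(f"salinity must be positive, got {salinity}")
    lo, mid, hi = SALINITY_THRESHOLDS
    if salinity < lo:
        return SalinityClass.FRESHWATER
    if salinity < mid:
        return SalinityClass.SUBSALINE
    if salinity < hi:
        return SalinityClass.HYPOSALINE
    return SalinityClass.MESOSALINE


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    adj_r2: float
    p_value: float
    n: int


def _adj_r2(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - p)


def _validate_positive(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be 1-dimensional")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"{name} must be finite and strictly positive for log transform")
    return arr


def _linfit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    n = len(x)
    if np.ptp(x) == 0:
        raise DomainError("zero variance in predictor")
    if np.ptp(y) == 0:
        # degenerate response: flat fit, no explained variance
        return RegressionResult(slope=0.0, intercept=float(y[0]), adj_r2=_adj_r2(0.0, n, 1),
                                p_value=1.0, n=n)
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        adj_r2=_adj_r2(res.rvalue**2, n, 1),
        p_value=float(res.pvalue),
        n=n,
    )


def loglinear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of ln(y) on ln(x) with adjusted R² and two-sided slope p-value."""
    xa = _validate_positive(np.asarray(x), "x")
    ya = _validate_positive(np.asarray(y), "y")
    if len(xa) != len(ya):
        raise DomainError("x and y must have equal length")
    if len(xa) < 3:
        raise DomainError("need n >= 3")
    return _linfit(np.log(xa), np.log(ya))


def partial_regression(
    y: Sequence[float], x: Sequence[float], control: Sequence[float]
) -> RegressionResult:
    """Residual-on-residual regression after removing a log-scale control.

    ln(y) and ln(x) are each residualised on ln(control) by OLS; the
    returned fit regresses the y-residuals on the x-residuals. The adjusted
    R² of that fit (simple-regression degrees of freedom, n − 2) is the
    partial effect; at large n it coincides with the squared partial
    correlation.
    """
    ya = np.log(_validate_positive(np.asarray(y), "y"))
    xa = np.log(_validate_positive(np.asarray(x), "x"))
    ca = np.log(_validate_positive(np.asarray(control), "control"))
    if not (len(ya) == len(xa) == len(ca)):
        raise DomainError("y, x, control must have equal length")
    if len(ya) < 4:
        raise DomainError("need n >= 4")
    if np.ptp(ca) == 0:
        raise DomainError("zero variance in control")

    def _resid(v: np.ndarray) -> np.ndarray:
        b, a = np.polyfit(ca, v, 1)
        return v - (a + b * ca)

    ry, rx = _resid(ya), _resid(xa)
    if np.ptp(rx) <= 1e-10 * max(1.0, float(np.ptp(xa))):
        raise DomainError("x is an exact function of the control")
    return _linfit(rx, ry)


# ---------------------------------------------------------------------------
# ANOVA with compact letter display


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    class_means: dict[str, float]
    letters: dict[str, str]
    alpha: float
    dropped_classes: tuple[str, ...] = ()


def _compact_letters(groups: list[str], means: dict[str, float],
                     not_different: set[frozenset[str]]) -> dict[str, str]:
    """Clique-based compact letter display.

    Groups sharing a letter are not significantly different. Maximal
    cliques of the "not different" graph each receive one letter, assigned
    in descending order of the clique's highest group mean.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for pair in not_different:
        a, b = tuple(pair)
        g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: (-max(means[m] for m in c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for i, clique in enumerate(cliques):
        letter = alphabet[i % len(alphabet)] * (i // len(alphabet) + 1)
        for member in clique:
            letters[member].append(letter)
    return {grp: "".join(sorted(ls)) for grp, ls in letters.items()}


def class_anova(
    values: Sequence[float], classes: Sequence[str], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA plus Tukey HSD pairwise letters at the given alpha.

    Classes with fewer than two observations are dropped with a warning.
    Degenerate designs (all values identical) report F = 0, p = 1 and a
    shared letter.
    """
    vals = np.asarray(values, dtype=float)
    cls = np.asarray([str(c) for c in classes])
    if len(vals) != len(cls):
        raise DomainError("values and classes must have equal length")

    dropped = []
    keep = np.ones(len(vals), dtype=bool)
    for name in pd.unique(cls):
        idx = cls == name
        if idx.sum() < 2:
            warnings.warn(f"class {name!r} has < 2 observations; dropped", stacklevel=2)
            dropped.append(str(name))
            keep &= ~idx
    vals, cls = vals[keep], cls[keep]
    names = [str(c) for c in pd.unique(cls)]
    if len(names) < 2:
        raise DomainError("need >= 2 classes with >= 2 observations each")

    groups = [vals[cls == name] for name in names]
    means = {name: float(np.mean(grp)) for name, grp in zip(names, groups)}

    grand = np.mean(vals)
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - np.mean(g)) ** 2)) for g in groups)
    df_b, df_w = len(names) - 1, len(vals) - len(names)
    if ssb == 0:
        f_stat, p_value = 0.0, 1.0
    elif ssw == 0:
        f_stat, p_value = math.inf, 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        p_value = float(sps.f.sf(f_stat, df_b, df_w))

    not_different: set[frozenset[str]] = set()
    if ssw == 0 and ssb == 0:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                not_different.add(frozenset((names[i], names[j])))
    else:
        tk = sps.tukey_hsd(*groups)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p = tk.pvalue[i, j]
                if not np.isfinite(p) or p >= alpha:
                    not_different.add(frozenset((names[i], names[j])))

    return AnovaResult(
        f_stat=float(f_stat),
        p_value=float(p_value),
        class_means=means,
        letters=_compact_letters(names, means, not_different),
        alpha=alpha,
        dropped_classes=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# Variance partitioning


@dataclass(frozen=True)
class VpaResult:
    """Adjusted-R² fractions over three predictor blocks (a, b, c).

    Individual fractions may be negative (adjusted R² is not monotone);
    they always sum to 1 with the residual. ``clamped()`` gives the
    display-friendly nonnegative version.
    """

    pure_a: float
    pure_b: float
    pure_c: float
    shared_ab: float
    shared_ac: float
    shared_bc: float
    shared_abc: float
    residual: float
    block_names: tuple[str, str, str] = ("a", "b", "c")

    def fractions(self) -> dict[str, float]:
        return {
            "pure_a": self.pure_a,
            "pure_b": self.pure_b,
            "pure_c": self.pure_c,
            "shared_ab": self.shared_ab,
            "shared_ac": self.shared_ac,
            "shared_bc": self.shared_bc,
            "shared_abc": self.shared_abc,
            "residual": self.residual,
        }

    def clamped(self) -> dict[str, float]:
        return {k: max(v, 0.0) for k, v in self.fractions().items()}


def _ols_r2(y: np.ndarray, X: np.ndarray, label: str) -> tuple[float, int]:
    """Raw R² and effective predictor count (rank) of an OLS fit with intercept."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if not np.all(np.isfinite(coef)):
        raise DomainError(f"singular fit for block union {label!r}")
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("response has zero variance")
    return 1.0 - float(np.sum(resid**2)) / ss_tot, rank - 1


def variance_partition(
    response: Sequence[float],
    block_a: np.ndarray | pd.DataFrame,
    block_b: np.ndarray | pd.DataFrame,
    block_c: np.ndarray | pd.DataFrame,
    block_names: tuple[str, str, str] = ("a", "b", "c"),
) -> VpaResult:
    """Three-block variance partitioning by inclusion–exclusion.

    Fits the seven OLS models on the non-empty block unions, converts each
    to adjusted R² (rank-based degrees of freedom), and solves for the
    seven fractions; residual = 1 − adjR²(abc).
    """
    y = np.asarray(response, dtype=float)
    blocks = [np.atleast_2d(np.asarray(b, dtype=float).T).T for b in (block_a, block_b, block_c)]
    for name, b in zip(block_names, blocks):
        if b.shape[0] != len(y):
            raise DomainError(f"block {name!r} row count does not match response")
        if b.shape[1] == 0:
            raise DomainError(f"block {name!r} is empty")
    n = len(y)
    total_p = sum(b.shape[1] for b in blocks)
    if n <= total_p + 1:
        raise DomainError("need n > total predictors + 1")

    def adj(parts: tuple[int, ...]) -> float:
        X = np.column_stack([blocks[i] for i in parts])
        label = "+".join(block_names[i] for i in parts)
        r2, p_eff = _ols_r2(y, X, label)
        return _adj_r2(r2, n, p_eff)

    Aa, Ab, Ac = adj((0,)), adj((1,)), adj((2,))
    Aab, Aac, Abc = adj((0, 1)), adj((0, 2)), adj((1, 2))
    Aabc = adj((0, 1, 2))

    pure_a = Aabc - Abc
    pure_b = Aabc - Aac
    pure_c = Aabc - Aab
    shared_abc = Aa + Ab + Ac - Aab - Aac - Abc + Aabc
    shared_ab = Aa + Ab - Aab - shared_abc
    shared_ac = Aa + Ac - Aac - shared_abc
    shared_bc = Ab + Ac - Abc - shared_abc
    residual = 1.0 - Aabc

    return VpaResult(
        pure_a=pure_a,
        pure_b=pure_b,
        pure_c=pure_c,
        shared_ab=shared_ab,
        shared_ac=shared_ac,
        shared_bc=shared_bc,
        shared_abc=shared_abc,
        residual=residual,
        block_names=block_names,
    )


# ---------------------------------------------------------------------------
# Multiple regression on distance matrices


@dataclass(frozen=True)
class MrmResult:
    coefficients: dict[str, float]
    r2: float
    p_values: dict[str, float]
    n_permutations: int
    seed: int


def _check_distance_matrix(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError(f"{name} is not square")
    if np.any(~np.isfinite(m)):
        raise InputError(f"{name} contains NaN/inf")
    if not np.allclose(m, m.T):
        raise InputError(f"{name} is not symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise InputError(f"{name} has a nonzero diagonal")
    return m


def mrm(
    response_dist: np.ndarray,
    predictor_dists: Sequence[np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> MrmResult:
    """Multiple regression on distance matrices with Mantel-style permutations.

    Upper triangles are unfolded and regressed by OLS (with intercept);
    per-coefficient p-values come from jointly permuting the rows/columns of
    the response matrix ``n_perm`` times, with the add-one convention
    p = (1 + #{|coef_perm| ≥ |coef_obs|}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    D = _check_distance_matrix(response_dist, "response matrix")
    n = D.shape[0]
    preds = []
    for i, p in enumerate(predictor_dists):
        pm = _check_distance_matrix(p, f"predictor matrix {i}")
        if pm.shape != D.shape:
            raise InputError(f"predictor matrix {i} dimension mismatch")
        preds.append(pm)
    if not preds:
        raise InputError("need at least one predictor matrix")
    names = list(names) if names is not None else [f"x{i+1}" for i in range(len(preds))]
    if len(names) != len(preds):
        raise InputError("names length must match predictor count")

    iu = np.triu_indices(n, k=1)
    X = np.column_stack([np.ones(len(iu[0]))] + [p[iu] for p in preds])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear predictor distance matrices", stacklevel=2)

    def fit(yvec: np.ndarray) -> tuple[np.ndarray, float]:
        coef, _, _, _ = np.linalg.lstsq(X, yvec, rcond=None)
        resid = yvec - X @ coef
        ss_tot = float(np.sum((yvec - yvec.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        return coef, r2

    y_obs = D[iu]
    coef_obs, r2_obs = fit(y_obs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(coef_obs) - 1, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        coef_p, _ = fit(D[np.ix_(perm, perm)][iu])
        exceed += np.abs(coef_p[1:]) >= np.abs(coef_obs[1:])
    pvals = (1 + exceed) / (n_perm + 1)

    return MrmResult(
        coefficients={"intercept": float(coef_obs[0]),
                      **{nm: float(c) for nm, c in zip(names, coef_obs[1:])}},
        r2=r2_obs,
        p_values={nm: float(p) for nm, p in zip(names, pvals)},
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Collinearity filter and standardisation


def _vif(X: np.ndarray, j: int) -> float:
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(X.shape[0]), others])
    coef, _, _, _ = np.linalg.lstsq(design, X[:, j], rcond=None)
    resid = X[:, j] - design @ coef
    ss_tot = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
    if ss_tot == 0:
        return math.inf
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)


def vif_filter(
    predictors: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], dict[str, float]]:
    """Iteratively drop the highest-VIF predictor while any VIF > threshold.

    Returns (retained column names, dropped name → VIF at removal). Ties at
    the maximum (e.g. an exactly collinear pair, both infinite) drop the
    later-alphabetical name first, making the procedure deterministic.
    """
    if predictors.shape[1] < 2:
        raise InputError("need >= 2 predictors")
    if predictors.shape[0] <= predictors.shape[1]:
        raise InputError("need n > number of predictors")
    cols = list(predictors.columns)
    dropped: dict[str, float] = {}
    while len(cols) > 1:
        X = predictors[cols].to_numpy(dtype=float)
        vifs = {c: _vif(X, j) for j, c in enumerate(cols)}
        worst = max(vifs.values())
        if worst <= threshold:
            break
        tied = sorted(c for c, v in vifs.items() if v == worst)
        victim = tied[-1]
        dropped[victim] = vifs[victim]
        cols.remove(victim)
    return cols, dropped


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardise to mean 0, sample (ddof=1) standard deviation 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DomainError("need n >= 2")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DomainError("zero variance input")
    return (arr - arr.mean()) / sd
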