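"""Dose-response curve fitting for reporter transactivation assays.

The analysis chain implemented here is the standard one for GAL4-LBD
luciferase assays of steroid receptors:

1. raw luminescence is normalized to the mean vehicle (ethanol) signal of the
   same construct, giving fold-activation with baseline 1;
2. doses above the dose of maximum average response (``d_max``) are excluded,
   because activity often declines at the top of the ladder — a signature of
   cytotoxicity — and including the decline drags the fitted upper bound, and
   with it the EC50, downward;
3. a logistic curve is fitted by multistart nonlinear least squares on
   log10(dose), and the converged start with the smallest residual sum of
   squares (RSS) wins, with a documented qualitative tie-break.

Two model variants are supported. The three-parameter logistic (3PL) pins the
zero-dose response at the vehicle baseline of 1::

    f(x) = beta1 + (1 - beta1) / (1 + (x / beta2)**beta3)

where ``beta1`` is the upper bound (fold units), ``beta2`` the EC50 (molar)
and ``beta3`` the shape. The four-parameter logistic (4PL) frees the
zero-dose asymptote ``beta0``::

    f(x) = beta1 + (beta0 - beta1) / (1 + (x / beta2)**beta3)

and is appropriate for constructs with measurable constitutive activity at
the lowest doses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    ConfigError,
    DegenerateBaselineError,
    InputError,
    MissingBaselineError,
    NoActivationError,
    NonConvergenceError,
)
from .simulate import MEASUREMENT_COLUMNS, VEHICLE_LABEL

__all__ = [
    "FoldActivationSeries",
    "Logistic3Params",
    "Logistic4Params",
    "FitConfig",
    "FitResult",
    "normalize_to_vehicle",
    "truncate_at_max_mean",
    "eval_logistic3",
    "eval_logistic4",
    "fit_dose_response",
    "estimate_ec50",
    "fit_measurement_table",
]

ModelKind = Literal["3PL", "4PL"]


@dataclass(frozen=True)
class FoldActivationSeries:
    """Vehicle-normalized replicate responses for one construct x ligand.

    ``points`` maps each molar dose to its replicate fold-activations; doses
    are strictly positive and unique (vehicle rows are consumed by
    normalization, not carried as data points).
    """

    construct: str
    ligand: str
    points: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        doses = [d for d, _ in self.points]
        if any(d <= 0 for d in doses):
            raise InputError(f"{self.construct}/{self.ligand}: doses must be strictly positive")
        if len(set(doses)) != len(doses):
            raise InputError(f"{self.construct}/{self.ligand}: duplicate doses")
        if any(len(reps) == 0 for _, reps in self.points):
            raise InputError(f"{self.construct}/{self.ligand}: every dose needs >= 1 replicate")

    @property
    def doses(self) -> np.ndarray:
        return np.array([d for d, _ in self.points])

    def mean_by_dose(self) -> np.ndarray:
        return np.array([np.mean(reps) for _, reps in self.points])

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """All (dose, fold) observations as parallel arrays."""
        x = np.concatenate([[d] * len(reps) for d, reps in self.points])
        y = np.concatenate([list(reps) for _, reps in self.points])
        return x, y

    def n_obs(self) -> int:
        return sum(len(reps) for _, reps in self.points)


@dataclass(frozen=True)
class Logistic3Params:
    """3PL parameters: upper bound, EC50 (molar), shape. f(0) = 1 by form."""

    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        if self.beta2 <= 0:
            raise ConfigError("beta2: EC50 must be > 0")
        if self.beta3 <= 0:
            raise ConfigError("beta3: shape must be > 0")


@dataclass(frozen=True)
class Logistic4Params:
    """4PL parameters: free zero-dose asymptote beta0 plus the 3PL triple."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        if self.beta2 <= 0:
            raise ConfigError("beta2: EC50 must be > 0")
        if self.beta3 <= 0:
            raise ConfigError("beta3: shape must be > 0")


def eval_logistic3(params: Logistic3Params, dose) -> np.ndarray | float:
    """Three-parameter logistic fold-activation; exactly 1 at dose 0."""
    x = np.asarray(dose, dtype=float)
    out = params.beta1 + (1.0 - params.beta1) / (1.0 + (x / params.beta2) ** params.beta3)
    return out if out.ndim else float(out)


def eval_logistic4(params: Logistic4Params, dose) -> np.ndarray | float:
    """Four-parameter logistic; f(0) = beta0, high-dose limit beta1."""
    x = np.asarray(dose, dtype=float)
    out = params.beta1 + (params.beta0 - params.beta1) / (1.0 + (x / params.beta2) ** params.beta3)
    return out if out.ndim else float(out)


def normalize_to_vehicle(raw: pd.DataFrame) -> list[FoldActivationSeries]:
    """Convert one construct's raw luminescence rows into fold-activation.

    ``raw`` must hold a single construct in the measurement dialect
    (columns ``construct, ligand, dose_molar, replicate, luminescence``) with
    vehicle rows at ``dose_molar == 0``. Each treatment value is divided by
    the mean vehicle value; one series per ligand is returned, vehicle rows
    consumed.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise InputError(f"measurement table missing columns: {', '.join(missing)}")
    constructs = raw["construct"].unique()
    if len(constructs) != 1:
        raise InputError(f"normalize_to_vehicle expects one construct, got {sorted(constructs)}")
    construct = constructs[0]
    vehicle = raw.loc[raw["dose_molar"] == 0, "luminescence"]
    if vehicle.empty:
        raise MissingBaselineError(f"{construct}: no vehicle (dose 0) rows")
    baseline = float(vehicle.mean())
    if baseline <= 0:
        raise DegenerateBaselineError(f"{construct}: vehicle mean {baseline} is not positive")

    treated = raw[raw["dose_molar"] > 0]
    series = []
    for ligand, sub in treated.groupby("ligand", sort=True):
        points = tuple(
            (float(dose), tuple(grp["luminescence"] / baseline))
            for dose, grp in sub.groupby("dose_molar", sort=True)
        )
        series.append(FoldActivationSeries(construct=construct, ligand=str(ligand), points=points))
    return series


def truncate_at_max_mean(
    series: FoldActivationSeries,
) -> tuple[FoldActivationSeries, float, tuple[float, ...]]:
    """Drop doses above the dose of maximum average response.

    Computes per-dose mean fold-activation, takes ``d_max`` as the largest
    dose attaining the maximum (a tie is not a decline, so the tie-break
    keeps the tied points), and retains all points with dose <= d_max.
    Returns ``(filtered series, d_max, excluded doses)``; monotone series
    pass through unchanged. Idempotent.
    """
    if not series.points:
        raise InputError(f"{series.construct}/{series.ligand}: empty series")
    doses = series.doses
    means = series.mean_by_dose()
    d_max = float(np.max(doses[means == means.max()]))
    kept = tuple(p for p in series.points if p[0] <= d_max)
    excluded = tuple(float(d) for d, _ in series.points if d > d_max)
    return replace(series, points=kept), d_max, excluded


@dataclass(frozen=True)
class FitConfig:
    """Multistart least-squares settings.

    The default start grid crosses upper-bound guesses {2, max observed mean,
    2 x max}, EC50 guesses at the 25/50/75% quantiles of the observed doses
    (geometric) and shapes {0.5, 1, 2} — 27 starts. Bounds keep the EC50 in
    (1e-13, 1e-3) M and the shape in (0.05, 10); the upper bound may not
    exceed 10x the largest observed mean; a free zero-dose asymptote is
    bounded in (0, 5). ``tol`` is applied to the optimizer's cost, step and
    gradient criteria. Series whose responses all lie within ``flat_tol`` of
    the baseline 1 are flagged as showing no activation. ``fit_means``
    switches from per-replicate fitting (default: all observations enter the
    least squares) to fitting per-dose means.
    """

    beta1_starts: tuple[float, ...] | None = None  # None -> {2, max, 2*max}
    beta2_quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)
    beta3_starts: tuple[float, ...] = (0.5, 1.0, 2.0)
    beta0_start: float = 1.0
    beta2_bounds: tuple[float, float] = (1e-13, 1e-3)
    beta3_bounds: tuple[float, float] = (0.05, 10.0)
    beta0_bounds: tuple[float, float] = (1e-6, 5.0)
    beta1_max_factor: float = 10.0
    tol: float = 1e-10
    flat_tol: float = 0.05
    rss_tie_rel: float = 0.01
    fit_means: bool = False


def _model_log(theta: np.ndarray, logx: np.ndarray, four: bool) -> np.ndarray:
    # (x/b2)**b3 computed as 10**(b3*(log10 x - log10 b2)) for stability
    if four:
        b0, b1, lb2, b3 = theta
    else:
        b0 = 1.0
        b1, lb2, b3 = theta
    return b1 + (b0 - b1) / (1.0 + 10.0 ** (b3 * (logx - lb2)))


def fit_dose_response(
    series: FoldActivationSeries,
    model_kind: ModelKind = "3PL",
    config: FitConfig | None = None,
    excluded_doses: Sequence[float] = (),
    d_max: float | None = None,
) -> "FitResult":
    """Fit a logistic curve by multistart nonlinear least squares.

    ``series`` should already be truncated by :func:`truncate_at_max_mean`
    (pass its ``d_max`` / ``excluded_doses`` through for the record). Every
    start is minimized with bounded trust-region least squares on
    log10(dose); among converged starts the smallest-RSS fit is selected.
    When several fits tie in RSS (within ``rss_tie_rel`` relative), the one
    whose EC50 lies inside the observed dose range is preferred — an EC50
    extrapolated beyond the ladder is not trustworthy — and otherwise the
    smallest EC50 wins.

    Raises
    ------
    NonConvergenceError
        If no start converges; carries per-start diagnostics.
    """
    if model_kind not in ("3PL", "4PL"):
        raise ConfigError(f"model_kind: unknown model {model_kind!r}")
    cfg = config or FitConfig()
    four = model_kind == "4PL"
    n_free = 4 if four else 3

    if cfg.fit_means:
        x, y = series.doses, series.mean_by_dose()
    else:
        x, y = series.flatten()
    if len(y) < n_free + 1:
        raise InputError(
            f"{series.construct}/{series.ligand}: {len(y)} observations cannot "
            f"constrain {n_free} free parameters"
        )
    if d_max is None:
        d_max = float(series.doses.max())

    if np.all(np.abs(y - 1.0) <= cfg.flat_tol):
        return FitResult(
            construct=series.construct,
            ligand=series.ligand,
            model_kind=model_kind,
            params=None,
            rss=float(np.sum((y - 1.0) ** 2)),
            excluded_doses=tuple(excluded_doses),
            d_max=d_max,
            n_points=len(y),
            n_starts=0,
            converged=False,
            flags=("no_activation",),
        )

    logx = np.log10(x)
    max_mean = float(series.mean_by_dose().max())
    b1_starts = cfg.beta1_starts or (2.0, max_mean, 2.0 * max_mean)
    lb2_starts = np.quantile(np.log10(series.doses), cfg.beta2_quantiles)
    b1_hi = cfg.beta1_max_factor * max_mean

    lo = [1e-6, np.log10(cfg.beta2_bounds[0]), cfg.beta3_bounds[0]]
    hi = [b1_hi, np.log10(cfg.beta2_bounds[1]), cfg.beta3_bounds[1]]
    if four:
        lo = [cfg.beta0_bounds[0]] + lo
        hi = [cfg.beta0_bounds[1]] + hi
    lo, hi = np.array(lo), np.array(hi)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model_log(theta, logx, four) - y

    fits: list[tuple[float, np.ndarray]] = []
    diagnostics: list[dict] = []
    n_starts = 0
    for b1 in b1_starts:
        for lb2 in lb2_starts:
            for b3 in cfg.beta3_starts:
                n_starts += 1
                theta0 = [min(max(b1, lo[-3] * 1.01), b1_hi * 0.99), lb2, b3]
                if four:
                    theta0 = [cfg.beta0_start] + theta0
                theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
                try:
                    res = least_squares(
                        residuals,
                        theta0,
                        bounds=(lo, hi),
                        method="trf",
                        ftol=cfg.tol,
                        xtol=cfg.tol,
                        gtol=cfg.tol,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    diagnostics.append({"start": list(theta0), "error": str(exc)})
                    continue
                if res.success:
                    fits.append((float(2.0 * res.cost), res.x))
                diagnostics.append(
                    {"start": list(theta0), "success": bool(res.success), "cost": float(res.cost)}
                )
    if not fits:
        raise NonConvergenceError(
            f"{series.construct}/{series.ligand}: no start converged", diagnostics
        )

    best_rss = min(r for r, _ in fits)
    tied = [(r, th) for r, th in fits if r <= best_rss * (1.0 + cfg.rss_tie_rel)]
    lb2_idx = 0 if not four else 1
    lo_dose, hi_dose = np.log10(series.doses.min()), np.log10(series.doses.max())
    inside = [(r, th) for r, th in tied if lo_dose <= th[lb2_idx + 1] <= hi_dose]
    if inside:
        rss, theta = min(inside, key=lambda t: t[0])
    else:
        rss, theta = min(tied, key=lambda t: t[1][lb2_idx + 1])

    if four:
        params: Logistic3Params | Logistic4Params = Logistic4Params(
            beta0=float(theta[0]),
            beta1=float(theta[1]),
            beta2=float(10.0 ** theta[2]),
            beta3=float(theta[3]),
        )
    else:
        params = Logistic3Params(
            beta1=float(theta[0]), beta2=float(10.0 ** theta[1]), beta3=float(theta[2])
        )
    flags = []
    if not (lo_dose <= np.log10(params.beta2) <= hi_dose):
        flags.append("ec50_outside_dose_range")
    return FitResult(
        construct=series.construct,
        ligand=series.ligand,
        model_kind=model_kind,
        params=params,
        rss=float(rss),
        excluded_doses=tuple(excluded_doses),
        d_max=d_max,
        n_points=len(y),
        n_starts=n_starts,
        converged=True,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multistart logistic fit for one construct x ligand."""

    construct: str
    ligand: str
    model_kind: ModelKind
    params: Logistic3Params | Logistic4Params | None
    rss: float
    excluded_doses: tuple[float, ...]
    d_max: float
    n_points: int
    n_starts: int
    converged: bool
    flags: tuple[str, ...] = ()

    @property
    def no_activation(self) -> bool:
        return "no_activation" in self.flags


def estimate_ec50(fit: FitResult, unit: Literal["molar", "nM"] = "molar") -> float:
    """EC50 of a converged fit, in molar (default) or nM (x 1e9)."""
    if fit.no_activation or fit.params is None:
        raise NoActivationError(
            f"{fit.construct}/{fit.ligand}: no activation above baseline, EC50 undefined"
        )
    ec50 = fit.params.beta2
    return ec50 * 1e9 if unit == "nM" else ec50


def fit_measurement_table(
    raw: pd.DataFrame,
    model_for_construct: dict[str, ModelKind] | None = None,
    config: FitConfig | None = None,
) -> tuple[pd.DataFrame, list[FitResult]]:
    """Run the full chain — normalize, truncate, fit — over a raw table.

    ``model_for_construct`` selects the 4PL for specific constructs (3PL is
    the default everywhere). Returns a summary table with one row per
    (construct, ligand): fitted parameters, EC50 in nM, RSS, d_max, excluded
    doses and flags, alongside the FitResult objects.
    """
    model_for_construct = model_for_construct or {}
    rows, results = [], []
    for construct, sub in raw.groupby("construct", sort=True):
        if (sub["dose_molar"] > 0).sum() == 0:
            raise InputError(f"{construct}: no treatment rows (only vehicle)")
        kind = model_for_construct.get(str(construct), "3PL")
        for series in normalize_to_vehicle(sub):
            truncated, d_max, excluded = truncate_at_max_mean(series)
            fit = fit_dose_response(
                truncated, model_kind=kind, config=config, excluded_doses=excluded, d_max=d_max
            )
            results.append(fit)
            p = fit.params
            rows.append(
                {
                    "construct": fit.construct,
                    "ligand": fit.ligand,
                    "model": fit.model_kind,
                    "beta0": getattr(p, "beta0", 1.0) if p else np.nan,
                    "beta1": p.beta1 if p else np.nan,
                    "ec50_nM": p.beta2 * 1e9 if p else np.nan,
                    "beta3": p.beta3 if p else np.nan,
                    "rss": fit.rss,
                    "d_max": fit.d_max,
                    "excluded_doses": ";".join(f"{d:g}" for d in fit.excluded_doses),
                    "flags": ";".join(fit.flags),
                }
            )
    return pd.DataFrame(rows), results
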