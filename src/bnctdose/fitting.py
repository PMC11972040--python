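"""Error-weighted nonlinear fitting of repair kinetics and survival curves.

Three fits are provided, mirroring how the radiobiological parameter set of
the isoeffective dose model is assembled from experiments:

1. bi-exponential foci-decay fit -> fast/slow repair times and fast fraction;
2. reference photon survival fit -> (alpha_R, beta_R) of the reference
   radiation, with the protraction factor per point taken as acute (G = 1) or
   computed from the delivery time at a constant dose rate;
3. simultaneous beam-only + BPA-BNCT fit -> (alpha_n, beta_n, alpha_B,
   beta_B), with the photon parameters held fixed at the reference values.

All fits minimize weighted residuals with non-negativity bounds (lmfit /
trust-region least squares); survival fits work in log-survival, where the
MLQ exponent is linear in the parameters being estimated. Confidence
intervals default to the linearized (covariance-based) 68% level; a seeded
parametric bootstrap is available as a cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    IrradiationProtocol,
    LetClass,
    LQParameters,
    MixedFieldDose,
    RepairKinetics,
    foci_intensity,
    g_dual,
    g_factors,
    log_kill_mixed,
)
from .errors import (
    ConvergenceError,
    IdentifiabilityError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "Condition",
    "FociTimeSeries",
    "SurvivalDataPoint",
    "FitResult",
    "fit_repair_kinetics",
    "fit_reference_curve",
    "fit_mixed_field_curves",
    "confidence_intervals",
    "parametric_bootstrap",
    "read_survival_table",
    "write_survival_table",
    "read_foci_series",
    "write_foci_series",
    "fit_result_to_dict",
    "save_fit_result",
]

#: absolute tolerance for declaring a parameter to sit on its lower bound
_BOUND_TOL = 1e-7


class Condition(str, Enum):
    """Experimental irradiation condition of a survival data point."""

    REFERENCE_PHOTON = "reference_photon"
    BEAM_ONLY = "beam_only"
    BPA_BNCT = "bpa_bnct"


@dataclass(frozen=True)
class FociTimeSeries:
    """Normalized DNA-damage foci counts versus time after irradiation."""

    times: np.ndarray
    intensities: np.ndarray
    sigmas: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)
        if self.sigmas is not None:
            s = np.asarray(self.sigmas, dtype=float)
            object.__setattr__(self, "sigmas", s)
            if s.shape != t.shape or np.any(s <= 0):
                raise InvalidInputError("sigmas must be positive and match times")
        if t.ndim != 1 or t.shape != i.shape:
            raise InvalidInputError("times and intensities must be 1-D and equal length")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise InvalidInputError("times must be strictly increasing and start >= 0")
        if np.any(i <= 0):
            raise InvalidInputError("intensities must be positive")


@dataclass(frozen=True)
class SurvivalDataPoint:
    """One clonogenic-assay point: component doses, survival and uncertainties."""

    dose: MixedFieldDose
    surviving_fraction: float
    sf_sigma: float
    protocol: IrradiationProtocol
    condition: Condition
    dose_sigma: MixedFieldDose | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.surviving_fraction <= 1.0):
            raise InvalidInputError(
                f"surviving fraction must lie in (0, 1], got {self.surviving_fraction}"
            )
        if self.sf_sigma <= 0:
            raise InvalidInputError("sf_sigma must be > 0")
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.condition is Condition.BEAM_ONLY and self.dose.d_boron != 0:
            raise InvalidInputError("beam-only points must have zero boron dose")
        if self.condition is Condition.REFERENCE_PHOTON and (
            self.dose.d_boron != 0 or self.dose.d_neutron != 0
        ):
            raise InvalidInputError("reference points must have only a photon dose")


@dataclass
class FitResult:
    """Estimates, 68% half-widths, covariance and diagnostics of one fit."""

    estimates: dict[str, float]
    sigmas: dict[str, float]
    covariance: np.ndarray | None
    param_names: list[str]
    objective: float
    n_points: int
    boundary_flags: dict[str, bool] = field(default_factory=dict)
    mse: float = float("nan")
    unidentifiable: list[str] = field(default_factory=list)


def _result_from_minimizer(out: lmfit.minimizer.MinimizerResult, names: Sequence[str]) -> FitResult:
    estimates = {n: float(out.params[n].value) for n in names}
    sigmas = {}
    unident = []
    for n in names:
        err = out.params[n].stderr
        if err is None or not np.isfinite(err):
            sigmas[n] = float("nan")
            unident.append(n)
        else:
            sigmas[n] = float(err)
    cov = getattr(out, "covar", None)
    if cov is not None:
        cov = np.asarray(cov, dtype=float)
    flags = {
        n: bool(
            out.params[n].min is not None
            and np.isfinite(out.params[n].min)
            and abs(out.params[n].value - out.params[n].min) <= _BOUND_TOL
        )
        for n in names
    }
    resid = np.asarray(out.residual, dtype=float)
    return FitResult(
        estimates=estimates,
        sigmas=sigmas,
        covariance=cov,
        param_names=list(names),
        objective=float(np.sum(resid**2)),
        n_points=int(resid.size),
        boundary_flags=flags,
        mse=float(np.mean(resid**2)),
        unidentifiable=unident,
    )


def _minimize_multistart(
    residual: Callable[[lmfit.Parameters], np.ndarray],
    starts: Sequence[lmfit.Parameters],
    scale_covar: bool,
) -> lmfit.minimizer.MinimizerResult:
    best = None
    for params in starts:
        try:
            out = lmfit.minimize(
                residual,
                params,
                method="least_squares",
                scale_covar=scale_covar,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise ConvergenceError("all multi-start fits failed")
    return best


# --------------------------------------------------------------------------
# Repair-kinetics (foci decay) fit
# --------------------------------------------------------------------------

def fit_repair_kinetics(series: FociTimeSeries, seed: int = 0) -> FitResult:
    """Fit the bi-exponential foci decay for (c, t0_fast, t0_slow).

    Multi-start bound-constrained least squares (the objective is shallow in
    the slow time constant); the fast/slow labels are normalized after the fit
    so that ``t0_fast <= t0_slow``. Residuals are weighted by the series
    sigmas when available, otherwise unweighted (covariance then scaled by the
    reduced chi-square).
    """
    t = series.times
    y = series.intensities
    if t.size < 4:
        raise InsufficientDataError("need at least 4 time points for 3 parameters")
    w = 1.0 / series.sigmas if series.sigmas is not None else np.ones_like(y)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = foci_intensity(t, p["c"].value, p["t0f"].value, p["t0s"].value)
        return (y - model) * w

    t_span = max(t[-1], 1.0)
    rng = np.random.default_rng(seed)
    starts = []
    for t0f0 in (t_span / 50, t_span / 10, t_span / 3):
        for t0s0 in (t_span / 2, t_span, 5 * t_span):
            for c0 in (0.5, 0.8):
                p = lmfit.Parameters()
                p.add("c", value=c0, min=0.0, max=1.0)
                p.add("t0f", value=t0f0, min=1e-6)
                p.add("t0s", value=t0s0, min=1e-6)
                starts.append(p)
    # a few jittered extra starts guard against pathological series
    for _ in range(4):
        p = lmfit.Parameters()
        p.add("c", value=rng.uniform(0.1, 0.9), min=0.0, max=1.0)
        p.add("t0f", value=t_span * 10 ** rng.uniform(-2, 0), min=1e-6)
        p.add("t0s", value=t_span * 10 ** rng.uniform(-0.5, 1), min=1e-6)
        starts.append(p)

    out = _minimize_multistart(residual, starts, scale_covar=series.sigmas is None)
    res = _result_from_minimizer(out, ["c", "t0f", "t0s"])
    if res.estimates["t0f"] > res.estimates["t0s"]:
        _relabel_fast_slow(res)
    return res


def _relabel_fast_slow(res: FitResult) -> None:
    """Swap the fast/slow labels so t0f <= t0s; c maps to 1 - c."""
    e, s, f = res.estimates, res.sigmas, res.boundary_flags
    e["t0f"], e["t0s"] = e["t0s"], e["t0f"]
    s["t0f"], s["t0s"] = s["t0s"], s["t0f"]
    f["t0f"], f["t0s"] = f["t0s"], f["t0f"]
    e["c"] = 1.0 - e["c"]
    if res.covariance is not None and res.covariance.shape == (3, 3):
        # parameter order (c, t0f, t0s): permute the time rows/cols and flip
        # the sign of covariances with c (variance of 1-c equals that of c)
        perm = np.array([[-1, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
        res.covariance = perm @ res.covariance @ perm.T


# --------------------------------------------------------------------------
# Survival-curve fits
# --------------------------------------------------------------------------

def _sorted_points(points: Sequence[SurvivalDataPoint]) -> list[SurvivalDataPoint]:
    # canonical ordering makes the fit exactly invariant to input order
    return sorted(
        points,
        key=lambda p: (
            p.condition.value,
            p.dose.d_boron,
            p.dose.d_neutron,
            p.dose.d_photon,
            p.protocol.duration,
        ),
    )


def _reference_g(point: SurvivalDataPoint, kinetics: RepairKinetics, mode: str, dose_rate: float) -> float:
    if mode == "acute":
        return 1.0
    if mode == "constant_rate":
        rate = point.protocol.dose_rate or dose_rate
        theta = point.dose.d_photon / rate if point.dose.d_photon > 0 else 0.0
        return g_dual(theta, kinetics, LetClass.LOW)
    raise InvalidInputError(f"unknown protraction mode {mode!r}")


def fit_reference_curve(
    points: Sequence[SurvivalDataPoint],
    kinetics: RepairKinetics,
    protraction_mode: str = "acute",
    dose_rate: float = 1.0,
) -> FitResult:
    """Weighted least-squares MLQ fit of a reference photon survival curve.

    Fits ``ln S = -(alpha D + beta G D^2)`` with non-negativity bounds; the
    per-point protraction factor is 1 in ``acute`` mode or computed from
    ``theta = D / dose_rate`` in ``constant_rate`` mode. Weights are the
    propagated log-survival uncertainties, and the covariance is left
    unscaled so that the reported 68% intervals reflect the supplied errors.
    """
    pts = _sorted_points(points)
    for p in pts:
        if p.condition is not Condition.REFERENCE_PHOTON:
            raise InvalidInputError("reference fit accepts only reference_photon points")
    doses = np.array([p.dose.d_photon for p in pts])
    if np.count_nonzero(doses) < 3:
        raise InsufficientDataError("need at least 3 nonzero-dose points")
    logs = np.log([p.surviving_fraction for p in pts])
    # sigma of ln S by error propagation: sigma_S / S
    sig_log = np.array([p.sf_sigma / p.surviving_fraction for p in pts])
    g = np.array([_reference_g(p, kinetics, protraction_mode, dose_rate) for p in pts])

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = -(p["alpha"].value * doses + p["beta"].value * g * doses**2)
        return (logs - model) / sig_log

    starts = []
    for a0, b0 in ((0.2, 0.02), (0.5, 0.05), (1.0, 0.2)):
        p = lmfit.Parameters()
        p.add("alpha", value=a0, min=0.0)
        p.add("beta", value=b0, min=0.0)
        starts.append(p)
    out = _minimize_multistart(residual, starts, scale_covar=False)
    return _result_from_minimizer(out, ["alpha", "beta"])


def fit_mixed_field_curves(
    beam_only: Sequence[SurvivalDataPoint],
    bnct: Sequence[SurvivalDataPoint],
    photon_params: LQParameters,
    kinetics: RepairKinetics,
) -> FitResult:
    """Simultaneous MLQ fit of beam-only and BPA-BNCT survival curves.

    Shares (alpha_n, beta_n) between the two conditions; (alpha_B, beta_B) are
    informed only by the BNCT points. The photon parameters are held fixed at
    the reference-radiation values, and per-point G factors follow each
    point's delivery duration. beta_B commonly lands on its zero bound and is
    flagged accordingly.
    """
    if not beam_only or not bnct:
        raise IdentifiabilityError(
            "both beam-only and BPA-BNCT curves are required; boron parameters "
            "are unidentifiable without BNCT points"
        )
    pts = _sorted_points(list(beam_only) + list(bnct))
    if not any(p.dose.d_boron > 0 for p in pts):
        raise IdentifiabilityError("BNCT points carry no boron dose")
    logs = np.log([p.surviving_fraction for p in pts])
    sig_log = np.array([p.sf_sigma / p.surviving_fraction for p in pts])
    gfs = [g_factors(p.protocol, kinetics) for p in pts]

    def residual(p: lmfit.Parameters) -> np.ndarray:
        neutron = LQParameters(p["alpha_n"].value, p["beta_n"].value, LetClass.HIGH)
        boron = LQParameters(p["alpha_b"].value, p["beta_b"].value, LetClass.HIGH)
        model = np.array(
            [
                -log_kill_mixed(
                    pt.dose.d_boron,
                    pt.dose.d_neutron,
                    pt.dose.d_photon,
                    photon_params,
                    neutron,
                    boron,
                    gf,
                )
                for pt, gf in zip(pts, gfs)
            ]
        )
        return (logs - model) / sig_log

    starts = []
    for a_n in (0.1, 1.0):
        for b_n in (0.1, 0.8):
            for a_b in (1.0, 3.0):
                for b_b in (0.0, 0.1):
                    p = lmfit.Parameters()
                    p.add("alpha_n", value=a_n, min=0.0)
                    p.add("beta_n", value=b_n, min=0.0)
                    p.add("alpha_b", value=a_b, min=0.0)
                    p.add("beta_b", value=b_b, min=0.0)
                    starts.append(p)
    out = _minimize_multistart(residual, starts, scale_covar=False)
    return _result_from_minimizer(out, ["alpha_n", "beta_n", "alpha_b", "beta_b"])


# --------------------------------------------------------------------------
# Confidence intervals
# --------------------------------------------------------------------------

def confidence_intervals(fit: FitResult, level: float = 0.68) -> dict[str, float]:
    """Per-parameter half-widths at the given confidence level.

    Linearized (normal-theory) intervals from the fit covariance: half-width =
    z * sigma with z the two-sided normal quantile. Parameters whose
    covariance direction is singular are reported in ``fit.unidentifiable``
    and get NaN half-widths rather than numbers.
    """
    if not (0.0 <= level < 1.0):
        raise InvalidInputError(f"level must lie in [0, 1), got {level}")
    if level == 0.0:
        return {n: 0.0 for n in fit.param_names}
    z = stats.norm.ppf(0.5 + level / 2.0)
    return {
        n: (float("nan") if n in fit.unidentifiable else z * fit.sigmas[n])
        for n in fit.param_names
    }


def parametric_bootstrap(
    refit: Callable[[np.random.Generator], FitResult],
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.68,
) -> dict[str, float]:
    """Seeded parametric-bootstrap half-widths.

    ``refit`` simulates one dataset from the fitted model using the supplied
    generator and refits it; the half-width is z * the empirical standard
    deviation of the bootstrap estimates (comparable with the linearized CI).
    """
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {}
    for _ in range(n_boot):
        res = refit(rng)
        for k, v in res.estimates.items():
            draws.setdefault(k, []).append(v)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return {k: float(z * np.std(v, ddof=1)) for k, v in draws.items()}


# --------------------------------------------------------------------------
# Delimited-text IO and fit-result serialization
# --------------------------------------------------------------------------

_SURVIVAL_COLUMNS = [
    "condition",
    "d_boron",
    "d_neutron",
    "d_photon",
    "d_boron_sigma",
    "surviving_fraction",
    "sf_sigma",
    "duration_min",
]


def write_survival_table(path, points: Sequence[SurvivalDataPoint]) -> None:
    rows = []
    for p in points:
        rows.append(
            {
                "condition": p.condition.value,
                "d_boron": p.dose.d_boron,
                "d_neutron": p.dose.d_neutron,
                "d_photon": p.dose.d_photon,
                "d_boron_sigma": p.dose_sigma.d_boron if p.dose_sigma else 0.0,
                "surviving_fraction": p.surviving_fraction,
                "sf_sigma": p.sf_sigma,
                "duration_min": p.protocol.duration,
            }
        )
    pd.DataFrame(rows, columns=_SURVIVAL_COLUMNS).to_csv(path, index=False)


def read_survival_table(path) -> list[SurvivalDataPoint]:
    df = pd.read_csv(path)
    missing = set(_SURVIVAL_COLUMNS) - {"d_boron_sigma"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"survival table missing columns: {sorted(missing)}")
    points = []
    for _, row in df.iterrows():
        dose_sigma = None
        if "d_boron_sigma" in df.columns and row["d_boron_sigma"] > 0:
            dose_sigma = MixedFieldDose(d_boron=float(row["d_boron_sigma"]))
        points.append(
            SurvivalDataPoint(
                dose=MixedFieldDose(
                    float(row["d_boron"]), float(row["d_neutron"]), float(row["d_photon"])
                ),
                surviving_fraction=float(row["surviving_fraction"]),
                sf_sigma=float(row["sf_sigma"]),
                protocol=IrradiationProtocol(duration=float(row["duration_min"])),
                condition=Condition(row["condition"]),
                dose_sigma=dose_sigma,
            )
        )
    return points


def write_foci_series(path, series: FociTimeSeries) -> None:
    df = pd.DataFrame({"time_min": series.times, "intensity": series.intensities})
    if series.sigmas is not None:
        df["sigma"] = series.sigmas
    df.to_csv(path, index=False)


def read_foci_series(path) -> FociTimeSeries:
    df = pd.read_csv(path)
    if not {"time_min", "intensity"} <= set(df.columns):
        raise InvalidInputError("foci series needs columns time_min, intensity")
    sigmas = df["sigma"].to_numpy(float) if "sigma" in df.columns else None
    return FociTimeSeries(
        times=df["time_min"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        sigmas=sigmas,
    )


def fit_result_to_dict(fit: FitResult, provenance: dict | None = None) -> dict:
    return {
        "estimates": fit.estimates,
        "sigmas_68": fit.sigmas,
        "covariance": None if fit.covariance is None else fit.covariance.tolist(),
        "param_names": fit.param_names,
        "objective": fit.objective,
        "n_points": fit.n_points,
        "boundary_flags": fit.boundary_flags,
        "mse": fit.mse,
        "unidentifiable": fit.unidentifiable,
        "provenance": provenance or {},
    }


def save_fit_result(path, fit: FitResult, provenance: dict | None = None) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit, provenance), indent=2))
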