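"""Aggregated Poisson regression with the three-level adjustment ladder.

Death counts per (tract x age-sex stratum) are modelled as Poisson with
a log link and log person-years offset:

    log E[y_ts] = log(py_ts) + b0 + b_x * x_t + stratum + SES terms

Level 1 is the crude association (exposure only), level 2 adds age-sex
stratum indicators, level 3 adds deprivation-category indicators.  The
fit is Fisher scoring (IRLS) on the exact likelihood; effects are
reported as percent change per a stated concentration increment,
(exp(increment * b) - 1) * 100, with Wald 95% intervals on the log scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .config import SES_CATEGORIES, STRATA, stratum_column
from .exposure import exposure_wide

logger = logging.getLogger(__name__)

HARBOUR_VARIABLE = "harbour"


@dataclass(frozen=True)
class ModelSpec:
    """One regression cell: cause, exposure variable, adjustment level."""

    outcome_cause: str
    exposure_variable: str  # pollutant name or "harbour"
    adjustment_level: int = 3
    increment: float = 5.0  # ug/m3 (ignored for the harbour indicator)

    def __post_init__(self) -> None:
        if self.adjustment_level not in (1, 2, 3):
            raise ValueError("adjustment_level must be 1, 2 or 3")
        if self.increment <= 0:
            raise ValueError("increment must be positive")


@dataclass
class DesignMatrix:
    """Model data: response, offset and covariates with named columns."""

    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    columns: list[str]
    index: pd.DataFrame  # (tract_id, age_class, sex) per row
    n_dropped: int = 0


@dataclass
class RegressionFit:
    params: pd.Series
    cov: pd.DataFrame
    deviance: float
    iterations: int
    converged: bool
    message: str = ""
    scale: float = 1.0
    #: coefficients drifting toward +/- infinity (separation analog:
    #: e.g. an indicator whose cells contain no events)
    drift_flags: list[str] = None

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))


@dataclass(frozen=True)
class PercentChange:
    estimate: float
    lower: float
    upper: float
    variable: str
    increment: float


def build_design(tracts: pd.DataFrame, deaths: pd.DataFrame,
                 exposures: pd.DataFrame | None, stratum: pd.DataFrame | None,
                 spec: ModelSpec,
                 ref_stratum: tuple[str, str] = ("35-64", "m"),
                 ref_ses: str = "very_high") -> DesignMatrix:
    """Assemble one analysis row per populated (tract x age-sex stratum).

    The exposure covariate is either an assigned pollutant mean
    (constant within tract) or the harbour indicator.  Rows with zero
    person-years are dropped (count logged); an all-zero outcome or an
    SES factor collapsed to a single category is rejected / degraded
    with an explicit message.
    """
    tr = tracts.set_index("tract_id")
    counts = deaths[deaths["cause"] == spec.outcome_cause].pivot_table(
        index=["tract_id", "age_class", "sex"], values="deaths",
        aggfunc="sum")["deaths"]

    if spec.exposure_variable == HARBOUR_VARIABLE:
        if stratum is None:
            raise ValueError("harbour model requires a stratum table")
        xvals = stratum.set_index("tract_id")["harbour"].astype(float)
    else:
        if exposures is None:
            raise ValueError("pollutant model requires an exposure table")
        xw = exposure_wide(exposures)
        if spec.exposure_variable not in xw.columns:
            raise ValueError(
                f"no exposure values for {spec.exposure_variable!r}")
        xvals = xw[spec.exposure_variable]
    missing = tr.index.difference(xvals.index)
    if len(missing):
        raise ValueError(f"tracts without exposure: {list(missing)[:5]}")

    rows = []
    n_dropped = 0
    for tid in tr.index:
        for age, sex in STRATA:
            pop = tr.at[tid, stratum_column(age, sex)]
            if pop <= 0:
                n_dropped += 1
                continue
            y = counts.get((tid, age, sex), 0)
            rows.append((tid, age, sex, float(pop), float(y),
                         float(xvals.loc[tid]), tr.at[tid, "ses_category"]))
    if n_dropped:
        logger.info("dropped %d zero-population stratum rows", n_dropped)
    frame = pd.DataFrame(rows, columns=["tract_id", "age_class", "sex",
                                        "pop", "y", "x", "ses"])
    if frame["y"].sum() == 0:
        raise ValueError(
            f"all {spec.outcome_cause} counts are zero; fit refused")

    cols = {"intercept": np.ones(len(frame)),
            spec.exposure_variable: frame["x"].to_numpy()}
    if spec.adjustment_level >= 2:
        present_strata = set(map(tuple, frame[["age_class", "sex"]]
                                 .drop_duplicates().to_numpy()))
        ref_s = ref_stratum if ref_stratum in present_strata \
            else sorted(present_strata)[0]
        for age, sex in STRATA:
            if (age, sex) == ref_s or (age, sex) not in present_strata:
                continue
            cols[f"stratum[{age}|{sex}]"] = (
                (frame["age_class"] == age) & (frame["sex"] == sex)
            ).to_numpy(dtype=float)
    if spec.adjustment_level >= 3:
        present = set(frame["ses"].unique())
        if len(present) < 2:
            warnings.warn(
                "SES has a single category; deprivation indicators dropped",
                stacklevel=2)
        else:
            # fall back to a present reference so the block stays full rank
            ref = ref_ses if ref_ses in present else sorted(present)[0]
            for ses in SES_CATEGORIES:
                if ses == ref or ses not in present:
                    continue
                cols[f"ses[{ses}]"] = (frame["ses"] == ses).to_numpy(dtype=float)

    X = np.column_stack(list(cols.values()))
    # person-years offset: population held static over the study window
    offset = np.log(frame["pop"].to_numpy())
    return DesignMatrix(X=X, y=frame["y"].to_numpy(), offset=offset,
                        columns=list(cols), index=frame[["tract_id",
                                                         "age_class", "sex"]],
                        n_dropped=n_dropped)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_poisson(design: DesignMatrix, tol: float = 1e-8,
                dev_tol: float = 1e-10, max_iter: int = 100,
                quasi: bool = False) -> RegressionFit:
    """Maximum-likelihood Poisson fit by Fisher scoring.

    Converged when the score max-norm drops below ``tol`` and the
    relative deviance change below ``dev_tol``.  The covariance is the
    inverse Fisher information at the optimum (multiplied by the Pearson
    dispersion when ``quasi`` is requested).  Rank deficiency and
    separation-like divergence produce flagged, never silent, results.
    """
    X, y, offset = design.X, design.y, design.offset
    n, p = X.shape
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        bad = design.columns[piv[int(np.argmin(diag))]]
        raise ValueError(f"design is rank deficient; aliased column {bad!r}")

    mu = y + 0.5
    eta = np.log(mu)
    beta = np.zeros(p)
    deviance = _poisson_deviance(y, mu)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        z = (eta - offset) + (y - mu) / mu
        sw = np.sqrt(mu)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta + offset
        if np.max(np.abs(eta)) > 700:
            message = "diverging linear predictor (separation-like geometry)"
            break
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        score = X.T @ (y - mu)
        # score measured relative to the information scale so the
        # criterion is attainable at any data magnitude
        score_scale = np.abs(X).T @ mu + 1.0
        rel = abs(new_dev - deviance) / (abs(deviance) + 1e-12)
        deviance = new_dev
        if np.max(np.abs(score) / score_scale) < tol and rel < dev_tol:
            converged = True
            break
    if not converged and not message:
        message = f"no convergence in {max_iter} iterations"

    info = (X * mu[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
        message = message or "singular Fisher information"
    scale = 1.0
    if quasi:
        pearson = float(np.sum((y - mu) ** 2 / mu))
        scale = pearson / max(n - p, 1)
        cov = cov * scale
    drift = [c for c, b in zip(design.columns, beta) if abs(b) > 10.0]
    if drift and not message:
        message = f"coefficient drift (separation analog) in {drift}"
    return RegressionFit(
        params=pd.Series(beta, index=design.columns),
        cov=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        deviance=deviance, iterations=it, converged=converged,
        message=message, scale=scale, drift_flags=drift,
    )


def percent_change(fit: RegressionFit, variable: str,
                   increment: float = 5.0,
                   z: float = 1.959963984540054) -> PercentChange:
    """Percent change of the rate per ``increment`` units of ``variable``."""
    if variable not in fit.params.index:
        raise ValueError(f"variable {variable!r} not in the fit")
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.message}")
    if fit.drift_flags and variable in fit.drift_flags:
        raise ValueError(
            f"{variable!r} drifted without bound (separation analog)")
    b = fit.params[variable]
    se = fit.se(variable)
    est = (np.exp(increment * b) - 1.0) * 100.0
    lo = (np.exp(increment * (b - z * se)) - 1.0) * 100.0
    hi = (np.exp(increment * (b + z * se)) - 1.0) * 100.0
    return PercentChange(estimate=float(est), lower=float(lo), upper=float(hi),
                         variable=variable, increment=increment)


def run_association_suite(tracts: pd.DataFrame, deaths: pd.DataFrame,
                          exposures: pd.DataFrame, stratum: pd.DataFrame,
                          causes: list[str], pollutants: list[str],
                          levels: tuple[int, ...] = (1, 2, 3),
                          increment: float = 5.0,
                          include_harbour: bool = True) -> pd.DataFrame:
    """Grid of percent-change estimates over cause x exposure x level.

    Pollutant effects are per ``increment`` ug/m3; the harbour row is
    the indicator contrast (increment 1).  Failed cells are reported
    with ``converged=False`` rather than aborting the suite.
    """
    variables = list(pollutants) + ([HARBOUR_VARIABLE] if include_harbour else [])
    rows = []
    for cause in causes:
        for var in variables:
            inc = 1.0 if var == HARBOUR_VARIABLE else increment
            for level in levels:
                spec = ModelSpec(outcome_cause=cause, exposure_variable=var,
                                 adjustment_level=level, increment=inc)
                rec = {"cause": cause, "exposure": var, "level": level,
                       "increment": inc, "pct": np.nan, "lo": np.nan,
                       "hi": np.nan, "converged": False, "message": ""}
                try:
                    design = build_design(tracts, deaths, exposures, stratum, spec)
                    fit = fit_poisson(design)
                    if fit.converged:
                        pc = percent_change(fit, var, inc)
                        rec.update(pct=pc.estimate, lo=pc.lower, hi=pc.upper,
                                   converged=True)
                    else:
                        rec["message"] = fit.message
                except ValueError as exc:
                    rec["message"] = str(exc)
                    logger.warning("suite cell (%s, %s, %d) failed: %s",
                                   cause, var, level, exc)
                rows.append(rec)
    return pd.DataFrame(rows)
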