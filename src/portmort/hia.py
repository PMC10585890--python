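"""Health impact assessment against WHO air-quality-guideline counterfactuals.

For each cause and pollutant the attributable fraction of deaths at
excess exposure D = exposure - AQG is

    AF = 1 - exp(-beta * D) = (RR_D - 1) / RR_D,    beta = ln(RR) / increment

clamped to zero when exposure is at or below the guideline (the
counterfactual is compliance, so only preventable deaths count).
Attributable deaths are AD = sum_t TD_t * AF(x_t) / study_years with
uncertainty from substituting the concentration-response lower / upper
relative risks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import exposure_wide

#: WHO 2021 annual-mean air quality guideline values, ug/m3.
AQG_2021 = {"pm25": 5.0, "pm10": 15.0, "no2": 10.0}


@dataclass(frozen=True)
class CRF:
    """Concentration-response function: RR per increment, with AQG."""

    cause: str
    pollutant: str
    rr: float
    rr_lower: float
    rr_upper: float
    increment: float = 10.0  # ug/m3
    aqg: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.rr_lower <= self.rr <= self.rr_upper):
            raise ValueError("require 0 < rr_lower <= rr <= rr_upper")
        if self.increment <= 0 or self.aqg < 0:
            raise ValueError("increment must be > 0 and AQG >= 0")


@dataclass
class CRFSet:
    entries: list[CRF] = field(default_factory=list)

    def get(self, cause: str, pollutant: str) -> CRF:
        for e in self.entries:
            if e.cause == cause and e.pollutant == pollutant:
                return e
        raise KeyError(f"no CRF for ({cause}, {pollutant})")

    def pairs(self) -> list[tuple[str, str]]:
        return [(e.cause, e.pollutant) for e in self.entries]


def default_crf_set(include_no2: bool = True) -> CRFSet:
    """Meta-analytic PM2.5 relative risks per 10 ug/m3, plus NO2 slots.

    The PM2.5 entries are the systematic-review values used to derive
    the 2021 guidelines (natural here = non-accidental mortality).  The
    NO2 entries are user-supplied placeholders meant to be overridden
    from a CRF file; they are not literature constants shipped with any
    authority.
    """
    entries = [
        CRF("natural", "pm25", 1.08, 1.06, 1.09, 10.0, AQG_2021["pm25"]),
        CRF("cardiovascular", "pm25", 1.11, 1.09, 1.14, 10.0, AQG_2021["pm25"]),
        CRF("respiratory", "pm25", 1.10, 1.03, 1.18, 10.0, AQG_2021["pm25"]),
        CRF("lung_cancer", "pm25", 1.12, 1.07, 1.16, 10.0, AQG_2021["pm25"]),
    ]
    if include_no2:
        entries += [
            CRF("natural", "no2", 1.02, 1.01, 1.04, 10.0, AQG_2021["no2"]),
            CRF("cardiovascular", "no2", 1.03, 1.01, 1.05, 10.0, AQG_2021["no2"]),
            CRF("respiratory", "no2", 1.03, 1.01, 1.05, 10.0, AQG_2021["no2"]),
        ]
    return CRFSet(entries)


def beta_from_rr(rr: float, increment: float) -> float:
    """Log rate ratio per 1 ug/m3 from an RR stated per ``increment``."""
    if rr <= 0 or increment <= 0:
        raise ValueError("rr and increment must be positive")
    return math.log(rr) / increment


def attributable_fraction(beta: float, exposure: float, aqg: float) -> float:
    """AF = 1 - exp(-beta * (exposure - AQG)), zero at or below the AQG."""
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    if exposure < 0 or aqg < 0:
        raise ValueError("exposure and AQG must be non-negative")
    delta = exposure - aqg
    if delta <= 0:
        return 0.0
    return 1.0 - math.exp(-beta * delta)


@dataclass
class HIAResult:
    """Annual attributable deaths per (cause, pollutant) with bounds."""

    summary: pd.DataFrame  # cause, pollutant, af, ad, ad_lower, ad_upper
    by_tract: pd.DataFrame  # tract_id, cause, pollutant, ad


def attributable_deaths(deaths: pd.DataFrame, exposures: pd.DataFrame,
                        crf: CRFSet, study_years: int,
                        mode: str = "tract",
                        population: pd.Series | None = None) -> HIAResult:
    """Annual attributable deaths for every (cause, pollutant) in the CRF set.

    mode="tract" evaluates AF at each tract's assigned exposure and sums
    tract death totals; mode="citywide" applies the AF of the
    population-weighted citywide mean exposure to citywide totals
    (aggregate diagnostic; requires ``population`` indexed by tract_id).
    Bounds re-evaluate the AF with the RR lower / upper limits.
    """
    if mode not in ("tract", "citywide"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "citywide" and population is None:
        raise ValueError("citywide mode needs a tract population series")
    xw = exposure_wide(exposures)
    td = deaths.groupby(["tract_id", "cause"])["deaths"].sum()

    summary_rows = []
    tract_rows = []
    for cause, pollutant in crf.pairs():
        entry = crf.get(cause, pollutant)
        if cause not in deaths["cause"].unique():
            raise ValueError(f"death table has no cause {cause!r}")
        td_c = td.xs(cause, level="cause")
        missing = td_c.index[(td_c > 0)].difference(xw.index)
        if len(missing):
            raise ValueError(
                f"tracts with {cause} deaths but no {pollutant} exposure: "
                f"{list(missing)[:5]}")
        x = xw[pollutant]

        def _ad(rr: float) -> tuple[float, pd.Series]:
            beta = beta_from_rr(rr, entry.increment)
            af = x.map(lambda v: attributable_fraction(beta, v, entry.aqg))
            per_tract = (td_c.reindex(x.index, fill_value=0) * af) / study_years
            return float(per_tract.sum()), per_tract

        if mode == "citywide":
            w = population.reindex(x.index)
            if w.isna().any():
                raise ValueError("population series missing tracts")
            x_city = float(np.average(x.to_numpy(), weights=w.to_numpy()))
            total = float(td_c.sum()) / study_years

            def _ad(rr: float, _x=x_city, _t=total):  # noqa: E731 shadowing
                beta = beta_from_rr(rr, entry.increment)
                af = attributable_fraction(beta, _x, entry.aqg)
                return _t * af, pd.Series(dtype=float)

        ad, per_tract = _ad(entry.rr)
        ad_lo, _ = _ad(entry.rr_lower)
        ad_hi, _ = _ad(entry.rr_upper)
        af_overall = ad * study_years / td_c.sum() if td_c.sum() else 0.0
        summary_rows.append({
            "cause": cause, "pollutant": pollutant, "af": af_overall,
            "ad": ad, "ad_lower": ad_lo, "ad_upper": ad_hi,
        })
        if mode == "tract":
            f = per_tract.rename("ad").reset_index()
            f["cause"] = cause
            f["pollutant"] = pollutant
            tract_rows.append(f)

    by_tract = (pd.concat(tract_rows, ignore_index=True)
                if tract_rows else pd.DataFrame(
                    columns=["tract_id", "ad", "cause", "pollutant"]))
    return HIAResult(summary=pd.DataFrame(summary_rows), by_tract=by_tract)


def hia_report(result: HIAResult, csv_path=None, png_path=None) -> pd.DataFrame:
    """Annual-attributable-deaths table and bar chart with uncertainty bars."""
    table = result.summary.copy()
    if csv_path is not None:
        table.to_csv(csv_path, index=False, float_format="%.6g")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        labels = [f"{r.cause}\n{r.pollutant}" for r in table.itertuples()]
        pos = np.arange(len(table))
        err = np.vstack([
            np.maximum(table["ad"] - table["ad_lower"], 0.0),
            np.maximum(table["ad_upper"] - table["ad"], 0.0),
        ])
        ax.bar(pos, table["ad"], yerr=err, capsize=3, color="#4878a8")
        ax.set_xticks(pos)
        ax.set_xticklabels(labels, fontsize=8)
        ax.set_ylabel("annual attributable deaths")
        ax.set_title("Preventable deaths under AQG-compliant exposure")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return table
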