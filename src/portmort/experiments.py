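"""Replicated simulation experiments: effect recovery, coverage, type-I error.

These helpers hold the tract geometry, exposure surface and design
matrix fixed and redraw only the death counts, which is the repeated
part of a calibration experiment: the question is whether the
regression recovers the known exposure effect from fresh Poisson noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .regression import ModelSpec, build_design, fit_poisson, percent_change
from .stratify import classify_harbour
from .synth import City, simulate_deaths


def replicate_fits(city: City, cause: str, variable: str,
                   level: int, n_reps: int, seed: int,
                   increment: float = 5.0,
                   config: ScenarioConfig | None = None) -> pd.DataFrame:
    """Redraw deaths ``n_reps`` times and refit one regression cell.

    ``config`` overrides the city's scenario for the death simulator
    (e.g. a null copy with ``true_beta={}``); geometry and exposure stay
    those of ``city``.  Returns one row per replicate with the percent
    change per ``increment``, its Wald bounds and the convergence flag.
    """
    cfg = config or city.config
    stratum = classify_harbour(city.tracts, cfg.harbour_centroid,
                               cfg.harbour_radius_m)
    spec = ModelSpec(outcome_cause=cause, exposure_variable=variable,
                     adjustment_level=level, increment=increment)
    design = build_design(city.tracts, city.deaths, city.exposures,
                          stratum, spec)
    key = pd.MultiIndex.from_frame(design.index)

    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        deaths = simulate_deaths(city.tracts, city.exposures, cfg, rng=rng)
        y = (deaths[deaths["cause"] == cause]
             .set_index(["tract_id", "age_class", "sex"])["deaths"]
             .reindex(key, fill_value=0)
             .to_numpy(dtype=float))
        design.y = y
        fit = fit_poisson(design)
        if fit.converged:
            pc = percent_change(fit, variable, increment)
            rows.append({"rep": rep, "pct": pc.estimate, "lo": pc.lower,
                         "hi": pc.upper, "converged": True})
        else:
            rows.append({"rep": rep, "pct": np.nan, "lo": np.nan,
                         "hi": np.nan, "converged": False})
    return pd.DataFrame(rows)


def summarize_recovery(fits: pd.DataFrame, true_pct: float) -> dict:
    """Mean recovered effect, CI coverage of truth, and null rejections."""
    ok = fits[fits["converged"]]
    covered = ((ok["lo"] <= true_pct) & (true_pct <= ok["hi"])).mean()
    rejects = ((ok["lo"] > 0) | (ok["hi"] < 0)).mean()
    return {
        "n_converged": int(len(ok)),
        "mean_pct": float(ok["pct"].mean()),
        "sd_pct": float(ok["pct"].std(ddof=1)),
        "coverage": float(covered),
        "reject_rate": float(rejects),
    }


def null_config(config: ScenarioConfig) -> ScenarioConfig:
    """Copy of a scenario with every exposure effect switched off."""
    return config.model_copy(update={"true_beta": {}}, deep=True)
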