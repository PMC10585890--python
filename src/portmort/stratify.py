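"""Harbour-buffer stratification and descriptive summaries.

Tracts are assigned to the harbour stratum when their polygon centroid
falls within a fixed radius of the port centroid (the whole-tract rule
used throughout the analysis); an area-overlap rule and a square buffer
are available as sensitivity options.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .config import (
    AGE_CLASSES,
    CAUSES,
    POP_COLUMNS,
    SES_CATEGORIES,
    SEXES,
    stratum_column,
)
from .exposure import exposure_wide


def classify_harbour(tracts: pd.DataFrame, harbour_centroid: tuple[float, float],
                     radius_m: float, rule: str = "centroid",
                     buffer_shape: str = "circle") -> pd.DataFrame:
    """Harbour / non-harbour indicator per tract.

    rule="centroid": tract is harbour iff its centroid lies within
    ``radius_m`` of the harbour point (Euclidean for a circular buffer,
    Chebyshev for ``buffer_shape="square"``).  rule="overlap": harbour
    iff >= 50% of the tract area falls inside the buffer polygon.

    Returns a DataFrame (tract_id, distance_m, harbour) with the radius
    recorded in ``DataFrame.attrs["radius_m"]``.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    hx, hy = harbour_centroid
    cents = np.array([(g.centroid.x, g.centroid.y) for g in tracts["geometry"]])
    if buffer_shape == "circle":
        dist = np.hypot(cents[:, 0] - hx, cents[:, 1] - hy)
    elif buffer_shape == "square":
        dist = np.maximum(np.abs(cents[:, 0] - hx), np.abs(cents[:, 1] - hy))
    else:
        raise ValueError(f"unknown buffer_shape {buffer_shape!r}")

    if rule == "centroid":
        harbour = dist <= radius_m
    elif rule == "overlap":
        if buffer_shape == "circle":
            buf = Point(hx, hy).buffer(radius_m, quad_segs=64)
        else:
            from shapely.geometry import box
            buf = box(hx - radius_m, hy - radius_m, hx + radius_m, hy + radius_m)
        harbour = np.array([
            g.intersection(buf).area >= 0.5 * g.area for g in tracts["geometry"]
        ])
    else:
        raise ValueError(f"unknown rule {rule!r}")

    out = pd.DataFrame({
        "tract_id": tracts["tract_id"].to_numpy(),
        "distance_m": dist,
        "harbour": harbour,
    })
    out.attrs["radius_m"] = float(radius_m)
    return out


def sensitivity_radii(tracts: pd.DataFrame,
                      harbour_centroid: tuple[float, float],
                      radii: list[float], **kwargs) -> pd.DataFrame:
    """Harbour stratum size for several buffer radii (600/800/1000 m style).

    Returns one row per radius with tract and population counts; the
    harbour population is monotone non-decreasing in the radius.
    """
    pop = tracts[POP_COLUMNS].sum(axis=1).to_numpy()
    rows = []
    for r in radii:
        s = classify_harbour(tracts, harbour_centroid, r, **kwargs)
        mask = s["harbour"].to_numpy()
        rows.append({
            "radius_m": float(r),
            "n_tracts": int(mask.sum()),
            "population": int(pop[mask].sum()),
            "pop_share": pop[mask].sum() / pop.sum() if pop.sum() else 0.0,
        })
    return pd.DataFrame(rows)


def descriptive_table(tracts: pd.DataFrame, deaths: pd.DataFrame,
                      exposures: pd.DataFrame,
                      stratum: pd.DataFrame) -> pd.DataFrame:
    """Population, exposure and mortality summary by harbour stratum.

    One row per (block, category): total population; age-class and sex
    counts with percentages of the stratum population; deprivation
    distribution; population-weighted exposure mean and SD per
    pollutant; cause-specific death counts with deaths per 100
    residents.  Columns come in (no, yes, total) triples.
    """
    ids = set(tracts["tract_id"])
    missing = ids - set(stratum["tract_id"])
    if missing:
        raise ValueError(f"stratum table missing tracts: {sorted(missing)[:5]}")
    # death tables are sparse (zero rows omitted): absent tract = no
    # deaths, but a tract unknown to the geometry is a keying error
    unknown = set(deaths["tract_id"]) - ids
    if unknown:
        raise ValueError(f"deaths table has unknown tracts: {sorted(unknown)[:5]}")

    harb = stratum.set_index("tract_id")["harbour"]
    tr = tracts.set_index("tract_id")
    groups = {
        "no": tr.index[~harb.loc[tr.index]],
        "yes": tr.index[harb.loc[tr.index]],
        "total": tr.index,
    }
    xw = exposure_wide(exposures)
    dsum = deaths.groupby(["tract_id", "cause"])["deaths"].sum().unstack(fill_value=0)

    rows: list[dict] = []

    def add(block: str, category: str, values: dict[str, float],
            pcts: dict[str, float]) -> None:
        row = {"block": block, "category": category}
        for g in groups:
            row[f"n_{g}"] = values[g]
            row[f"pct_{g}"] = pcts.get(g, np.nan)
        rows.append(row)

    pops = {g: tr.loc[idx, POP_COLUMNS].sum().sum() for g, idx in groups.items()}
    add("population", "total", pops, {g: 100.0 for g in groups})

    for age in AGE_CLASSES:
        cols = [stratum_column(age, s) for s in SEXES]
        vals = {g: tr.loc[idx, cols].sum().sum() for g, idx in groups.items()}
        add("age_class", age, vals,
            {g: 100.0 * vals[g] / pops[g] if pops[g] else np.nan for g in groups})
    for sex in SEXES:
        cols = [stratum_column(a, sex) for a in AGE_CLASSES]
        vals = {g: tr.loc[idx, cols].sum().sum() for g, idx in groups.items()}
        add("sex", sex, vals,
            {g: 100.0 * vals[g] / pops[g] if pops[g] else np.nan for g in groups})
    tract_pop = tr[POP_COLUMNS].sum(axis=1)
    for ses in SES_CATEGORIES:
        vals = {g: tract_pop.loc[idx][tr.loc[idx, "ses_category"] == ses].sum()
                for g, idx in groups.items()}
        add("ses", ses, vals,
            {g: 100.0 * vals[g] / pops[g] if pops[g] else np.nan for g in groups})

    for pollutant in xw.columns:
        means, sds = {}, {}
        for g, idx in groups.items():
            w = tract_pop.loc[idx].to_numpy(dtype=float)
            v = xw.loc[idx, pollutant].to_numpy(dtype=float)
            if w.sum() > 0:
                m = np.average(v, weights=w)
                means[g] = m
                sds[g] = np.sqrt(np.average((v - m) ** 2, weights=w))
            else:
                means[g] = sds[g] = np.nan
        # SD reported in the percent column slot, as mean (SD) pairs
        add("exposure", pollutant, means, sds)

    for cause in CAUSES:
        if cause not in dsum.columns:
            continue
        vals = {g: dsum.loc[dsum.index.intersection(idx), cause].sum()
                for g, idx in groups.items()}
        add("mortality", cause, vals,
            {g: 100.0 * vals[g] / pops[g] if pops[g] else np.nan for g in groups})

    return pd.DataFrame(rows)


def format_descriptive_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of :func:`descriptive_table` output."""
    lines = [f"{'':<22}{'Non-harbour':>18}{'Harbour':>18}{'Total':>18}",
             "-" * 76]
    for _, r in table.iterrows():
        label = f"{r['block']}:{r['category']}"
        cells = []
        for g in ("no", "yes", "total"):
            n, p = r[f"n_{g}"], r[f"pct_{g}"]
            if r["block"] == "exposure":
                cells.append(f"{n:10.1f} ({p:4.1f})")
            else:
                cells.append(f"{n:10.0f} ({p:4.1f})" if np.isfinite(p)
                             else f"{n:10.0f}       ")
        lines.append(f"{label:<22}" + "".join(f"{c:>18}" for c in cells))
    return "\n".join(lines) + "\n"
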