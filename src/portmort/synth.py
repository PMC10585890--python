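"""Synthetic port-city generator: tracts, populations, surfaces, deaths.

The generator emulates the statistical structure the downstream analysis
assumes: an urban extent tiled by census tracts (seeded Voronoi cells,
or a regular grid for exact-answer tests), a population allocated to
tracts and 10 age-sex strata from fixed margins, pollutant surfaces that
decay exponentially from the harbour point source over a dispersion-grid
raster, and cause-specific death counts drawn from a log-linear Poisson
model with age/sex/deprivation baseline structure and known exposure
effects.  All randomness flows from the scenario seed through fixed,
stage-labelled streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .config import (
    CAUSES,
    NATURAL_COMPONENTS,
    POP_COLUMNS,
    SES_CATEGORIES,
    STRATA,
    ScenarioConfig,
    stratum_column,
)
from .exposure import ExposureGrid, assign_exposure, assign_exposures, exposure_wide

# fixed offsets so each stage draws from its own labelled stream
_STAGE_STREAMS = {"tracts": 1, "ses": 2, "population": 3, "surface": 4, "deaths": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the master seed."""
    return np.random.default_rng([seed, _STAGE_STREAMS[stage]])


@dataclass
class City:
    """A fully realised synthetic city ready for analysis."""

    config: ScenarioConfig
    tracts: pd.DataFrame
    grids: dict[str, ExposureGrid]
    exposures: pd.DataFrame  # long (tract_id, pollutant, mean, coverage)
    deaths: pd.DataFrame  # long (tract_id, cause, age_class, sex, deaths)
    expected: pd.DataFrame = field(repr=False, default=None)


# --- tract geometry ---------------------------------------------------------


def _canonical_ring(poly: Polygon) -> Polygon:
    """CCW exterior ring starting at its lexicographically smallest vertex."""
    ring = shapely.geometry.polygon.orient(poly, sign=1.0)
    coords = list(ring.exterior.coords)[:-1]
    start = min(range(len(coords)), key=lambda i: coords[i])
    coords = coords[start:] + coords[:start]
    return Polygon(coords)


def generate_tracts(config: ScenarioConfig) -> pd.DataFrame:
    """Tile the city extent with tracts and attach SES and population.

    ``voronoi`` mode tessellates around seeded uniform random points and
    clips the cells to the extent; ``grid_tracts`` mode produces an
    axis-aligned rectangular tiling (exact geometry for tests).  SES is
    sampled per tract from the configured distribution; the population
    is allocated so the harbour stratum receives the configured share.
    """
    xmin, ymin, xmax, ymax = config.city_extent
    extent = box(xmin, ymin, xmax, ymax)
    n = config.n_tracts

    if config.tract_mode == "grid_tracts":
        polys = _grid_tiling(n, xmin, ymin, xmax, ymax)
    else:
        rng = stage_rng(config.seed, "tracts")
        pts = np.column_stack([
            rng.uniform(xmin, xmax, size=n),
            rng.uniform(ymin, ymax, size=n),
        ])
        cells = voronoi_diagram(MultiPoint(pts), envelope=extent)
        tree = shapely.STRtree(list(cells.geoms))
        polys = []
        for x, y in pts:
            p = Point(x, y)
            idx = [i for i in tree.query(p) if cells.geoms[i].intersects(p)]
            if not idx:  # point on a Voronoi edge: nearest cell wins
                idx = [tree.nearest(p)]
            cell = cells.geoms[idx[0]].intersection(extent)
            polys.append(_canonical_ring(cell))

    rng_ses = stage_rng(config.seed, "ses")
    ses_p = np.array([config.ses_distribution[c] for c in SES_CATEGORIES])
    ses = [SES_CATEGORIES[i] for i in rng_ses.choice(len(SES_CATEGORIES),
                                                     size=n, p=ses_p)]
    width = len(str(n))
    tracts = pd.DataFrame({
        "tract_id": [f"T{i:0{width}d}" for i in range(1, n + 1)],
        "geometry": polys,
        "ses_category": ses,
    })
    return _allocate_population(tracts, config)


def _grid_tiling(n: int, xmin: float, ymin: float,
                 xmax: float, ymax: float) -> list[Polygon]:
    # choose the rows x cols factorisation closest to the extent aspect
    w, h = xmax - xmin, ymax - ymin
    best = None
    for nr in range(1, n + 1):
        if n % nr:
            continue
        nc = n // nr
        mismatch = abs(math.log((w / nc) / (h / nr)))
        if best is None or mismatch < best[0]:
            best = (mismatch, nr, nc)
    _, nr, nc = best
    dx, dy = w / nc, h / nr
    polys = []
    for r in range(nr):
        for c in range(nc):
            x0, y0 = xmin + c * dx, ymin + r * dy
            polys.append(Polygon([(x0, y0), (x0 + dx, y0),
                                  (x0 + dx, y0 + dy), (x0, y0 + dy)]))
    return polys


def _allocate_population(tracts: pd.DataFrame,
                         config: ScenarioConfig) -> pd.DataFrame:
    """Integer population per tract and stratum honouring all margins."""
    hx, hy = config.harbour_centroid
    cents = np.array([(p.centroid.x, p.centroid.y) for p in tracts["geometry"]])
    dist = np.hypot(cents[:, 0] - hx, cents[:, 1] - hy)
    harbour = dist <= config.harbour_radius_m
    areas = np.array([p.area for p in tracts["geometry"]])

    total = config.total_population
    if config.harbour_pop_share is None:
        tract_pop = _largest_remainder(total, areas)
    else:
        if not harbour.any():
            raise ValueError(
                "harbour_pop_share set but no tract centroid lies within "
                f"{config.harbour_radius_m} m of the harbour centroid"
            )
        n_harb = round(total * config.harbour_pop_share)
        tract_pop = np.zeros(len(tracts), dtype=int)
        tract_pop[harbour] = _largest_remainder(n_harb, areas[harbour])
        tract_pop[~harbour] = _largest_remainder(total - n_harb, areas[~harbour])

    margins = config.age_sex_margins()
    p = np.array([margins[s] for s in STRATA])
    p = p / p.sum()
    rng = stage_rng(config.seed, "population")
    strata_counts = np.vstack([
        rng.multinomial(int(np_t), p) for np_t in tract_pop
    ])
    out = tracts.copy()
    for j, (a, s) in enumerate(STRATA):
        out[stratum_column(a, s)] = strata_counts[:, j]
    return out


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic integer apportionment of ``total`` by ``weights``."""
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    q = total * weights / weights.sum()
    base = np.floor(q).astype(int)
    short = total - base.sum()
    order = np.argsort(-(q - base), kind="stable")
    base[order[:short]] += 1
    return base


def tract_population(tracts: pd.DataFrame) -> pd.Series:
    """Total residents per tract (sum over the 10 strata), tract_id index."""
    return tracts.set_index("tract_id")[POP_COLUMNS].sum(axis=1)


# --- exposure surfaces ------------------------------------------------------


def _surface_components(config: ScenarioConfig,
                        pollutant: str) -> tuple[np.ndarray, np.ndarray]:
    """(decay, noise) cell-centre fields for one pollutant.

    ``decay`` is exp(-d / decay_length); ``noise`` is a smooth Gaussian
    random field scaled to the configured marginal SD, drawn from a
    pollutant-specific labelled stream so reruns are reproducible and
    pollutants carry independent noise.
    """
    params = config.pollutants[pollutant]
    n_rows, n_cols = config.grid_shape
    xs = config.grid_origin[0] + (np.arange(n_cols) + 0.5) * config.grid_cell_size
    ys = config.grid_origin[1] + (np.arange(n_rows) + 0.5) * config.grid_cell_size
    xx, yy = np.meshgrid(xs, ys)
    d = np.hypot(xx - config.harbour_centroid[0], yy - config.harbour_centroid[1])
    decay = np.exp(-d / params.decay_length)
    if params.noise_sd > 0:
        rng = np.random.default_rng(
            [config.seed, _STAGE_STREAMS["surface"], *pollutant.encode()])
        white = rng.standard_normal((n_rows, n_cols))
        smooth = ndimage.gaussian_filter(white, params.noise_correlation_cells,
                                         mode="reflect")
        noise = params.noise_sd * smooth / smooth.std()
    else:
        noise = np.zeros((n_rows, n_cols))
    return decay, noise


def generate_exposure_surface(config: ScenarioConfig,
                              pollutant: str) -> ExposureGrid:
    """Render one pollutant's parametric surface onto the dispersion grid.

    value = background + amplitude * exp(-d / decay_length) + recentred
    smooth seeded noise, d = distance from cell centre to the harbour
    centroid; values clipped at zero.
    """
    params = config.pollutants[pollutant]
    decay, noise = _surface_components(config, pollutant)
    vals = (params.background + params.amplitude * decay + noise
            - params.noise_mean_adjust - params.noise_decay_adjust * decay)
    return ExposureGrid(pollutant=pollutant, origin=config.grid_origin,
                        cell_size=config.grid_cell_size,
                        values=np.maximum(vals, 0.0))


def calibrate_surfaces(config: ScenarioConfig,
                       tracts: pd.DataFrame) -> ScenarioConfig:
    """Fit background/amplitude so tract means hit the calibration targets.

    For each pollutant with a ``calibration_target`` the amplitude is
    found by bisection on the harbour-vs-rest gap of population-weighted
    tract means (monotone in amplitude because the zonal mean is linear
    in the grid), then the background is set so the rest-of-city mean
    matches.  The unit-amplitude decay field is assigned to tracts once
    and reused thanks to that same linearity.
    """
    targets = {p: sp.calibration_target for p, sp in config.pollutants.items()
               if sp.calibration_target is not None}
    if not targets:
        return config

    pop = tract_population(tracts).to_numpy(dtype=float)
    hx, hy = config.harbour_centroid
    cents = np.array([(g.centroid.x, g.centroid.y) for g in tracts["geometry"]])
    harbour = np.hypot(cents[:, 0] - hx, cents[:, 1] - hy) <= config.harbour_radius_m
    if not harbour.any() or harbour.all():
        raise ValueError("calibration needs both harbour and non-harbour tracts")

    def stratum_means(cell_field: np.ndarray) -> tuple[float, float]:
        # zonal means of an arbitrary-sign field via a positive shift
        # (exact by linearity of the area-weighted mean)
        shift = float(max(0.0, -cell_field.min())) + 1.0
        g = ExposureGrid(pollutant="probe", origin=config.grid_origin,
                         cell_size=config.grid_cell_size,
                         values=cell_field + shift)
        m = assign_exposure(g, tracts)["mean"].to_numpy() - shift
        return (float(np.average(m[harbour], weights=pop[harbour])),
                float(np.average(m[~harbour], weights=pop[~harbour])))

    updated = config.model_copy(deep=True)
    for pollutant, (target_h, target_r) in targets.items():
        params = config.pollutants[pollutant]
        decay, noise = _surface_components(config, pollutant)
        m_h, m_r = stratum_means(decay)
        gap = target_h - target_r
        if gap < 0 or m_h <= m_r:
            raise ValueError(f"cannot calibrate {pollutant}: non-positive gap")
        amplitude = _bisect_amplitude(gap, m_h - m_r)
        background = target_r - amplitude * m_r
        if background < 0:
            raise ValueError(
                f"calibration for {pollutant} would need negative background")
        n_adj = m_adj = 0.0
        if params.noise_sd > 0:
            # recentre the realized noise so its harbour and rest means
            # vanish: noise' = noise - (m_adj + n_adj * decay)
            n_h, n_r = stratum_means(noise)
            n_adj = (n_h - n_r) / (m_h - m_r)
            m_adj = n_r - n_adj * m_r
        new = params.model_copy(update={
            "background": background, "amplitude": amplitude,
            "noise_mean_adjust": m_adj, "noise_decay_adjust": n_adj})
        updated.pollutants[pollutant] = new
    return updated


def _bisect_amplitude(target_gap: float, slope: float,
                      tol: float = 1e-12) -> float:
    # gap(A) = A * slope is monotone increasing; bracket then bisect
    lo, hi = 0.0, 1.0
    while hi * slope < target_gap:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("amplitude bracket exploded during calibration")
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if mid * slope < target_gap:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --- death simulation -------------------------------------------------------


def expected_deaths(tracts: pd.DataFrame, exposures: pd.DataFrame,
                    config: ScenarioConfig) -> pd.DataFrame:
    """Analytic Poisson means per (tract, cause, stratum) over the window.

    mu(t, c, s) = person_years(t, s) * rate_c(s) * exp(sum_p beta_cp x_tp
    + gamma_ses(t)), with rates rescaled per cause when ``cause_totals``
    calibration targets are set.
    """
    x = exposure_wide(exposures)
    tr = tracts.set_index("tract_id")
    missing = tr.index.difference(x.index)
    if len(missing):
        raise ValueError(f"tracts missing exposure values: {list(missing)[:5]}")
    x = x.loc[tr.index]

    gamma = tr["ses_category"].map(config.ses_effects).to_numpy(dtype=float)
    records = []
    for cause in CAUSES:
        rates = config.baseline_rates.get(cause)
        if rates is None:
            continue
        betas = config.true_beta.get(cause, {})
        lin = np.zeros(len(tr))
        for pollutant, b in betas.items():
            if pollutant not in x.columns:
                raise ValueError(
                    f"true_beta references pollutant {pollutant!r} with no "
                    "assigned exposure")
            lin = lin + b * x[pollutant].to_numpy()
        rr = np.exp(lin + gamma)
        for age, sex in STRATA:
            py = tr[stratum_column(age, sex)].to_numpy(dtype=float) \
                * config.study_years
            rate = rates[age] * config.sex_rate_factors[sex]
            if rate < 0:
                raise ValueError(f"negative rate for {cause}/{age}")
            mu = py * rate * rr
            records.append(pd.DataFrame({
                "tract_id": tr.index, "cause": cause, "age_class": age,
                "sex": sex, "mu": mu,
            }))
    out = pd.concat(records, ignore_index=True)

    if config.cause_totals:
        for cause, target in config.cause_totals.items():
            mask = out["cause"] == cause
            current = out.loc[mask, "mu"].sum()
            if current <= 0:
                raise ValueError(
                    f"cannot calibrate {cause}: zero expected deaths")
            out.loc[mask, "mu"] *= target / current
    return out


def simulate_deaths(tracts: pd.DataFrame, exposures: pd.DataFrame,
                    config: ScenarioConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a cause-specific death table consistent with the cause hierarchy.

    Cardiovascular, respiratory, cancer and a residual "other natural"
    component are drawn as independent Poissons whose means sum to the
    natural mean, so natural = their sum is Poisson with the intended
    mean and sub-causes can never exceed it; lung cancer is a binomial
    thinning of the cancer draw.  Configs whose effects would force a
    negative residual mean or a thinning probability above one are
    rejected with an explanatory error.
    """
    if rng is None:
        rng = stage_rng(config.seed, "deaths")
    mu = expected_deaths(tracts, exposures, config)
    wide = mu.pivot_table(index=["tract_id", "age_class", "sex"],
                          columns="cause", values="mu", fill_value=0.0)
    for cause in CAUSES:
        if cause not in wide.columns:
            wide[cause] = 0.0
    mu_other = wide["natural"] - wide[NATURAL_COMPONENTS].sum(axis=1)
    if (mu_other < -1e-9).any():
        worst = mu_other.idxmin()
        raise ValueError(
            "sub-cause means exceed the natural mean (extreme exposure "
            f"effects); worst cell {worst}: residual {mu_other.min():.3g}"
        )
    mu_other = mu_other.clip(lower=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_lung = np.where(wide["cancer"] > 0,
                          wide["lung_cancer"] / wide["cancer"], 0.0)
    if (p_lung > 1 + 1e-9).any():
        raise ValueError("lung-cancer mean exceeds cancer mean in some cell")
    p_lung = np.clip(p_lung, 0.0, 1.0)

    draws = {c: rng.poisson(wide[c].to_numpy())
             for c in NATURAL_COMPONENTS}
    other = rng.poisson(mu_other.to_numpy())
    draws["natural"] = sum(draws[c] for c in NATURAL_COMPONENTS) + other
    draws["lung_cancer"] = rng.binomial(draws["cancer"], p_lung)

    idx = wide.index.to_frame(index=False)
    frames = []
    for cause in CAUSES:
        f = idx.copy()
        f["cause"] = cause
        f["deaths"] = draws[cause]
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    return out[["tract_id", "cause", "age_class", "sex", "deaths"]]


# --- orchestration ----------------------------------------------------------


def generate_city(config: ScenarioConfig) -> City:
    """Run the full generator: tracts -> calibrated surfaces -> deaths."""
    tracts = generate_tracts(config)
    config = calibrate_surfaces(config, tracts)
    grids = {p: generate_exposure_surface(config, p) for p in config.pollutants}
    exposures = assign_exposures(grids, tracts)
    expected = expected_deaths(tracts, exposures, config)
    deaths = simulate_deaths(tracts, exposures, config)
    return City(config=config, tracts=tracts, grids=grids,
                exposures=exposures, deaths=deaths, expected=expected)
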