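"""Community and range-shift metrics derived from projection cubes.

Covers expected species richness, relative dominance, the four geographic
range indicators (range, biomass, core range via the present-day 90th biomass
quantile, core biomass), linear rates of change, centroid shifts, raster
fragmentation, trait regressions with backward selection, and the signed-rank
test for community-wide shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage
from scipy.spatial.distance import cdist
from scipy.stats import wilcoxon

from .projection import ProjectionCube

logger = logging.getLogger(__name__)

EIGHT_CONN = np.ones((3, 3), dtype=int)


def richness_map(cube: ProjectionCube) -> np.ndarray:
    """Expected species richness per cell x period: sum of occurrence
    probabilities over species, without thresholding."""
    p = cube.occurrence_probability
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    return p.sum(axis=0)


def dominance_map(cube: ProjectionCube) -> tuple[np.ndarray, np.ndarray]:
    """Relative dominance per cell x period.

    Returns (dominance_pct, dominant_index): 100 * max_s b_s / sum_s b_s and
    the argmax species index (ties resolved by species-identifier order,
    logged). Cells with zero total biomass get NaN / -1.
    """
    b = cube.combined_log_cpue
    if b is None:
        raise ValueError("cube has no combined biomass layer")
    if np.any(b < 0):
        raise ValueError("thresholded biomass must be non-negative")
    tot = b.sum(axis=0)
    mx = b.max(axis=0)
    # argmax takes the first maximum: species-identifier order by construction
    arg = b.argmax(axis=0)
    ties = (b == mx[None, :, :]).sum(axis=0) > 1
    if (ties & (tot > 0)).any():
        logger.info("dominance_map: %d cells had tied dominant species", int(ties.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(tot > 0, 100.0 * mx / tot, np.nan)
    arg = np.where(tot > 0, arg, -1)
    return pct, arg


def dominance_area_share(dominant: np.ndarray, cube: ProjectionCube) -> pd.DataFrame:
    """Percent of the study area dominated by each species, per period.

    Area-weighted over cells with a defined dominant; shares sum to 100 per
    period wherever any cell is non-missing.
    """
    areas = cube.grid.cell_area
    out = {}
    for k, period in enumerate(cube.periods):
        dom = dominant[:, k]
        ok = dom >= 0
        total = areas[ok].sum()
        shares = np.zeros(len(cube.species))
        if total > 0:
            for i in range(len(cube.species)):
                shares[i] = 100.0 * areas[ok & (dom == i)].sum() / total
        out[period] = shares
    return pd.DataFrame(out, index=cube.species)


def range_and_core(cube: ProjectionCube, present_period: str = "present") -> pd.DataFrame:
    """The four range indicators per species x period.

    range_km2 — summed area of presence cells; biomass_total — summed
    thresholded log CPUE; core cells — biomass at or above the species'
    present-day 90th percentile (linear interpolation) of positive biomass;
    core_biomass — biomass summed over core cells. Species with an empty
    present-day range get missing core metrics.
    """
    if cube.presence is None or cube.combined_log_cpue is None:
        raise ValueError("cube needs presence and combined biomass layers")
    if present_period not in cube.periods:
        raise ValueError(f"present period '{present_period}' not in cube")
    areas = cube.grid.cell_area
    kp = cube.period_index(present_period)
    rows = []
    for i, sp in enumerate(cube.species):
        b_pres = cube.combined_log_cpue[i, :, kp]
        pos = b_pres[b_pres > 0]
        q90 = np.percentile(pos, 90) if pos.size else np.nan
        for k, period in enumerate(cube.periods):
            pres = cube.presence[i, :, k]
            b = cube.combined_log_cpue[i, :, k]
            # core cells are kept within the binarised range so that the
            # core range can never exceed the range itself
            core = (b >= q90) & pres if np.isfinite(q90) else np.zeros_like(b, dtype=bool)
            rows.append(
                {
                    "species": sp,
                    "period": period,
                    "range_km2": float(areas[pres].sum()),
                    "biomass_total": float(b.sum()),
                    "core_range_km2": float(areas[core].sum()) if np.isfinite(q90) else np.nan,
                    "core_biomass": float(b[core].sum()) if np.isfinite(q90) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def rate_of_change(values: np.ndarray, years: np.ndarray) -> tuple[float, float]:
    """OLS slope per year plus percentage rate relative to the present value.

    The present is the earliest year (anchored at 2010 in a standard run);
    a zero present value leaves the percentage missing.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 2:
        raise ValueError("need at least 2 periods")
    slope = np.polyfit(years[ok], values[ok], 1)[0]
    present = values[ok][np.argmin(years[ok])]
    pct = slope / present * 100.0 if present != 0 else np.nan
    return float(slope), float(pct)


def centroid_shift(
    cube: ProjectionCube, weighted: bool = False, scenario: str | None = None
) -> pd.DataFrame:
    """Range centroids per species x period with northward/eastward km/yr rates.

    Centroid = area-weighted mean of the equal-area (x, y) coordinates over
    presence cells, or biomass-weighted with weighted=True. Rates are OLS
    slopes of the centroid coordinates against period year (requires >= 2
    non-missing periods); empty ranges leave that period's centroid missing.
    """
    if cube.presence is None:
        raise ValueError("cube needs a presence layer")
    grid = cube.grid
    periods = cube.periods if scenario is None else [
        p for p in cube.periods if p == "present" or p.startswith(scenario)
    ]
    years = np.array([_period_year(p) for p in periods], dtype=float)
    rows = []
    for i, sp in enumerate(cube.species):
        cx = np.full(len(periods), np.nan)
        cy = np.full(len(periods), np.nan)
        for k, period in enumerate(periods):
            kk = cube.period_index(period)
            pres = cube.presence[i, :, kk]
            if not pres.any():
                continue
            if weighted:
                if cube.combined_log_cpue is None:
                    raise ValueError("biomass-weighted centroid needs combined biomass")
                w = cube.combined_log_cpue[i, :, kk] * grid.cell_area
                w = np.where(pres, np.clip(w, 0, None), 0.0)
            else:
                w = np.where(pres, grid.cell_area, 0.0)
            if w.sum() == 0:
                continue
            cx[k] = np.average(grid.x, weights=w)
            cy[k] = np.average(grid.y, weights=w)
        ok = np.isfinite(cx)
        north = east = np.nan
        if ok.sum() >= 2:
            east, _ = rate_of_change(cx[ok], years[ok])
            north, _ = rate_of_change(cy[ok], years[ok])
        for k, period in enumerate(periods):
            rows.append(
                {
                    "species": sp,
                    "period": period,
                    "centroid_x_km": cx[k],
                    "centroid_y_km": cy[k],
                    "north_km_per_yr": north,
                    "east_km_per_yr": east,
                }
            )
    return pd.DataFrame(rows)


def _period_year(period: str) -> int:
    if period == "present":
        return 2010
    if ":" in period:
        return int(period.split(":")[1])
    return int(period.split("-")[0])


@dataclass
class FragmentationResult:
    n_polygons: int
    mean_polygon_area_km2: float
    mean_interpolygon_distance_km: float


def fragmentation(presence: np.ndarray, grid) -> FragmentationResult:
    """Raster fragmentation of one species/period presence layer.

    Polygons are 8-connected components of presence cells; the inter-polygon
    distance is the minimum cell-centre distance between a component pair,
    averaged over all unordered pairs. A single component leaves the distance
    missing; an empty range leaves both area and distance missing.
    """
    pres = np.asarray(presence, dtype=bool)
    raster = grid.raster(pres)
    labels, n = ndimage.label(raster, structure=EIGHT_CONN)
    if n == 0:
        return FragmentationResult(0, np.nan, np.nan)
    flat = labels.ravel()
    areas = np.array([grid.cell_area[flat == c].sum() for c in range(1, n + 1)])
    if n == 1:
        return FragmentationResult(1, float(areas.mean()), np.nan)
    coords = [grid.coords_km[flat == c] for c in range(1, n + 1)]
    dists = []
    for a in range(n):
        for b in range(a + 1, n):
            dists.append(cdist(coords[a], coords[b]).min())
    return FragmentationResult(int(n), float(areas.mean()), float(np.mean(dists)))


def trait_effects(
    rates: pd.Series, traits: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Backward-selection multiple regression of a per-species rate on traits.

    Starts from the full linear model; iteratively drops the least significant
    term (categorical traits enter and leave as a dummy block, tested with a
    block F-test) until every remaining term has p < alpha. Returns the final
    coefficient table (term, coefficient, p-value); empty if nothing survives.
    """
    common = rates.index.intersection(traits.index)
    y = rates.loc[common].to_numpy(float)
    traits = traits.loc[common]

    blocks: dict[str, pd.DataFrame] = {}
    for c in traits.columns:
        col = traits[c]
        if col.dtype.kind in "if":
            v = col.to_numpy(float)
            if c == "fecundity":
                v = np.log(v)
            blocks[c] = pd.DataFrame({c: v}, index=common)
        else:
            levels = sorted(col.unique())
            if len(levels) < 2:
                continue
            dummies = pd.DataFrame(
                {f"{c}[{lev}]": (col == lev).astype(float) for lev in levels[1:]},
                index=common,
            )
            blocks[c] = dummies

    active = list(blocks)
    while active:
        X = pd.concat([blocks[b] for b in active], axis=1)
        X = sm.add_constant(X)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValueError(
                f"rank-deficient trait design; aliased terms among {list(X.columns)}"
            )
        fit = sm.OLS(y, X).fit()
        pvals = {}
        for b in active:
            cols = list(blocks[b].columns)
            if len(cols) == 1:
                pvals[b] = float(fit.pvalues[cols[0]])
            else:
                R = np.zeros((len(cols), X.shape[1]))
                for r, cname in enumerate(cols):
                    R[r, list(X.columns).index(cname)] = 1.0
                pvals[b] = float(fit.f_test(R).pvalue)
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            rows = []
            for b in active:
                for cname in blocks[b].columns:
                    rows.append(
                        {
                            "term": cname,
                            "coef": float(fit.params[cname]),
                            "pvalue": float(fit.pvalues[cname]),
                            "block": b,
                            "block_pvalue": pvals[b],
                        }
                    )
            return pd.DataFrame(rows)
        active.remove(worst)
    return pd.DataFrame(columns=["term", "coef", "pvalue", "block", "block_pvalue"])


def shift_test(values: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value against a zero median.

    Exact enumeration for n <= 25 without ties; normal approximation with tie
    correction otherwise. All-zero input leaves the p-value missing.
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    if v.size == 0:
        return np.nan
    abs_ties = len(np.unique(np.abs(v))) < v.size
    method = "exact" if (v.size <= 25 and not abs_ties) else "approx"
    return float(wilcoxon(v, alternative="two-sided", method=method).pvalue)
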