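"""Scenario projection: occurrence probability and hurdle biomass per grid
cell and period, the detectability zero-threshold, and presence binarisation.

Projections use the fixed (environmental) effects only; the spatial random
effect estimated during fitting is excluded, since estimated spatial
structure cannot be assumed to persist under future climates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .model import HurdleJSDMResults
from .synthetic import EnvStack

logger = logging.getLogger(__name__)


@dataclass
class ProjectionCube:
    """species x cell x period stack of projected quantities.

    occurrence_probability in [0, 1]; combined biomass on the log-CPUE scale
    (occurrence probability times Gaussian-submodel log-CPUE prediction,
    zeroed below the detectability threshold); presence from the per-species
    max-TSS thresholds.
    """

    species: list[str]
    grid: object
    periods: list[str]
    occurrence_probability: np.ndarray  # (S, n_cells, n_periods)
    combined_log_cpue: np.ndarray | None = None
    presence: np.ndarray | None = None
    thresholds: pd.Series | None = None

    def period_index(self, period: str) -> int:
        return self.periods.index(period)

    def sel(self, field: str, species: str, period: str) -> np.ndarray:
        arr = getattr(self, field)
        return arr[self.species.index(species), :, self.period_index(period)]


def _design_per_period(results: HurdleJSDMResults, env: EnvStack) -> dict[str, np.ndarray]:
    design = results.model.design
    needed = {t.base for t in design.terms if t.degree > 0}
    missing = needed - set(env.covariates)
    if missing:
        raise KeyError(f"covariates missing from the environment stack: {sorted(missing)}")
    return {
        period: design.transform(env.table(period)).to_numpy(float)
        for period in env.periods
    }


def project_occurrence(
    results: HurdleJSDMResults, env: EnvStack, include_spatial: bool = False
) -> ProjectionCube:
    """Posterior-mean occurrence probability per species x cell x period.

    With include_spatial=False (default and the only supported mode for new
    grids) the output is invariant to the latent-factor draws.
    """
    if include_spatial:
        raise NotImplementedError("projections exclude the spatial random effect")
    Xp = _design_per_period(results, env)
    S = len(results.species)
    out = np.zeros((S, env.grid.n_cells, len(env.periods)))
    beta = results.occurrence.flat("beta")  # (D, p, S)
    for k, period in enumerate(env.periods):
        eta = np.einsum("np,dps->dns", Xp[period], beta)
        out[:, :, k] = ndtr(eta).mean(axis=0).T
    return ProjectionCube(
        species=list(results.species),
        grid=env.grid,
        periods=list(env.periods),
        occurrence_probability=out,
    )


def project_biomass(
    results: HurdleJSDMResults,
    env: EnvStack,
    combine: str = "log_product",
) -> ProjectionCube:
    """Hurdle combination: occurrence probability times the Gaussian-submodel
    log-CPUE prediction, computed per posterior draw and averaged.

    `combine="expected_cpue"` instead returns p * exp(g + sigma^2 / 2), the
    arithmetic-scale expected CPUE (non-default alternative).
    """
    if results.biomass is None:
        raise ValueError("biomass submodel was not fitted")
    if combine not in ("log_product", "expected_cpue"):
        raise ValueError(f"unknown combine rule '{combine}'")
    Xp = _design_per_period(results, env)
    S = len(results.species)
    cube = np.zeros((S, env.grid.n_cells, len(env.periods)))
    occ = np.zeros_like(cube)
    beta_o = results.occurrence.flat("beta")
    beta_b = results.biomass.flat("beta")
    D = min(beta_o.shape[0], beta_b.shape[0])  # pair draws by index
    sigma = results.biomass.flat("sigma")[:D]  # (D, S)
    n_neg = 0
    for k, period in enumerate(env.periods):
        X = Xp[period]
        eta_o = np.einsum("np,dps->dns", X, beta_o[:D])
        g = np.einsum("np,dps->dns", X, beta_b[:D])
        p = ndtr(eta_o)
        if combine == "log_product":
            comb = p * g
        else:
            comb = p * np.exp(g + 0.5 * sigma[:, None, :] ** 2)
        n_neg += int((g.mean(axis=0) < 0).sum())
        cube[:, :, k] = comb.mean(axis=0).T
        occ[:, :, k] = p.mean(axis=0).T
    if n_neg:
        logger.info("project_biomass: %d cell/species Gaussian predictions are negative "
                    "(log scale admits this); retained", n_neg)
    return ProjectionCube(
        species=list(results.species),
        grid=env.grid,
        periods=list(env.periods),
        occurrence_probability=occ,
        combined_log_cpue=cube,
    )


def apply_zero_threshold(cube: ProjectionCube, survey: pd.DataFrame) -> ProjectionCube:
    """Zero out combined biomass below each species' detectability threshold.

    The threshold is the minimum positive recorded CPUE of the species in the
    (filtered) survey, divided by 2; values strictly below it become 0, values
    equal to it are retained.
    """
    if cube.combined_log_cpue is None:
        raise ValueError("cube has no combined biomass layer")
    pos = survey[survey["cpue"] > 0]
    mins = pos.groupby("species")["cpue"].min()
    missing = set(cube.species) - set(mins.index)
    if missing:
        raise KeyError(f"species absent from survey: {sorted(missing)}")
    out = cube.combined_log_cpue.copy()
    for i, sp in enumerate(cube.species):
        thr = mins[sp] / 2.0
        out[i][out[i] < thr] = 0.0
    return ProjectionCube(
        species=cube.species,
        grid=cube.grid,
        periods=cube.periods,
        occurrence_probability=cube.occurrence_probability,
        combined_log_cpue=out,
        presence=cube.presence,
        thresholds=cube.thresholds,
    )


def binarize(cube: ProjectionCube, thresholds: pd.Series) -> ProjectionCube:
    """Presence = occurrence probability >= the species' max-TSS threshold."""
    missing = set(cube.species) - set(thresholds.index)
    if missing:
        raise KeyError(f"thresholds missing for species: {sorted(missing)}")
    pres = np.zeros_like(cube.occurrence_probability, dtype=bool)
    for i, sp in enumerate(cube.species):
        pres[i] = cube.occurrence_probability[i] >= thresholds[sp]
    return ProjectionCube(
        species=cube.species,
        grid=cube.grid,
        periods=cube.periods,
        occurrence_probability=cube.occurrence_probability,
        combined_log_cpue=cube.combined_log_cpue,
        presence=pres,
        thresholds=thresholds.loc[cube.species],
    )


def project_cube(
    results: HurdleJSDMResults,
    env: EnvStack,
    survey: pd.DataFrame,
    thresholds: pd.Series,
) -> ProjectionCube:
    """Full projection pipeline: hurdle biomass, zero threshold, binarisation."""
    cube = project_biomass(results, env)
    cube = apply_zero_threshold(cube, survey)
    return binarize(cube, thresholds)
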