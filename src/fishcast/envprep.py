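"""Survey and covariate preparation: collinearity screening, design matrices,
environmental extraction at haul locations, and record filters.

The preparation steps mirror standard shelf-survey practice: covariates with
variance inflation factor (VIF) at or above 4 are dropped iteratively, depth
and bottom temperature enter with quadratic (bell-shaped) response terms,
covariates are matched to hauls on survey month (sea ice on the annual mean),
and hauls deeper than 500 m plus species seen in fewer than 100 hauls or
fewer than 10 years are removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_QUADRATIC = ("depth", "bottom_temperature")


@dataclass(frozen=True)
class Term:
    """One design-matrix column: name, the covariate it derives from, degree."""

    name: str
    base: str
    degree: int  # 0 = intercept, 1 = linear, 2 = squared


@dataclass
class ModelDesign:
    """Haul x term design matrix with frozen standardization constants.

    Linear terms are standardized to mean 0, SD 1 on the fitting data; squared
    terms are squares of the standardized values. The constants are stored so
    that projection grids are transformed identically to the fitting data.
    `species_masks` marks, per species, which terms enter that species' model
    (used to exclude sea ice for strictly temperate species).
    """

    X: pd.DataFrame  # index = haul_id, columns = term names
    terms: list[Term]
    means: dict[str, float]
    sds: dict[str, float]
    species_masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def term_mask(self, species: str) -> np.ndarray:
        """Boolean inclusion mask over terms for one species (default: all)."""
        if species in self.species_masks:
            return self.species_masks[species]
        return np.ones(self.n_terms, dtype=bool)

    def transform(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored standardization to a new covariate table."""
        cols = {}
        for t in self.terms:
            if t.degree == 0:
                cols[t.name] = np.ones(len(covariates))
            else:
                if t.base not in covariates.columns:
                    raise KeyError(f"covariate '{t.base}' missing from input table")
                z = (covariates[t.base].to_numpy(float) - self.means[t.base]) / self.sds[t.base]
                cols[t.name] = z if t.degree == 1 else z**2
        return pd.DataFrame(cols, index=covariates.index)

    def subset(self, haul_ids) -> "ModelDesign":
        """Row subset sharing the stored constants (used for cross-validation)."""
        return ModelDesign(
            X=self.X.loc[haul_ids],
            terms=self.terms,
            means=self.means,
            sds=self.sds,
            species_masks=self.species_masks,
        )


def vif_screen(
    covariates: pd.DataFrame, threshold: float = 4.0
) -> tuple[list[str], pd.Series]:
    """Iteratively remove the highest-VIF covariate until all VIFs < threshold.

    Constant columns are flagged and removed first (their VIF is undefined).
    Ties are broken by removing the column appearing later in the input order.

    Returns
    -------
    (retained, vifs) : retained column names in input order and their final
        VIF values.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least 2 covariates")
    if covariates.shape[0] <= covariates.shape[1]:
        raise ValueError("need more rows than covariates")

    cols = list(covariates.columns)
    for c in list(cols):
        if np.isclose(covariates[c].std(ddof=0), 0.0):
            warnings.warn(f"constant covariate '{c}' removed before VIF screening")
            logger.info("vif_screen: removed constant column %s", c)
            cols.remove(c)

    def _vifs(names: list[str]) -> np.ndarray:
        Z = covariates[names].to_numpy(float)
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=0)
        out = np.empty(len(names))
        for j in range(len(names)):
            others = np.delete(Z, j, axis=1)
            A = np.column_stack([np.ones(len(Z)), others])
            coef, *_ = np.linalg.lstsq(A, Z[:, j], rcond=None)
            resid = Z[:, j] - A @ coef
            r2 = 1.0 - resid @ resid / (Z[:, j] @ Z[:, j])
            out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    while len(cols) >= 2:
        v = _vifs(cols)
        if np.nanmax(v) < threshold:
            break
        # later column wins the tie-break, so take the last argmax
        worst = len(v) - 1 - int(np.argmax(v[::-1]))
        logger.info("vif_screen: removed %s (VIF=%.3g)", cols[worst], v[worst])
        cols.pop(worst)

    final = pd.Series(_vifs(cols), index=cols) if len(cols) >= 2 else pd.Series(1.0, index=cols)
    return cols, final


def build_design(
    covariates: pd.DataFrame,
    quadratic_for: tuple[str, ...] = DEFAULT_QUADRATIC,
    species_flags: dict[str, list[str]] | None = None,
) -> ModelDesign:
    """Build the standardized design matrix with intercept and quadratic terms.

    Parameters
    ----------
    covariates : haul x covariate table (index = haul_id) of retained covariates
    quadratic_for : covariates receiving an additional squared term
    species_flags : optional map species -> covariates excluded for that species
        (e.g. sea ice for strictly temperate species)
    """
    unknown = set(quadratic_for) - set(covariates.columns)
    if unknown:
        raise ValueError(f"quadratic_for names not in covariates: {sorted(unknown)}")

    terms: list[Term] = [Term("intercept", "intercept", 0)]
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for c in covariates.columns:
        m = float(covariates[c].mean())
        s = float(covariates[c].std(ddof=0))
        if np.isclose(s, 0.0):
            raise ValueError(f"covariate '{c}' is constant; screen it out first")
        means[c], sds[c] = m, s
        terms.append(Term(c, c, 1))
    for c in quadratic_for:
        terms.append(Term(f"{c}^2", c, 2))

    design = ModelDesign(X=pd.DataFrame(), terms=terms, means=means, sds=sds)
    design.X = design.transform(covariates)

    if species_flags:
        for sp, excluded in species_flags.items():
            mask = np.array([t.base not in set(excluded) for t in terms])
            design.species_masks[sp] = mask
    return design


def extract_at_hauls(survey: pd.DataFrame, env) -> pd.DataFrame:
    """Match environmental covariates to hauls.

    All covariates are taken from the monthly period of the haul's survey
    month; sea ice concentration is replaced by the annual mean over that
    haul's year. Hauls falling outside the grid are dropped (count logged).

    Parameters
    ----------
    survey : SurveyTable records (haul_id, lon, lat, year, month, ...)
    env : EnvStack with monthly periods labelled "YYYY-MM"

    Returns
    -------
    haul x covariate DataFrame indexed by haul_id.
    """
    hauls = survey.drop_duplicates("haul_id").set_index("haul_id")
    cells = env.grid.cell_at(hauls["lon"].to_numpy(), hauls["lat"].to_numpy())
    off = cells < 0
    if off.any():
        logger.warning("extract_at_hauls: dropped %d hauls outside the grid", int(off.sum()))
    hauls = hauls.loc[~off]
    cells = cells[~off]

    rows = []
    for (hid, h), cell in zip(hauls.iterrows(), cells):
        label = f"{int(h['year'])}-{int(h['month']):02d}"
        vals = env.values_at(label, int(cell)).copy()
        if "ice_concentration" in vals:
            vals["ice_concentration"] = env.annual_mean(
                int(h["year"]), "ice_concentration", int(cell)
            )
        rows.append(pd.Series(vals, name=hid))
    return pd.DataFrame(rows)


def filter_records(
    survey: pd.DataFrame,
    max_depth: float = 500.0,
    min_hauls: int = 100,
    min_years: int = 10,
) -> pd.DataFrame:
    """Apply the haul-depth and species-rarity filters.

    Hauls deeper than ``max_depth`` are removed first; then species recorded
    (cpue > 0) in fewer than ``min_hauls`` hauls or fewer than ``min_years``
    distinct years are removed entirely (strict "less than" rules). Idempotent.
    """
    if "depth" not in survey.columns:
        raise ValueError("filter_records requires a per-haul 'depth' column")
    out = survey[survey["depth"] <= max_depth]
    pos = out[out["cpue"] > 0]
    n_hauls = pos.groupby("species")["haul_id"].nunique()
    n_years = pos.groupby("species")["year"].nunique()
    keep = n_hauls.index[(n_hauls >= min_hauls) & (n_years.reindex(n_hauls.index) >= min_years)]
    out = out[out["species"].isin(keep)]
    if out.empty:
        raise ValueError("filter_records: no records remain after filtering")
    logger.info(
        "filter_records: %d -> %d rows, %d -> %d species",
        len(survey), len(out), survey["species"].nunique(), out["species"].nunique(),
    )
    return out.reset_index(drop=True)
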