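"""Model evaluation: discrimination, calibration, cross-validation, variance
partitioning, presence thresholds, and environmental-extrapolation mapping."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import HurdleJSDM, HurdleJSDMResults, McmcConfig

logger = logging.getLogger(__name__)

MESS_SENTINEL = -1e6  # stands in for -inf when a training covariate has zero range


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties share ranks."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def r2_biomass(obs: np.ndarray, pred: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted log CPUE.

    Sign-blind by construction: pred = -obs scores 1.0.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size < 3:
        raise ValueError("need at least 3 positive records")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("R^2 undefined: zero variance")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r**2)


def max_tss_threshold(labels: np.ndarray, probs: np.ndarray) -> float:
    """Probability threshold maximising the True Skill Statistic.

    TSS(t) = sensitivity(t) + specificity(t) - 1 with presence predicted as
    prob >= t, evaluated at every distinct predicted probability; ties are
    broken towards the smallest maximising threshold.
    """
    labels = np.asarray(labels).astype(bool)
    probs = np.asarray(probs, dtype=float)
    if labels.all() or (~labels).all():
        raise ValueError("threshold undefined: both classes must be present")
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_t, best_tss = None, -np.inf
    for t in np.sort(np.unique(probs)):
        pred = probs >= t
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_t = tss, t
    return float(best_t)


def mess(train: pd.DataFrame, points: pd.DataFrame) -> np.ndarray:
    """Multivariate environmental similarity surface.

    Per covariate, with f the percentage of training values strictly below
    the point value:

    * f = 0   -> 100 (p - min) / (max - min)
    * 0<f<=50 -> 2 f
    * 50<=f<100 -> 2 (100 - f)
    * f = 100 -> 100 (max - p) / (max - min)

    The cell value is the minimum over covariates; negative values flag
    extrapolation beyond the training range. A zero-range training covariate
    contributes 0 at its value and a large negative sentinel elsewhere.
    """
    if set(train.columns) != set(points.columns):
        raise ValueError("train and points must share the same covariates")
    points = points[train.columns]
    out = np.full((len(points), train.shape[1]), np.inf)
    n = len(train)
    for k, c in enumerate(train.columns):
        tv = np.sort(train[c].to_numpy(float))
        lo, hi = tv[0], tv[-1]
        rng = hi - lo
        p = points[c].to_numpy(float)
        if rng == 0:
            out[:, k] = np.where(p == lo, 0.0, MESS_SENTINEL)
            continue
        below = np.searchsorted(tv, p, side="left")
        f = 100.0 * below / n
        sim = np.empty_like(p)
        m0 = f <= 0
        m100 = f >= 100
        mlow = (~m0) & (f <= 50)
        mhigh = (~m100) & (f > 50)
        sim[m0] = 100.0 * (p[m0] - lo) / rng
        sim[m100] = 100.0 * (hi - p[m100]) / rng
        sim[mlow] = 2.0 * f[mlow]
        sim[mhigh] = 2.0 * (100.0 - f[mhigh])
        out[:, k] = sim
    return out.min(axis=1)


def variance_partition(
    results: HurdleJSDMResults,
    groups: dict[str, str],
    submodel: str = "occurrence",
) -> pd.DataFrame:
    """Per-species explained-variance fractions of the latent predictor.

    Each design term must map (via its base covariate) to a group; quadratic
    terms share their base covariate's group. Per posterior draw and species,
    the variance over fitting hauls of each group's partial predictor
    X_g beta_g — plus the spatial random effect — is normalised by the total,
    so fractions are non-negative and sum to 1.
    """
    model = results.model
    post = results.posteriors[submodel]
    terms = model.design.terms
    bases = sorted({t.base for t in terms if t.degree > 0})
    unmapped = [b for b in bases if b not in groups]
    if unmapped:
        raise KeyError(f"covariates missing from the group map: {unmapped}")
    group_names = sorted(set(groups[b] for b in bases))
    term_group = np.array(
        [group_names.index(groups[t.base]) if t.degree > 0 else -1 for t in terms]
    )

    beta = post.flat("beta")  # (D, p, S)
    X = model.X
    D, p, S = beta.shape
    has_spatial = model.n_factors > 0
    cols = group_names + (["spatial"] if has_spatial else [])
    acc = np.zeros((S, len(cols)))
    spatial = None
    if has_spatial:
        from .model import _site_interpolators

        spatial = _site_interpolators(model, post)  # (D, n, S)
    for d in range(D):
        parts = np.zeros((len(cols), S))
        for g in range(len(group_names)):
            sel = term_group == g
            if sel.any():
                fg = X[:, sel] @ beta[d][sel, :]
                parts[g] = fg.var(axis=0)
        if has_spatial:
            parts[-1] = spatial[d].var(axis=0)
        tot = parts.sum(axis=0)
        tot[tot == 0] = 1.0
        acc += (parts / tot).T
    frac = acc / D
    return pd.DataFrame(frac, index=model.species, columns=cols)


@dataclass
class FitReport:
    """Explanatory and cross-validated performance per species."""

    explanatory: pd.DataFrame  # columns: auc, r2
    cv: pd.DataFrame | None = None  # columns: cv_auc, cv_r2 (+ per-fold)
    thresholds: pd.Series | None = None  # per-species max-TSS threshold
    retained: list[str] | None = None  # species with mean CV-R^2 > 0.05


def explanatory_fit(results: HurdleJSDMResults) -> FitReport:
    """In-sample AUC (occurrence) and R^2 (biomass) per species, plus the
    per-species max-TSS binarisation threshold."""
    model = results.model
    prob = results.fitted_occurrence_prob(include_spatial=model.n_factors > 0)
    rows = {}
    thresholds = {}
    pred_bio = (
        results.fitted_biomass_mean(include_spatial=model.n_factors > 0)
        if results.biomass is not None
        else None
    )
    for j, sp in enumerate(model.species):
        y = model.Y_occ[:, j]
        a = auc(y, prob[:, j]) if 0 < y.mean() < 1 else np.nan
        thresholds[sp] = (
            max_tss_threshold(y, prob[:, j]) if 0 < y.mean() < 1 else np.nan
        )
        r2 = np.nan
        if pred_bio is not None:
            obs_mask = ~np.isnan(model.Y_bio[:, j])
            if obs_mask.sum() >= 3:
                try:
                    r2 = r2_biomass(model.Y_bio[obs_mask, j], pred_bio[obs_mask, j])
                except ValueError:
                    pass
        rows[sp] = {"auc": a, "r2": r2}
    return FitReport(
        explanatory=pd.DataFrame(rows).T,
        thresholds=pd.Series(thresholds),
    )


def kfold_cv(
    survey: pd.DataFrame,
    design,
    tree,
    traits,
    knots=None,
    cfg: McmcConfig = McmcConfig(),
    k: int = 5,
    seed: int = 0,
    retain_above: float = 0.05,
    **model_kwargs,
) -> FitReport:
    """Five-fold (by default) cross-validation over hauls.

    Hauls are partitioned at random into k folds; the model is refitted on
    each training split and scored on the withheld hauls with fixed effects
    only (projection rule). Species are retained for biomass analyses iff
    their mean CV-R^2 strictly exceeds `retain_above`. Folds where a species
    has a single class (AUC) or degenerate positives (R^2) are skipped with a
    log entry.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    hauls = np.sort(survey["haul_id"].unique())
    perm = rng.permutation(len(hauls))
    folds = np.array_split(perm, k)
    species = sorted(survey["species"].unique())
    aucs = {sp: [] for sp in species}
    r2s = {sp: [] for sp in species}

    for fi, test_idx in enumerate(folds):
        test_hauls = set(hauls[test_idx])
        train = survey[~survey["haul_id"].isin(test_hauls)]
        test = survey[survey["haul_id"].isin(test_hauls)]
        model = HurdleJSDM(
            train, design.subset(np.sort(train["haul_id"].unique())), tree, traits,
            knots=knots, **model_kwargs,
        )
        res = model.fit(cfg)
        test_wide = test.pivot_table(index="haul_id", columns="species", values="cpue")
        test_wide = test_wide[model.species]
        Xt = design.X.loc[test_wide.index].to_numpy(float)
        prob = res.predict_occurrence_prob(Xt)
        pred_bio = res.predict_linear(Xt, "biomass") if res.biomass is not None else None
        for j, sp in enumerate(model.species):
            y = (test_wide[sp].to_numpy(float) > 0).astype(float)
            if 0 < y.mean() < 1:
                aucs[sp].append(auc(y, prob[:, j]))
            else:
                logger.info("kfold_cv: fold %d single-class for %s; AUC skipped", fi, sp)
            if pred_bio is not None:
                obs = test_wide[sp].to_numpy(float)
                pos = obs > 0
                if pos.sum() >= 3 and np.std(np.log(obs[pos])) > 0:
                    try:
                        r2s[sp].append(r2_biomass(np.log(obs[pos]), pred_bio[pos, j]))
                    except ValueError:
                        logger.info("kfold_cv: fold %d degenerate R^2 for %s", fi, sp)

    cv = pd.DataFrame(
        {
            "cv_auc": {sp: np.mean(v) if v else np.nan for sp, v in aucs.items()},
            "cv_r2": {sp: np.mean(v) if v else np.nan for sp, v in r2s.items()},
            "n_auc_folds": {sp: len(v) for sp, v in aucs.items()},
            "n_r2_folds": {sp: len(v) for sp, v in r2s.items()},
        }
    )
    retained = [sp for sp in species if np.nan_to_num(cv.loc[sp, "cv_r2"], nan=-1) > retain_above]
    return FitReport(explanatory=pd.DataFrame(), cv=cv, retained=retained)
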