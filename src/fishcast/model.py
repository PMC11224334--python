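"""Hierarchical hurdle joint species distribution model, fitted by Gibbs sampling.

Two submodels share one architecture:

* occurrence — probit regression on presence/absence of every haul, sampled
  with truncated-normal latent-score augmentation;
* biomass — Gaussian regression on log CPUE of the positive records only
  (zeros are unobserved for this submodel; a true hurdle).

Species coefficient vectors beta_j have a hierarchical prior centred on a
trait-predicted mean Gamma t_j, with cross-species covariance per covariate
rho C + (1 - rho) I (C the phylogenetic correlation matrix) scaled by a
covariate-covariance matrix V. rho is sampled on a discrete grid over [0, 1].
Residual co-occurrence is captured by spatial latent factors evaluated at a
reduced set of knot locations (a Gaussian predictive process) and carried to
haul sites by the conditional-mean interpolator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import ndtr
from scipy.stats import invwishart
from sklearn.cluster import KMeans

from ._utils import laea_project, pairwise_dist, spawn_seed, truncnorm_draw
from .envprep import ModelDesign
from .phylo import TaxonTree
from .synthetic import trait_design

logger = logging.getLogger(__name__)

__all__ = [
    "McmcConfig",
    "KnotSet",
    "select_knots",
    "HurdleJSDM",
    "HurdleJSDMResults",
    "SubmodelPosterior",
    "fit_hurdle",
    "compute_psrf",
    "ConvergenceReport",
    "residual_cooccurrence",
    "CooccurrenceResult",
    "probit_loglik",
    "gpp_interpolator",
]


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run shape. `desk()` is the fast default used throughout the test
    suite; `paper_scale()` reproduces the published run shape (4 chains x 250
    samples, thinning 500, burn-in 62 500) and is hours of compute."""

    n_chains: int = 2
    samples_per_chain: int = 250
    thin: int = 5
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self):
        for f in ("n_chains", "samples_per_chain", "thin", "burn_in"):
            if getattr(self, f) < (0 if f == "burn_in" else 1):
                raise ValueError(f"{f} must be positive")

    @classmethod
    def desk(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_chains=2, samples_per_chain=250, thin=5, burn_in=500, seed=seed)

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_chains=4, samples_per_chain=250, thin=500, burn_in=62500, seed=seed)


@dataclass
class KnotSet:
    """Spatial knot locations (km, equal-area plane) for the predictive process."""

    coords: np.ndarray  # (m, 2)

    @property
    def n_knots(self) -> int:
        return self.coords.shape[0]


def select_knots(haul_coords: np.ndarray, n_knots: int = 183, seed: int = 0) -> KnotSet:
    """Choose knots by seeded k-means clustering of haul coordinates.

    If `n_knots` is at least the number of distinct haul locations the
    distinct locations themselves become the knots (with a warning).
    """
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    coords = np.asarray(haul_coords, dtype=float)
    distinct = np.unique(coords, axis=0)
    if n_knots >= len(distinct):
        if n_knots > len(distinct):
            warnings.warn(
                f"n_knots={n_knots} exceeds {len(distinct)} distinct locations; "
                "using the distinct locations as knots"
            )
        return KnotSet(coords=distinct)
    km = KMeans(n_clusters=n_knots, random_state=seed, n_init=4).fit(coords)
    return KnotSet(coords=km.cluster_centers_)


def gpp_interpolator(
    site_coords: np.ndarray, knot_coords: np.ndarray, alpha: float, jitter: float = 1e-8
) -> np.ndarray:
    """Conditional-mean interpolator A = C_sk C_kk^{-1} of the predictive
    process with exponential correlation of range `alpha` (km). With knots
    equal to sites, A is the identity."""
    Dkk = pairwise_dist(knot_coords)
    Dsk = pairwise_dist(site_coords, knot_coords)
    Kkk = np.exp(-Dkk / alpha) + jitter * np.eye(len(knot_coords))
    Ksk = np.exp(-Dsk / alpha)
    return sla.solve(Kkk, Ksk.T, assume_a="pos").T


def probit_loglik(Y: np.ndarray, mu: np.ndarray) -> float:
    """Bernoulli-probit log-likelihood of presence matrix Y given latent mean mu."""
    p = np.clip(ndtr(mu), 1e-12, 1 - 1e-12)
    return float(np.sum(np.where(Y > 0, np.log(p), np.log1p(-p))))


# ---------------------------------------------------------------------------
# prior settings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Priors:
    gamma_var: float = 4.0  # iid prior variance of trait effects
    v_df_add: float = 1.0  # V ~ IW(p + v_df_add, v_scale * I)
    v_scale: float = 1.0
    rho_grid_step: float = 0.01
    sigma_a0: float = 2.0  # sigma^2 ~ InvGamma(a0, b0)
    sigma_b0: float = 1.0
    shrink_a1: float = 2.0  # multiplicative-gamma loading shrinkage
    shrink_a2: float = 3.0
    n_alpha: int = 10  # spatial-range grid size per factor


@dataclass
class SubmodelPosterior:
    """Thinned posterior draws of one submodel, kept per chain.

    Array shapes: beta (chains, draws, p, S); gamma (chains, draws, p, t);
    V (chains, draws, p, p); rho (chains, draws); Lambda (chains, draws, S, q);
    eta (chains, draws, m, q); alpha (chains, draws, q); sigma (chains,
    draws, S) for the Gaussian submodel, else None.
    """

    beta: np.ndarray
    gamma: np.ndarray
    V: np.ndarray
    rho: np.ndarray
    Lambda: np.ndarray
    eta: np.ndarray
    alpha: np.ndarray
    sigma: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])

    @property
    def beta_mean(self) -> np.ndarray:
        return self.flat("beta").mean(axis=0)

    @property
    def beta_sd(self) -> np.ndarray:
        return self.flat("beta").std(axis=0, ddof=1)

    def rho_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        r = self.flat("rho")
        return float(np.quantile(r, lo)), float(np.quantile(r, 1 - lo))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class HurdleJSDM:
    """Two-part hurdle joint species distribution model.

    Parameters
    ----------
    survey : long-format records with columns haul_id, species, cpue (zeros
        explicit), plus lon/lat for spatial coordinates
    design : ModelDesign whose rows cover every haul in `survey`
    tree : TaxonTree covering all surveyed species
    traits : trait table indexed by species
    knots : KnotSet, or None to select `n_knots` by clustering
    n_factors : number of spatial latent factors (0 disables the spatial
        random effect); capped at 5
    """

    MAX_FACTORS = 5

    def __init__(
        self,
        survey: pd.DataFrame,
        design: ModelDesign,
        tree: TaxonTree,
        traits: pd.DataFrame,
        knots: KnotSet | None = None,
        n_factors: int = 2,
        n_knots: int = 183,
        traits_used: list[str] | None = None,
        priors: Priors = Priors(),
    ):
        self.species = sorted(survey["species"].unique())
        missing = set(self.species) - set(tree.species)
        if missing:
            raise ValueError(f"species absent from tree: {sorted(missing)}")
        sub = tree.subset(self.species)
        self.C = sub.corr
        self.tree = sub
        self.traits = traits.loc[self.species]
        self.T, self.trait_names = trait_design(self.traits, use=traits_used)
        self.priors = priors

        wide = survey.pivot_table(index="haul_id", columns="species", values="cpue")
        wide = wide[self.species]
        self.haul_ids = wide.index.to_numpy()
        self.design = design
        self.X = design.X.loc[self.haul_ids].to_numpy(float)
        self.Y_occ = (wide.to_numpy(float) > 0).astype(float)
        with np.errstate(divide="ignore"):
            self.Y_bio = np.where(wide.to_numpy(float) > 0, np.log(wide.to_numpy(float)), np.nan)

        hauls = survey.drop_duplicates("haul_id").set_index("haul_id").loc[self.haul_ids]
        lon0, lat0 = float(hauls["lon"].mean()), float(hauls["lat"].mean())
        hx, hy = laea_project(hauls["lon"].to_numpy(), hauls["lat"].to_numpy(), lon0, lat0)
        self.site_coords = np.column_stack([hx, hy])

        self.n_factors = int(min(n_factors, self.MAX_FACTORS))
        if self.n_factors > 0:
            self.knots = knots if knots is not None else select_knots(
                self.site_coords, n_knots=min(n_knots, len(self.site_coords)), seed=0
            )
        else:
            self.knots = knots

        all_present = self.Y_occ.mean(axis=0) == 1.0
        all_absent = self.Y_occ.mean(axis=0) == 0.0
        if all_present.any() or all_absent.any():
            warnings.warn(
                "species with no within-sample occurrence variation; their "
                "occurrence fit is intercept-dominated"
            )

        # per-species term masks from the design
        self.free_mask = np.concatenate(
            [design.term_mask(sp) for sp in self.species]
        )  # species-major (S * p)

    def fit(
        self, cfg: McmcConfig = McmcConfig(), submodels: tuple[str, ...] = ("occurrence", "biomass")
    ) -> "HurdleJSDMResults":
        root = np.random.default_rng(cfg.seed)
        posteriors: dict[str, SubmodelPosterior] = {}
        for kind in submodels:
            if kind not in ("occurrence", "biomass"):
                raise ValueError(f"unknown submodel '{kind}'")
            chains = []
            for _ in range(cfg.n_chains):
                rng = np.random.default_rng(spawn_seed(root))
                chains.append(self._run_chain(kind, cfg, rng))
            posteriors[kind] = _stack_chains(chains, gaussian=kind == "biomass")
        return HurdleJSDMResults(model=self, config=cfg, posteriors=posteriors)

    # -- sampler ------------------------------------------------------------

    def _run_chain(self, kind: str, cfg: McmcConfig, rng: np.random.Generator) -> dict:
        gaussian = kind == "biomass"
        X = self.X
        n, p = X.shape
        S = len(self.species)
        q = self.n_factors
        pri = self.priors
        T = self.T
        t = T.shape[1]

        if gaussian:
            M_obs = ~np.isnan(self.Y_bio)
            Y = np.where(M_obs, self.Y_bio, 0.0)
        else:
            M_obs = np.ones_like(self.Y_occ, dtype=bool)
            Y = self.Y_occ

        XtX = [X[M_obs[:, j]].T @ X[M_obs[:, j]] for j in range(S)]
        n_obs = M_obs.sum(axis=0)

        # phylogeny eigendecomposition for the rho grid
        d_eig, Q_eig = np.linalg.eigh(self.C)
        d_eig = np.clip(d_eig, 0.0, None)
        rho_grid = np.arange(0.0, 1.0 + pri.rho_grid_step / 2, pri.rho_grid_step)
        w_grid = rho_grid[:, None] * d_eig[None, :] + (1 - rho_grid[:, None])  # (G, S)
        w_grid = np.clip(w_grid, 1e-10, None)
        logdet_w = np.log(w_grid).sum(axis=1)  # (G,)

        # spatial machinery per candidate range
        if q > 0:
            knots = self.knots.coords
            m = len(knots)
            extent = max(np.ptp(self.site_coords[:, 0]), np.ptp(self.site_coords[:, 1]), 1.0)
            alpha_grid = np.linspace(0.05, 1.0, pri.n_alpha) * extent
            Dkk = pairwise_dist(knots)
            Dsk = pairwise_dist(self.site_coords, knots)
            K_chol, A_all, K_logdet = [], [], []
            for a in alpha_grid:
                K = np.exp(-Dkk / a) + 1e-8 * np.eye(m)
                L = np.linalg.cholesky(K)
                K_chol.append(L)
                K_logdet.append(2.0 * np.log(np.diag(L)).sum())
                A_all.append(sla.cho_solve((L, True), np.exp(-Dsk / a).T).T)
        else:
            m = 0

        # state
        B = np.zeros((p, S))
        Gamma = np.zeros((p, t))
        V = np.eye(p)
        Vinv = np.eye(p)
        rho = 0.5
        gi = len(rho_grid) // 2
        Lambda = rng.normal(0, 0.1, (S, q)) if q else np.zeros((S, 0))
        eta = np.zeros((m, q))
        a_idx = np.full(q, max(0, (pri.n_alpha // 2) - 1), dtype=int)
        delta = np.ones(q)
        sigma2 = np.ones(S)
        z = Y.copy() if gaussian else np.where(self.Y_occ > 0, 0.5, -0.5)
        F = A_all[a_idx[0]] @ eta if q else np.zeros((n, 0))

        free = self.free_mask
        n_iter = cfg.burn_in + cfg.samples_per_chain * cfg.thin
        keep = {
            "beta": [], "gamma": [], "V": [], "rho": [], "Lambda": [],
            "eta": [], "alpha": [], "sigma": [],
        }

        for it in range(n_iter):
            spatial = F @ Lambda.T if q else 0.0

            # 1. latent probit scores
            if not gaussian:
                z = truncnorm_draw(rng, X @ B + spatial, self.Y_occ > 0)

            resid_target = (z if not gaussian else Y) - spatial

            # 2. coefficients B | rest (joint across species, phylogenetic prior)
            w = w_grid[gi]
            Winv = (Q_eig / w) @ Q_eig.T
            P0 = np.kron(Winv, Vinv)
            P = P0.copy()
            bvec = np.empty(S * p)
            inv_s2 = 1.0 / sigma2 if gaussian else np.ones(S)
            for j in range(S):
                sl = slice(j * p, (j + 1) * p)
                P[sl, sl] += XtX[j] * inv_s2[j]
                rj = resid_target[M_obs[:, j], j]
                bvec[sl] = (X[M_obs[:, j]].T @ rj) * inv_s2[j]
            Mprior = Gamma @ T.T  # (p, S)
            bvec += P0 @ Mprior.T.ravel()
            Pf = P[np.ix_(free, free)]
            bf = bvec[free]
            cf, low = sla.cho_factor(Pf, lower=True)
            mean = sla.cho_solve((cf, low), bf)
            draw = mean + sla.solve_triangular(cf, rng.standard_normal(free.sum()),
                                               lower=True, trans="T")
            full = np.zeros(S * p)
            full[free] = draw
            B = full.reshape(S, p).T

            # 3. trait effects Gamma
            E_for_g = B  # prior mean regression target
            Prec_g = np.kron(T.T @ Winv @ T, Vinv) + np.eye(p * t) / pri.gamma_var
            b_g = (Vinv @ E_for_g @ Winv @ T).T.ravel()
            cg, lowg = sla.cho_factor(Prec_g, lower=True)
            mg = sla.cho_solve((cg, lowg), b_g)
            gdraw = mg + sla.solve_triangular(cg, rng.standard_normal(p * t),
                                              lower=True, trans="T")
            Gamma = gdraw.reshape(t, p).T

            # 4. covariate covariance V
            E = B - Gamma @ T.T
            scale = pri.v_scale * np.eye(p) + E @ Winv @ E.T
            V = invwishart.rvs(df=p + pri.v_df_add + S, scale=scale, random_state=rng)
            V = np.atleast_2d(V)
            Vinv = np.linalg.inv(V)

            # 5. phylogenetic signal rho on its grid
            EQ = E @ Q_eig  # (p, S)
            u = np.einsum("ps,ps->s", EQ, Vinv @ EQ)
            ll = -0.5 * p * logdet_w - 0.5 * (u[None, :] / w_grid).sum(axis=1)
            ll -= ll.max()
            prob = np.exp(ll)
            gi = int(rng.choice(len(rho_grid), p=prob / prob.sum()))
            rho = float(rho_grid[gi])

            # 6. latent factors
            if q:
                tau = np.cumprod(delta)
                R = (z if not gaussian else Y) - X @ B
                for j in range(S):
                    Fo = F[M_obs[:, j]]
                    prec = Fo.T @ Fo * inv_s2[j] + np.diag(tau)
                    bl = Fo.T @ R[M_obs[:, j], j] * inv_s2[j]
                    cl = np.linalg.cholesky(prec)
                    ml = sla.cho_solve((cl, True), bl)
                    Lambda[j] = ml + sla.solve_triangular(
                        cl, rng.standard_normal(q), lower=True, trans="T"
                    )
                Rw = np.where(M_obs, R, 0.0)
                for h in range(q):
                    others = np.delete(np.arange(q), h)
                    Rh = Rw - sum(
                        (F[:, g][:, None] * Lambda[:, g][None, :]) * M_obs for g in others
                    ) if others.size else Rw
                    lam_h = Lambda[:, h]
                    dvec = M_obs @ (lam_h**2 * inv_s2)
                    rhs_site = Rh @ (lam_h * inv_s2)
                    A = A_all[a_idx[h]]
                    L0 = K_chol[a_idx[h]]
                    Kinv = sla.cho_solve((L0, True), np.eye(m))
                    prec = Kinv + (A * dvec[:, None]).T @ A
                    bh = A.T @ rhs_site
                    ch = np.linalg.cholesky(prec)
                    mh = sla.cho_solve((ch, True), bh)
                    eta[:, h] = mh + sla.solve_triangular(
                        ch, rng.standard_normal(m), lower=True, trans="T"
                    )
                    # spatial range for this factor
                    lls = np.array(
                        [
                            -0.5 * K_logdet[k]
                            - 0.5 * np.sum(
                                sla.solve_triangular(K_chol[k], eta[:, h], lower=True) ** 2
                            )
                            for k in range(len(alpha_grid))
                        ]
                    )
                    lls -= lls.max()
                    pr = np.exp(lls)
                    a_idx[h] = int(rng.choice(len(alpha_grid), p=pr / pr.sum()))
                    F[:, h] = A_all[a_idx[h]] @ eta[:, h]

                # multiplicative-gamma shrinkage of loadings
                lam2 = (Lambda**2).sum(axis=0)  # per factor
                for l in range(q):
                    tau_part = np.cumprod(delta)
                    tau_wo = tau_part / delta[l]
                    shape = (pri.shrink_a1 if l == 0 else pri.shrink_a2) + 0.5 * S * (q - l)
                    rate = 1.0 + 0.5 * np.sum(tau_wo[l:] * lam2[l:])
                    delta[l] = rng.gamma(shape, 1.0 / rate)

            # 7. residual variances (Gaussian submodel)
            if gaussian:
                spatial = F @ Lambda.T if q else 0.0
                resid = Y - X @ B - spatial
                for j in range(S):
                    e = resid[M_obs[:, j], j]
                    shape = pri.sigma_a0 + 0.5 * n_obs[j]
                    rate = pri.sigma_b0 + 0.5 * e @ e
                    sigma2[j] = 1.0 / rng.gamma(shape, 1.0 / rate)

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                keep["beta"].append(B.copy())
                keep["gamma"].append(Gamma.copy())
                keep["V"].append(V.copy())
                keep["rho"].append(rho)
                keep["Lambda"].append(Lambda.copy())
                keep["eta"].append(eta.copy())
                keep["alpha"].append(alpha_grid[a_idx].copy() if q else np.zeros(0))
                keep["sigma"].append(np.sqrt(sigma2).copy())

        return {k: np.array(v) for k, v in keep.items()}


def _stack_chains(chains: list[dict], gaussian: bool) -> SubmodelPosterior:
    stack = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    return SubmodelPosterior(
        beta=stack["beta"],
        gamma=stack["gamma"],
        V=stack["V"],
        rho=stack["rho"],
        Lambda=stack["Lambda"],
        eta=stack["eta"],
        alpha=stack["alpha"],
        sigma=stack["sigma"] if gaussian else None,
    )


def fit_hurdle(
    survey: pd.DataFrame,
    design: ModelDesign,
    tree: TaxonTree,
    traits: pd.DataFrame,
    knots: KnotSet | None = None,
    cfg: McmcConfig = McmcConfig(),
    **kwargs,
) -> "HurdleJSDMResults":
    """Convenience wrapper: build a `HurdleJSDM` and fit both submodels."""
    model = HurdleJSDM(survey, design, tree, traits, knots=knots, **kwargs)
    return model.fit(cfg)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class HurdleJSDMResults:
    """Posterior of the fitted hurdle model with prediction helpers."""

    model: HurdleJSDM
    config: McmcConfig
    posteriors: dict[str, SubmodelPosterior]

    @property
    def occurrence(self) -> SubmodelPosterior:
        return self.posteriors["occurrence"]

    @property
    def biomass(self) -> SubmodelPosterior | None:
        return self.posteriors.get("biomass")

    @property
    def species(self) -> list[str]:
        return self.model.species

    def predict_linear(self, Xnew: np.ndarray, submodel: str, per_draw: bool = False):
        """Linear predictor of a submodel at new design rows; fixed effects only.

        Returns (draws, n, S) if per_draw else the posterior-mean (n, S).
        """
        post = self.posteriors[submodel]
        beta = post.flat("beta")  # (D, p, S)
        eta = np.einsum("np,dps->dns", Xnew, beta)
        return eta if per_draw else eta.mean(axis=0)

    def predict_occurrence_prob(
        self, Xnew: np.ndarray, include_spatial: bool = False, per_draw: bool = False
    ):
        """Posterior (mean) occurrence probability at new design rows.

        With `include_spatial=False` (the rule used for all projections) the
        result depends only on the regression coefficients, not on the latent
        factor draws.
        """
        eta = self.predict_linear(Xnew, "occurrence", per_draw=True)
        if include_spatial:
            raise NotImplementedError(
                "spatial interpolation to arbitrary new sites is not supported; "
                "projections exclude the spatial random effect"
            )
        prob = ndtr(eta)
        return prob if per_draw else prob.mean(axis=0)

    def fitted_occurrence_prob(self, include_spatial: bool = True) -> np.ndarray:
        """Posterior-mean occurrence probability at the fitting hauls."""
        post = self.occurrence
        beta = post.flat("beta")
        eta = np.einsum("np,dps->dns", self.model.X, beta)
        if include_spatial and self.model.n_factors:
            A = _site_interpolators(self.model, post)
            eta = eta + A
        return ndtr(eta).mean(axis=0)

    def fitted_biomass_mean(self, include_spatial: bool = True) -> np.ndarray:
        """Posterior-mean log-CPUE prediction at the fitting hauls."""
        post = self.posteriors["biomass"]
        beta = post.flat("beta")
        eta = np.einsum("np,dps->dns", self.model.X, beta)
        if include_spatial and self.model.n_factors:
            eta = eta + _site_interpolators(self.model, post)
        return eta.mean(axis=0)

    def summary(self) -> str:
        lines = ["Hurdle joint species distribution model", "=" * 40]
        lines.append(
            f"hauls: {len(self.model.haul_ids)}   species: {len(self.species)}   "
            f"terms: {self.model.X.shape[1]}   latent factors: {self.model.n_factors}"
        )
        lines.append(
            f"chains: {self.config.n_chains}   samples/chain: {self.config.samples_per_chain}"
            f"   thin: {self.config.thin}   burn-in: {self.config.burn_in}"
        )
        for kind, post in self.posteriors.items():
            r = post.flat("rho")
            lo, hi = post.rho_interval()
            lines.append(
                f"{kind}: rho = {r.mean():.2f} [95% CI {lo:.2f}, {hi:.2f}]"
            )
        try:
            rep = compute_psrf(self)
            lines.append(f"mean PSRF = {rep.mean:.3f} ({'converged' if rep.converged else 'NOT converged'})")
        except ValueError:
            pass
        return "\n".join(lines)


def _site_interpolators(model: HurdleJSDM, post: SubmodelPosterior) -> np.ndarray:
    """Per-draw spatial contribution F Lambda' at the fitting sites."""
    eta_d = post.flat("eta")  # (D, m, q)
    lam_d = post.flat("Lambda")  # (D, S, q)
    alpha_d = post.flat("alpha")  # (D, q)
    D = eta_d.shape[0]
    n = model.site_coords.shape[0]
    S = len(model.species)
    out = np.zeros((D, n, S))
    cache: dict[float, np.ndarray] = {}
    for d in range(D):
        F = np.zeros((n, eta_d.shape[2]))
        for h in range(eta_d.shape[2]):
            a = float(alpha_d[d, h])
            if a not in cache:
                cache[a] = gpp_interpolator(model.site_coords, model.knots.coords, a)
            F[:, h] = cache[a] @ eta_d[d, :, h]
        out[d] = F @ lam_d[d].T
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceReport:
    psrf: pd.Series  # per scalar parameter
    mean: float
    converged: bool  # mean PSRF < 1.1


def _gelman_rubin(draws: np.ndarray) -> float:
    """Classic potential scale reduction factor for (chains, draws) samples."""
    m, n = draws.shape
    means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def compute_psrf(results: HurdleJSDMResults | SubmodelPosterior) -> ConvergenceReport:
    """Gelman-Rubin PSRF per scalar parameter; converged iff mean PSRF < 1.1.

    Covers regression coefficients, trait effects, rho, the diagonal of V and
    (Gaussian submodel) residual SDs. Factor loadings are excluded: their sign
    and ordering are not identified, which makes the raw PSRF meaningless.
    """
    if isinstance(results, SubmodelPosterior):
        posts = {"submodel": results}
        free = None
        species = None
        terms = None
    else:
        posts = results.posteriors
        free = results.model.free_mask
        species = results.species
        terms = results.model.design.term_names
    rows = {}
    for kind, post in posts.items():
        if post.beta.shape[0] < 2:
            raise ValueError("PSRF requires at least 2 chains")
        c, dr, p, S = post.beta.shape
        flat = post.beta.transpose(0, 1, 3, 2).reshape(c, dr, S * p)  # species-major
        for idx in range(S * p):
            if free is not None and not free[idx]:
                continue
            j, k = divmod(idx, p)
            name = (
                f"{kind}.beta[{species[j]},{terms[k]}]"
                if species is not None
                else f"{kind}.beta[{idx}]"
            )
            rows[name] = _gelman_rubin(flat[:, :, idx])
        gt = post.gamma.reshape(c, dr, -1)
        for idx in range(gt.shape[2]):
            rows[f"{kind}.gamma[{idx}]"] = _gelman_rubin(gt[:, :, idx])
        rows[f"{kind}.rho"] = _gelman_rubin(post.rho)
        vd = np.stack([post.V[:, :, i, i] for i in range(post.V.shape[2])], axis=2)
        for i in range(vd.shape[2]):
            rows[f"{kind}.V[{i},{i}]"] = _gelman_rubin(vd[:, :, i])
        if post.sigma is not None:
            for j in range(post.sigma.shape[2]):
                nm = species[j] if species is not None else j
                rows[f"{kind}.sigma[{nm}]"] = _gelman_rubin(post.sigma[:, :, j])
    psrf = pd.Series(rows)
    mean = float(psrf.mean())
    return ConvergenceReport(psrf=psrf, mean=mean, converged=bool(mean < 1.1))


@dataclass
class CooccurrenceResult:
    corr: pd.DataFrame  # posterior-mean residual correlation
    supported: pd.DataFrame  # bool, posterior sign agreement >= support level


def residual_cooccurrence(
    results: HurdleJSDMResults,
    submodel: str = "occurrence",
    support: float = 0.95,
) -> CooccurrenceResult:
    """Residual species-species correlation from the latent-factor loadings.

    Per draw, Omega = Lambda Lambda' is normalised to unit diagonal; a pair is
    flagged as supported when at least `support` of the draws agree in sign.
    With zero factors the identity matrix is returned with an empty mask.
    """
    post = results.posteriors[submodel]
    species = results.species
    S = len(species)
    lam = post.flat("Lambda")
    if lam.shape[2] == 0:
        eye = pd.DataFrame(np.eye(S), index=species, columns=species)
        return CooccurrenceResult(corr=eye, supported=pd.DataFrame(False, index=species, columns=species))
    corrs = np.zeros((lam.shape[0], S, S))
    for d in range(lam.shape[0]):
        Om = lam[d] @ lam[d].T
        sd = np.sqrt(np.clip(np.diag(Om), 1e-12, None))
        corrs[d] = Om / np.outer(sd, sd)
        corrs[d][np.diag_indices(S)] = 1.0
    mean = corrs.mean(axis=0)
    pos = (corrs > 0).mean(axis=0)
    neg = (corrs < 0).mean(axis=0)
    supported = (np.maximum(pos, neg) >= support) & ~np.eye(S, dtype=bool)
    return CooccurrenceResult(
        corr=pd.DataFrame(mean, index=species, columns=species),
        supported=pd.DataFrame(supported, index=species, columns=species),
    )
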