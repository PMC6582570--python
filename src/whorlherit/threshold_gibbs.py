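"""Bayesian threshold (liability) animal model fitted by Gibbs sampling.

Model: each observation's ordered category Y in 1..C is determined by a
latent Gaussian liability

    L = beta_sex + u_individual + e,
    u ~ N(0, A sigma2_u),  e ~ N(0, I sigma2_e),

with strictly increasing thresholds t_1 < ... < t_{C-1} cutting the
liability scale into C intervals (Y = c iff t_{c-1} < L <= t_c, where
t_0 = -inf and t_C = +inf).  Heritability on the liability scale is
h2 = sigma2_u / (sigma2_u + sigma2_e).

Identifiability: h2 is invariant to the location and scale of the
liability, which must therefore be pinned by convention.  For binary
traits t_1 = 0 and sigma2_e = 1 are fixed (the classic data-augmentation
parameterization).  For C >= 3 the default fixes two thresholds
(t_1 = 0, t_2 = 1) and samples sigma2_e instead: the interval-pinned
middle category anchors the liability scale directly, which mixes far
better than single-site threshold updates; the fix-sigma2_e
parameterization remains available and any thresholds beyond t_2 are
sampled from their uniform conditionals.

Priors are flat on the fixed effects and thresholds.  The variances get
scaled inverse chi-square priors that are weakly informative but proper
(default nu = 4, S = 0.25, prior mean 0.5).  A flat variance prior
(nu = -2) is expressible but yields an improper posterior here: the
categorical likelihood tends to a positive constant as sigma2_u grows
(every observation retains its own latent liability freedom), so a chain
under the flat prior eventually drifts to h2 -> 1.

The full conditionals:

* liabilities — truncated normals within each observation's category
  interval;
* fixed effects and breeding values — the mixed-model-equations Gaussian
  conditional; breeding values are updated single-site, batched over
  "color classes" of pedigree members that share no A-inverse entry (a
  chromatic Gibbs sweep, distributionally identical to sequential
  single-site updates);
* sigma2_u — scaled inverse chi-square with df q + nu and scale
  u' A^-1 u + nu S;
* free thresholds — uniform between the largest liability of the lower
  category and the smallest liability of the upper category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import ndtr, ndtri
from scipy.stats import gaussian_kde

from .pedigree import Pedigree, sparse_a_inverse
from .phenotypes import TraitDataset

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    """Raised for unidentifiable or inconsistent model inputs/states."""


def resolve_parameterization(parameterization: str, n_categories: int) -> str:
    """Resolve "auto" to the concrete identifiability convention for C categories."""
    if parameterization == "auto":
        return "fix_var_e" if n_categories <= 2 else "fix_two_thresholds"
    if parameterization == "fix_two_thresholds" and n_categories < 3:
        raise ModelError("fix_two_thresholds requires >= 3 categories")
    if parameterization not in ("fix_var_e", "fix_two_thresholds"):
        raise ModelError(f"unknown parameterization {parameterization!r}")
    return parameterization


# --------------------------------------------------------------------------
# configuration and state containers


@dataclass
class MCMCConfig:
    """Gibbs-sampler settings.

    The published analysis used 1,050,000 iterations with a 50,000 burn-in;
    tests and simulation experiments use far shorter chains.
    ``prior_nu``/``prior_scale`` and ``prior_nu_e``/``prior_scale_e``
    parameterize the scaled inverse chi-square priors on sigma2_u and
    sigma2_e (nu = -2, S = 0 would be flat on a variance, but is improper
    for this model — see the module docstring).  ``parameterization`` is
    "auto" (binary: fix t_1 = 0 and sigma2_e = 1; C >= 3: fix t_1 = 0,
    t_2 = 1 and sample sigma2_e), "fix_var_e", or "fix_two_thresholds".
    ``var_u_floor`` prevents an absorbing state at sigma2_u = 0 in early
    iterations.
    """

    n_iterations: int = 1_050_000
    burn_in: int = 50_000
    thinning: int = 1
    seed: int = 0
    n_chains: int = 1
    var_u_init: float = 0.5
    var_e_init: float = 0.5
    prior_nu: float = 4.0
    prior_scale: float = 0.25
    prior_nu_e: float = 4.0
    prior_scale_e: float = 0.25
    parameterization: str = "auto"
    var_u_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.thinning <= 0 or self.n_chains <= 0:
            raise ModelError("n_iterations, thinning and n_chains must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ModelError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.parameterization not in ("auto", "fix_var_e", "fix_two_thresholds"):
            raise ModelError(f"unknown parameterization {self.parameterization!r}")

    def resolve_parameterization(self, n_categories: int) -> str:
        return resolve_parameterization(self.parameterization, n_categories)

    @property
    def n_retained(self) -> int:
        return -(-(self.n_iterations - self.burn_in) // self.thinning)

    def sampler_settings(self) -> tuple:
        """Settings that must match for chains to be comparable (seed excluded)."""
        return (self.n_iterations, self.burn_in, self.thinning,
                self.var_u_init, self.var_e_init, self.prior_nu, self.prior_scale,
                self.prior_nu_e, self.prior_scale_e, self.parameterization,
                self.var_u_floor)


@dataclass
class LiabilityState:
    """Full Gibbs state: liabilities, fixed effects, breeding values, variances, thresholds."""

    L: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    var_u: float
    var_e: float
    thresholds: np.ndarray
    iteration: int = 0


@dataclass
class GibbsChain:
    """Retained post-burn-in samples of (sigma2_u, sigma2_e, thresholds, h2)."""

    trait_name: str
    config: MCMCConfig
    seed: int
    var_u: np.ndarray
    var_e: np.ndarray
    thresholds: np.ndarray  # shape (n_retained, C - 1)
    h2: np.ndarray

    def __len__(self) -> int:
        return len(self.h2)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"var_u": self.var_u, "var_e": self.var_e})
        for j in range(self.thresholds.shape[1]):
            df[f"t{j + 1}"] = self.thresholds[:, j]
        df["h2"] = self.h2
        return df


@dataclass
class PosteriorSummary:
    """Mode, mean +/- SD, and 95% credible interval of a posterior sample."""

    mode: float
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict[str, float]:
        return {"mode": self.mode, "mean": self.mean, "sd": self.sd,
                "ci_low": self.ci_low, "ci_high": self.ci_high}


# --------------------------------------------------------------------------
# model data


class ThresholdModelData:
    """Observation arrays, A-inverse, and the chromatic update schedule.

    Bundles everything the samplers need: pedigree-aligned observation
    indices, sex-level codes, 0-based categories, the sparse A^-1 with its
    diagonal, per-individual observation counts, and color classes —
    groups of pedigree members with no off-diagonal A^-1 entry between
    them, which can therefore be Gibbs-updated simultaneously.
    """

    def __init__(self, trait_name: str, obs_ind: np.ndarray, obs_sex: np.ndarray,
                 category: np.ndarray, n_categories: int, sex_levels: list[str],
                 ainv: sparse.csr_matrix):
        self.trait_name = trait_name
        self.obs_ind = obs_ind
        self.obs_sex = obs_sex
        self.category = category
        self.n_categories = int(n_categories)
        self.sex_levels = sex_levels
        self.n_sex = len(sex_levels)
        self.ainv = ainv
        self.n_individuals = ainv.shape[0]
        self.ainv_diag = ainv.diagonal()
        self.sex_counts = np.bincount(obs_sex, minlength=self.n_sex).astype(float)
        if np.any(self.sex_counts == 0):
            empty = [sex_levels[i] for i in np.flatnonzero(self.sex_counts == 0)]
            raise ModelError(f"sex level(s) without observations: {empty} (singular system)")
        self.obs_counts = np.bincount(obs_ind, minlength=self.n_individuals).astype(float)
        self.category_counts = np.bincount(category, minlength=self.n_categories)
        self.category_masks = [category == c for c in range(self.n_categories)]
        self.color_classes = _color_classes(ainv)

    @classmethod
    def from_dataset(cls, data: TraitDataset, ped: Pedigree,
                     sex_levels: list[str] | None = None) -> "ThresholdModelData":
        missing = [i for i in data.ids if i not in ped]
        if missing:
            raise ModelError(f"phenotyped individual(s) missing from pedigree: {missing[:10]}")
        obs_ind = np.array([ped.order_index[i] for i in data.ids], dtype=np.int64)
        sexes = data.observations["sex"].tolist()
        if sex_levels is None:
            sex_levels = sorted(set(sexes))
        level_code = {s: i for i, s in enumerate(sex_levels)}
        unknown = set(sexes) - set(sex_levels)
        if unknown:
            raise ModelError(f"sex value(s) {sorted(unknown)} not in levels {sex_levels}")
        obs_sex = np.array([level_code[s] for s in sexes], dtype=np.int64)
        category = data.categories.astype(np.int64) - 1
        return cls(data.trait_name, obs_ind, obs_sex, category, data.n_categories,
                   sex_levels, sparse_a_inverse(ped))


def _color_classes(ainv: sparse.csr_matrix) -> list[np.ndarray]:
    """Greedy coloring of the A^-1 adjacency graph; classes are mutually
    conditionally independent given the rest, so each class updates jointly."""
    n = ainv.shape[0]
    indptr, indices = ainv.indptr, ainv.indices
    colors = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        neigh = indices[indptr[i]:indptr[i + 1]]
        used = set(colors[neigh].tolist())
        c = 0
        while c in used:
            c += 1
        colors[i] = c
    return [np.flatnonzero(colors == c) for c in range(int(colors.max()) + 1)]


# --------------------------------------------------------------------------
# elementary samplers


def sample_truncated_normal(mean, sd, lower, upper, rng: np.random.Generator) -> np.ndarray:
    """Draw from Normal(mean, sd^2) truncated to (lower, upper], vectorized.

    Uses the inverse-CDF method on whichever tail is numerically stable:
    intervals lying mostly above the mean are reflected so the CDF is
    evaluated in the lower tail, where ``ndtr`` keeps full precision down
    to ~1e-308.  Robust for truncation regions far into the tails.
    """
    mean, sd, lower, upper = np.broadcast_arrays(
        np.asarray(mean, float), np.asarray(sd, float),
        np.asarray(lower, float), np.asarray(upper, float))
    with np.errstate(invalid="ignore"):
        a = (lower - mean) / sd
        b = (upper - mean) / sd
        flip = (a + b) > 0  # NaN (-inf + inf) compares False: no flip needed
    aa = np.where(flip, -b, a)
    bb = np.where(flip, -a, b)
    pa = ndtr(aa)
    pb = ndtr(bb)
    u = pa + (pb - pa) * rng.random(aa.shape)
    u = np.clip(u, np.finfo(float).tiny, 1.0 - 1e-16)
    z = ndtri(u)
    # numerical safety when the interval mass underflows: pin to the bounds
    z = np.minimum(np.maximum(z, aa), bb)
    z = np.where(flip, -z, z)
    return mean + sd * z


def _threshold_bounds(thresholds: np.ndarray) -> np.ndarray:
    return np.concatenate(([-np.inf], thresholds, [np.inf]))


def initialize_state(data, ped: Pedigree | None = None, seed=0,
                     var_u_init: float = 0.5, var_e_init: float = 0.5,
                     parameterization: str = "auto") -> LiabilityState:
    """Starting state: beta = 0, u = 0, variances at their init values, and
    thresholds from the inverse-normal CDF of cumulative category
    frequencies, rescaled so the constrained thresholds hold (t_1 = 0;
    additionally t_2 = 1 under the fix-two-thresholds parameterization).
    Liabilities are drawn from the correct truncated region.

    ``data`` may be a TraitDataset (with ``ped``) or a prepared
    ThresholdModelData.  Raises if any category has no observations
    (thresholds would be unidentifiable).
    """
    model = data if isinstance(data, ThresholdModelData) else \
        ThresholdModelData.from_dataset(data, ped)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.any(model.category_counts == 0):
        empty = np.flatnonzero(model.category_counts == 0) + 1
        raise ModelError(f"category {empty.tolist()} has no observations; "
                         "thresholds are unidentifiable")
    param = resolve_parameterization(parameterization, model.n_categories)
    cum = np.cumsum(model.category_counts) / model.category_counts.sum()
    z = ndtri(cum[:-1])
    if param == "fix_two_thresholds":
        thresholds = (z - z[0]) / (z[1] - z[0])  # t_1 = 0, t_2 = 1
        var_e = float(var_e_init)
    else:
        thresholds = z - z[0] if z.size else z  # t_1 = 0 (none for C = 1)
        var_e = 1.0
    bounds = _threshold_bounds(thresholds)
    L = sample_truncated_normal(0.0, 1.0, bounds[model.category],
                                bounds[model.category + 1], rng)
    return LiabilityState(
        L=L,
        beta=np.zeros(model.n_sex),
        u=np.zeros(model.n_individuals),
        var_u=float(var_u_init),
        var_e=var_e,
        thresholds=thresholds,
        iteration=0,
    )


def sample_liabilities(state: LiabilityState, model: ThresholdModelData,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw each liability from its truncated-normal full conditional."""
    mu = state.beta[model.obs_sex] + state.u[model.obs_ind]
    bounds = _threshold_bounds(state.thresholds)
    return sample_truncated_normal(mu, np.sqrt(state.var_e),
                                   bounds[model.category],
                                   bounds[model.category + 1], rng)


def sample_location_effects(state: LiabilityState, model: ThresholdModelData,
                            rng: np.random.Generator,
                            var_u_floor: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Draw fixed effects and breeding values from their Gaussian conditionals.

    Fixed effects use a flat prior (cell-means parameterization over sex
    levels).  Breeding values follow the mixed-model-equations conditional
    with precision Z'Z / sigma2_e + A^-1 / sigma2_u, updated single-site in
    chromatic batches; the stationary distribution equals the joint
    Gaussian conditional.
    """
    ve = state.var_e
    vu = max(state.var_u, var_u_floor)
    resid = state.L - state.u[model.obs_ind]
    sums = np.bincount(model.obs_sex, weights=resid, minlength=model.n_sex)
    beta = sums / model.sex_counts + \
        rng.standard_normal(model.n_sex) * np.sqrt(ve / model.sex_counts)
    adj = state.L - beta[model.obs_sex]
    r = np.bincount(model.obs_ind, weights=adj, minlength=model.n_individuals)
    u = state.u.copy()
    for cls in model.color_classes:
        s_full = model.ainv @ u
        off = s_full[cls] - model.ainv_diag[cls] * u[cls]
        prec = model.obs_counts[cls] / ve + model.ainv_diag[cls] / vu
        mean = (r[cls] / ve - off / vu) / prec
        u[cls] = mean + rng.standard_normal(cls.size) / np.sqrt(prec)
    return beta, u


def sample_genetic_variance(state: LiabilityState, model: ThresholdModelData,
                            rng: np.random.Generator, prior_nu: float = -2.0,
                            prior_scale: float = 0.0,
                            var_u_floor: float = 1e-8) -> float:
    """Draw sigma2_u from its scaled inverse chi-square full conditional.

    df = q + nu and scale = u' A^-1 u + nu S, where q is the number of
    pedigree individuals; the default prior (nu = -2, S = 0) is flat on
    the variance.  A small floor guards the absorbing state at zero.
    """
    q = model.n_individuals
    scale = float(state.u @ (model.ainv @ state.u)) + prior_nu * prior_scale
    df = q + prior_nu
    if df <= 0:
        raise ModelError(f"non-positive degrees of freedom {df} for sigma2_u draw")
    draw = scale / rng.chisquare(df)
    return max(float(draw), var_u_floor)


def sample_residual_variance(state: LiabilityState, model: ThresholdModelData,
                             rng: np.random.Generator, prior_nu: float = 4.0,
                             prior_scale: float = 0.25) -> float:
    """Draw sigma2_e from its scaled inverse chi-square full conditional.

    df = n + nu and scale = e'e + nu S with e = L - beta_sex - u.  Only
    used when the liability scale is anchored by two fixed thresholds.
    """
    e = state.L - state.beta[model.obs_sex] - state.u[model.obs_ind]
    scale = float(e @ e) + prior_nu * prior_scale
    df = len(e) + prior_nu
    if df <= 0:
        raise ModelError(f"non-positive degrees of freedom {df} for sigma2_e draw")
    return float(scale / rng.chisquare(df))


def sample_thresholds(state: LiabilityState, model: ThresholdModelData,
                      rng: np.random.Generator, n_fixed: int = 1) -> np.ndarray:
    """Draw each free threshold uniformly between the adjacent categories'
    extreme liabilities (single-site conditional); the first ``n_fixed``
    thresholds stay at their constrained values.

    A no-op when every threshold is constrained (e.g. binary traits).
    """
    t = state.thresholds.copy()
    for j in range(n_fixed, model.n_categories - 1):
        lower = float(state.L[model.category_masks[j]].max())
        upper = float(state.L[model.category_masks[j + 1]].min())
        if lower > upper:
            raise ModelError(
                f"inconsistent liabilities around threshold {j + 1}: "
                f"max(lower category) = {lower} > min(upper category) = {upper}")
        t[j] = rng.uniform(lower, upper)
    return t


# --------------------------------------------------------------------------
# the full sampler


def run_gibbs(data, ped: Pedigree | None = None,
              cfg: MCMCConfig | None = None) -> GibbsChain:
    """Run one Gibbs chain and return the retained post-burn-in samples.

    Cycles liabilities -> location effects -> genetic variance ->
    thresholds; fully reproducible given ``cfg.seed``.  ``data`` may be a
    TraitDataset (with ``ped``) or a prepared ThresholdModelData.
    """
    if cfg is None:
        cfg = MCMCConfig()
    model = data if isinstance(data, ThresholdModelData) else \
        ThresholdModelData.from_dataset(data, ped)
    rng = np.random.default_rng(cfg.seed)
    param = cfg.resolve_parameterization(model.n_categories)
    state = initialize_state(model, seed=rng, var_u_init=cfg.var_u_init,
                             var_e_init=cfg.var_e_init, parameterization=param)

    n_ret = cfg.n_retained
    var_u = np.empty(n_ret)
    var_e = np.empty(n_ret)
    thr = np.empty((n_ret, model.n_categories - 1))
    sample_ve = param == "fix_two_thresholds"
    n_fixed = 2 if sample_ve else 1
    free_thresholds = model.n_categories - 1 > n_fixed
    k = 0
    log_every = max(cfg.n_iterations // 10, 1)
    for it in range(1, cfg.n_iterations + 1):
        state.L = sample_liabilities(state, model, rng)
        state.beta, state.u = sample_location_effects(state, model, rng,
                                                      var_u_floor=cfg.var_u_floor)
        state.var_u = sample_genetic_variance(state, model, rng,
                                              prior_nu=cfg.prior_nu,
                                              prior_scale=cfg.prior_scale,
                                              var_u_floor=cfg.var_u_floor)
        if sample_ve:
            state.var_e = sample_residual_variance(state, model, rng,
                                                   prior_nu=cfg.prior_nu_e,
                                                   prior_scale=cfg.prior_scale_e)
        if free_thresholds:
            state.thresholds = sample_thresholds(state, model, rng, n_fixed=n_fixed)
        state.iteration = it
        if it > cfg.burn_in and (it - cfg.burn_in - 1) % cfg.thinning == 0:
            var_u[k] = state.var_u
            var_e[k] = state.var_e
            thr[k] = state.thresholds
            k += 1
        if it % log_every == 0:
            logger.debug("gibbs %s: iteration %d/%d, var_u=%.4f",
                         model.trait_name, it, cfg.n_iterations, state.var_u)
    chain = GibbsChain(trait_name=model.trait_name, config=cfg, seed=cfg.seed,
                       var_u=var_u[:k], var_e=var_e[:k], thresholds=thr[:k],
                       h2=heritability(var_u[:k], var_e[:k]))
    mcse = _mc_standard_error(chain.h2)
    logger.info("gibbs %s: retained %d samples, posterior mean h2 = %.4f "
                "(MC s.e. %.4f)", model.trait_name, len(chain), chain.h2.mean(), mcse)
    return chain


def run_chains(data, ped: Pedigree | None = None,
               cfg: MCMCConfig | None = None) -> list[GibbsChain]:
    """Run ``cfg.n_chains`` chains with seeds cfg.seed, cfg.seed + 1, ..."""
    if cfg is None:
        cfg = MCMCConfig()
    model = data if isinstance(data, ThresholdModelData) else \
        ThresholdModelData.from_dataset(data, ped)
    return [run_gibbs(model, cfg=replace(cfg, seed=cfg.seed + k))
            for k in range(cfg.n_chains)]


def _mc_standard_error(samples: np.ndarray) -> float:
    if samples.std() == 0:
        return 0.0
    import arviz as az
    ess = float(az.ess(az.convert_to_dataset(samples[None, :]))["x"])
    return float(samples.std(ddof=1) / np.sqrt(max(ess, 1.0)))


def heritability(var_u, var_e):
    """h2 = sigma2_u / (sigma2_u + sigma2_e); elementwise on arrays."""
    var_u = np.asarray(var_u, dtype=float)
    var_e = np.asarray(var_e, dtype=float)
    if np.any(var_e <= 0):
        raise ModelError("residual variance must be positive")
    if np.any(var_u < 0):
        raise ModelError("genetic variance must be non-negative")
    out = var_u / (var_u + var_e)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# posterior summaries and diagnostics


def posterior_mode(samples: np.ndarray, grid_size: int = 512,
                   support: tuple[float, float] = (0.0, 1.0)) -> float:
    """Mode of a Gaussian-KDE (Silverman bandwidth) on a fixed grid.

    Logs a warning when the density has more than one substantial peak
    (secondary peaks at >= 50% of the maximum).
    """
    samples = np.asarray(samples, float)
    if np.ptp(samples) == 0:
        return float(samples[0])
    kde = gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(support[0], support[1], grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if dens[0] > dens[1]:
        peaks = np.concatenate(([0], peaks))
    if dens[-1] > dens[-2]:
        peaks = np.concatenate((peaks, [grid_size - 1]))
    major = peaks[dens[peaks] >= 0.5 * dens.max()]
    if len(major) > 1:
        logger.warning("posterior appears multimodal: %d major peaks at %s",
                       len(major), np.round(grid[major], 3).tolist())
    return float(grid[dens.argmax()])


def summarize_posterior(chain, min_samples: int = 1000,
                        ci: str = "equal_tailed") -> PosteriorSummary:
    """Mode, mean, SD, and 95% credible interval of the h2 posterior.

    ``ci`` is "equal_tailed" (2.5%/97.5% quantiles, the default) or "hpd"
    (95% highest-posterior-density interval).
    """
    samples = chain.h2 if isinstance(chain, GibbsChain) else np.asarray(chain, float)
    if len(samples) < min_samples:
        raise ModelError(f"need >= {min_samples} retained samples, got {len(samples)}")
    if np.ptp(samples) == 0:
        v = float(samples[0])
        return PosteriorSummary(mode=v, mean=v, sd=0.0, ci_low=v, ci_high=v)
    mean = float(samples.mean())
    sd = float(samples.std(ddof=1))
    if ci == "equal_tailed":
        lo, hi = np.quantile(samples, [0.025, 0.975])
    elif ci == "hpd":
        import arviz as az
        lo, hi = az.hdi(samples, hdi_prob=0.95)
    else:
        raise ModelError(f"unknown ci method {ci!r}")
    return PosteriorSummary(mode=posterior_mode(samples), mean=mean, sd=sd,
                            ci_low=float(lo), ci_high=float(hi))


@dataclass
class DiagnosticsReport:
    """Cross-chain convergence diagnostics for h2."""

    psrf: float
    ess: float
    n_chains: int
    degenerate: bool
    flagged: bool

    @property
    def converged(self) -> bool:
        return not self.flagged and not self.degenerate


def convergence_diagnostics(chains: list[GibbsChain]) -> DiagnosticsReport:
    """Potential-scale-reduction (split-Rhat) and effective sample size for h2.

    Requires >= 2 chains with identical sampler settings (seeds may
    differ); flags PSRF > 1.1, and flags same-seed/identical chains as
    degenerate rather than computing a meaningless statistic.
    """
    import arviz as az

    if len(chains) < 2:
        raise ModelError("convergence diagnostics require at least 2 chains")
    base = chains[0]
    for c in chains[1:]:
        if c.config.sampler_settings() != base.config.sampler_settings() or \
                c.trait_name != base.trait_name:
            raise ModelError("chains have mismatched configurations or traits")
        if len(c) != len(base):
            raise ModelError("chains have different lengths")
    arr = np.stack([c.h2 for c in chains])
    if all(np.array_equal(arr[0], arr[i]) for i in range(1, len(chains))):
        logger.warning("chains are identical (same seed?); PSRF is degenerate")
        return DiagnosticsReport(psrf=float("nan"), ess=float("nan"),
                                 n_chains=len(chains), degenerate=True, flagged=True)
    ds = az.convert_to_dataset(arr)
    psrf = float(az.rhat(ds)["x"])
    ess = float(az.ess(ds)["x"])
    flagged = bool(psrf > 1.1)
    if flagged:
        logger.warning("PSRF %.3f > 1.1: chains have not converged", psrf)
    return DiagnosticsReport(psrf=psrf, ess=ess, n_chains=len(chains),
                             degenerate=False, flagged=flagged)
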