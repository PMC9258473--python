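"""Bayesian causal forest fits for randomized trials.

The outcome model for unit i observed at row j is

    y_ij = alpha_i + beta(x_ij) + sum_k tau_k(w_ij) 1[z_i = k] + eps_ij

where ``beta`` is a prognostic sum-of-trees surface over covariates x,
``tau_k`` is a treatment-moderation sum-of-trees surface over moderators w
for treated arm k (two-arm fits have a single tau), ``alpha_i`` is a normal
random intercept, and eps is homoskedastic Gaussian noise.  The moderator
forests carry deliberately conservative priors so that effects shrink toward
homogeneity unless the data demand otherwise.

Fitting is by Gibbs sampling: Bayesian backfitting for each forest,
conjugate normal draws for the intercept block, and conjugate inverse-gamma
draws for the two variance components.  Internally the treated indicator is
centred (z - c with c = 1/(K+1)) to decorrelate tau from the intercept;
reported ``tau`` draws are on the treated-minus-control scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import TrialDataset
from .trees import (
    CovariateSet,
    DepthPrior,
    Forest,
    ForestPrior,
    ProposalProbs,
    VariancePrior,
    sample_error_variance,
    snapshot_raw_prediction,
)


@dataclass
class BCFConfig:
    """Sampler and prior settings for a causal-forest fit.

    ``leaf_scale_prognostic`` / ``leaf_scale_moderator`` are the prior s.d.
    of the whole surface at a point, in units of the outcome s.d. (spread
    over trees internally); the moderator default of 0.3 is the conservative
    homogeneity-shrinking choice.
    """

    n_trees_prognostic: int = 200
    n_trees_moderator: int = 50
    draws: int = 2000
    burnin: int = 1000
    thin: int = 1
    seed: int = 0
    leaf_scale_prognostic: float = 1.0
    leaf_scale_moderator: float = 0.3
    depth_prior: tuple[float, float] = (0.95, 2.0)
    moderator_depth_prior: tuple[float, float] = (0.95, 2.0)
    min_leaf: int = 5
    proposal_probs: tuple[float, float, float] = (0.28, 0.28, 0.44)
    error_variance_prior: tuple[float, float] = (3.0, 0.90)  # (nu, quantile)
    intercept_scale_prior: tuple[float, float] = (2.0, 0.05)  # IG shape, scale×var(y)
    include_propensity: bool = False
    imputation: str = "median_mode"
    n_cutpoints: int = 100
    keep_moderator_forests: bool = True

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if self.burnin < 0 or self.thin < 1:
            raise ValueError("burnin must be >= 0 and thin >= 1")
        if self.leaf_scale_prognostic <= 0 or self.leaf_scale_moderator <= 0:
            raise ValueError("leaf scales must be positive")


@dataclass
class BCFPosterior:
    """Retained posterior draws from a causal-forest fit.

    All draw matrices are on the outcome's original scale.  Per draw the
    fitted mean reconstructs the model exactly:
    ``alpha[unit] + mu + sum_k tau_k * 1[arm == k]``.
    """

    alpha_draws: np.ndarray  # draws x units
    mu_draws: np.ndarray  # draws x rows (control-arm surface, includes intercept)
    tau_draws: dict[int, np.ndarray]  # arm -> draws x rows
    sigma_draws: np.ndarray
    sigma_alpha_draws: np.ndarray
    config: BCFConfig
    unit_labels: list
    unit_codes: np.ndarray
    arm_codes: np.ndarray
    row_index: np.ndarray
    moderator_columns: list[str]
    _moderator_cov: CovariateSet | None = None
    _moderator_snapshots: dict[int, list] | None = None
    time_info: dict | None = None

    @property
    def n_draws(self) -> int:
        return self.sigma_draws.size

    @property
    def arms(self) -> list[int]:
        return sorted(self.tau_draws)

    def fitted_draws(self) -> np.ndarray:
        """draws x rows posterior of the conditional mean (reconstruction)."""
        out = self.alpha_draws[:, self.unit_codes] + self.mu_draws
        for k, tau in self.tau_draws.items():
            out = out + tau * (self.arm_codes == k)
        return out

    def ate_draws(self, arm: int = 1, row_subset: np.ndarray | None = None) -> np.ndarray:
        if arm not in self.tau_draws:
            raise ValueError(f"unknown arm {arm!r}; fitted arms are {self.arms}")
        tau = self.tau_draws[arm]
        if row_subset is None:
            return tau.mean(axis=1)
        row_subset = np.asarray(row_subset)
        if row_subset.dtype == bool:
            if not row_subset.any():
                raise ValueError("empty row subset")
            return tau[:, row_subset].mean(axis=1)
        if row_subset.size == 0:
            raise ValueError("empty row subset")
        return tau[:, row_subset].mean(axis=1)


def impute_covariates(
    dataset: TrialDataset,
    strategy: str = "median_mode",
    rng: np.random.Generator | None = None,
) -> TrialDataset:
    """Complete missing covariate / moderator cells (intent-to-treat style).

    The default deterministic strategy fills numeric columns with the
    observed median and categorical columns with the modal category, and adds
    a ``<name>_missing`` indicator covariate per imputed variable.  Row order
    and count are preserved.
    """
    if strategy != "median_mode":
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    if dataset.frame[dataset.arm].isna().any():
        raise ValueError("arm column must be complete before imputation")
    mask = dataset.missing_mask()
    if not mask.to_numpy().any():
        return dataset
    frame = dataset.frame.copy()
    covariates = list(dataset.covariates)
    for col in mask.columns[mask.any(axis=0)]:
        series = frame[col]
        if series.isna().all():
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        indicator = f"{col}_missing"
        frame[indicator] = series.isna().astype(float)
        if pd.api.types.is_numeric_dtype(series):
            frame[col] = series.fillna(series.median())
        else:
            frame[col] = series.fillna(series.mode(dropna=True).iloc[0])
        if indicator not in covariates:
            covariates.append(indicator)
    return dataset.with_frame(frame, covariates=covariates)


# --------------------------------------------------------------------------
# the Gibbs engine (shared by two-arm, multi-arm and targeted-smoothing fits)
# --------------------------------------------------------------------------


def _prepare_covariates(dataset: TrialDataset, config: BCFConfig):
    ds = dataset
    if ds.has_missing():
        ds = impute_covariates(ds, config.imputation)
    x = ds.covariate_frame()
    if config.include_propensity:
        # randomized assignment: constant-by-design propensity, no estimation
        x = x.assign(propensity=1.0 / (ds.n_arms + 1))
    w = ds.moderator_frame()
    return ds, x, w


def _run_gibbs(
    dataset: TrialDataset,
    config: BCFConfig,
    basis_builder=None,
) -> BCFPosterior:
    ds, x_frame, w_frame = _prepare_covariates(dataset, config)
    y = ds.y
    n = y.size
    arm = ds.arm_codes
    K = ds.n_arms
    counts = np.bincount(arm, minlength=K + 1)
    if (counts == 0).any():
        empty = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"arm {empty} has no observations")
    if K < 1:
        raise ValueError("all rows are in one arm; a treated arm is required")

    rng = np.random.default_rng(config.seed)
    ym, ys = float(y.mean()), float(y.std())
    if ys <= 0:
        ys = 1.0
    ystd = (y - ym) / ys

    if x_frame.shape[1] == 0:
        x_frame = pd.DataFrame({"_const": np.zeros(n)})
    if w_frame.shape[1] == 0:
        w_frame = pd.DataFrame({"_const": np.zeros(n)})
    x_cov = CovariateSet(x_frame, config.n_cutpoints)
    w_cov = CovariateSet(w_frame, config.n_cutpoints)

    basis = basis_builder(ds) if basis_builder is not None else None
    if basis is None:
        prog_cov_mat = None
        bdim = 1
        prog_leaf_cov = mod_leaf_cov = None
        prog_basis = mod_basis = None
    else:
        prog_basis, mod_basis, prog_leaf_cov, mod_leaf_cov, time_info = basis
        bdim = prog_basis.shape[1]

    a_struct, b_struct = config.depth_prior
    am_struct, bm_struct = config.moderator_depth_prior
    m_p, m_m = config.n_trees_prognostic, config.n_trees_moderator
    s_prog = config.leaf_scale_prognostic / np.sqrt(m_p)
    s_mod = config.leaf_scale_moderator / np.sqrt(m_m)
    props = ProposalProbs(*config.proposal_probs)

    def make_prior(scale, a, b, leaf_cov):
        cov = None if leaf_cov is None else scale**2 * leaf_cov
        return ForestPrior(
            leaf_scale=scale,
            depth_prior=DepthPrior(a, b),
            proposals=props,
            min_leaf=config.min_leaf,
            leaf_cov=cov,
        )

    prog_prior = make_prior(s_prog, a_struct, b_struct, prog_leaf_cov)
    mod_prior = make_prior(s_mod, am_struct, bm_struct, mod_leaf_cov)

    c = 1.0 / (K + 1)
    prog_forest = Forest(x_cov, m_p, prog_prior, basis=prog_basis)
    mod_forests = {
        k: Forest(w_cov, m_m, mod_prior, mult=(arm == k) - c, basis=mod_basis)
        for k in range(1, K + 1)
    }

    unit_codes = ds.unit_codes
    n_units = int(unit_codes.max()) + 1
    unit_counts = np.bincount(unit_codes, minlength=n_units).astype(float)
    single_obs = bool((unit_counts <= 1).all())
    alpha = np.zeros(n_units)

    nu, q = config.error_variance_prior
    var_prior = VariancePrior.from_data(ystd, nu=nu, q=q)
    a0_alpha, b0_scale = config.intercept_scale_prior
    b0_alpha = b0_scale * float(np.var(ystd))
    sigma2 = max(float(np.var(ystd)), 1e-8)
    sigma2_alpha = 0.0 if single_obs else 0.25

    resid = ystd.copy()  # all fits start at zero

    n_keep = config.draws
    total = config.burnin + n_keep * config.thin
    alpha_draws = np.empty((n_keep, n_units))
    mu_draws = np.empty((n_keep, n))
    tau_draws = {k: np.empty((n_keep, n)) for k in range(1, K + 1)}
    sigma_draws = np.empty(n_keep)
    sigma_alpha_draws = np.empty(n_keep)
    snapshots = {k: [] for k in range(1, K + 1)} if config.keep_moderator_forests else None

    kept = 0
    for sweep in range(total):
        sigma = float(np.sqrt(sigma2))
        resid = prog_forest.backfit_sweep(resid, sigma, rng)
        for k in range(1, K + 1):
            resid = mod_forests[k].backfit_sweep(resid, sigma, rng)
        if not single_obs:
            e = resid + alpha[unit_codes]
            sums = np.bincount(unit_codes, weights=e, minlength=n_units)
            prec = unit_counts / sigma2 + (
                1.0 / sigma2_alpha if sigma2_alpha > 0 else 1e12
            )
            mean = (sums / sigma2) / prec
            alpha = mean + rng.standard_normal(n_units) / np.sqrt(prec)
            resid = e - alpha[unit_codes]
            sigma2_alpha = float(
                (b0_alpha + 0.5 * float(alpha @ alpha))
                / rng.gamma(a0_alpha + 0.5 * n_units)
            )
        sigma2 = sample_error_variance(resid, var_prior, rng)

        if sweep >= config.burnin and (sweep - config.burnin) % config.thin == 0:
            prog_raw = prog_forest.raw_prediction()
            mod_raw = {k: f.raw_prediction() for k, f in mod_forests.items()}
            mu = prog_raw - c * sum(mod_raw.values())
            alpha_draws[kept] = ys * alpha
            mu_draws[kept] = ym + ys * mu
            for k in range(1, K + 1):
                tau_draws[k][kept] = ys * mod_raw[k]
                if snapshots is not None:
                    snapshots[k].append(mod_forests[k].snapshot())
            sigma_draws[kept] = ys * np.sqrt(sigma2)
            sigma_alpha_draws[kept] = ys * np.sqrt(sigma2_alpha)
            kept += 1
            if kept == n_keep:
                break

    post = BCFPosterior(
        alpha_draws=alpha_draws,
        mu_draws=mu_draws,
        tau_draws=tau_draws,
        sigma_draws=sigma_draws,
        sigma_alpha_draws=sigma_alpha_draws,
        config=config,
        unit_labels=ds.unit_labels,
        unit_codes=unit_codes,
        arm_codes=arm,
        row_index=np.arange(n),
        moderator_columns=list(w_frame.columns),
        _moderator_cov=w_cov,
        _moderator_snapshots=snapshots,
        time_info=None if basis is None else time_info,
    )
    if basis is not None:
        post.time_info["snapshot_scale"] = ys
    post._tau_scale = ys  # noqa: SLF001 - internal rescaling factor
    return post


def fit_bcf(dataset: TrialDataset, config: BCFConfig | None = None) -> BCFPosterior:
    """Fit the two-arm Bayesian causal forest.

    Requires exactly one treated arm (arm codes in {0, 1}); use
    :func:`trialforest.extensions.fit_multiarm_bcf` for more arms.
    """
    config = config or BCFConfig()
    if dataset.n_arms != 1:
        raise ValueError(
            f"fit_bcf handles two-arm trials; found K = {dataset.n_arms} "
            "treated arms (use fit_multiarm_bcf)"
        )
    return _run_gibbs(dataset, config)


def predict_effect_surface(
    posterior: BCFPosterior, new_moderators: pd.DataFrame, arm: int = 1
) -> np.ndarray:
    """Per-draw moderator-forest evaluations at new rows (outcome units).

    Rows carrying a categorical level unseen in fitting are routed to the
    larger child of any split on that variable, with a warning.
    """
    if posterior._moderator_snapshots is None:
        raise ValueError("fit was run without keep_moderator_forests")
    if arm not in posterior.tau_draws:
        raise ValueError(f"unknown arm {arm!r}")
    if posterior.time_info is not None:
        raise ValueError("time-smoothed fits are evaluated with effect_curve")
    cov = posterior._moderator_cov
    values, unseen = cov.encode_like(new_moderators)
    if unseen.any():
        warnings.warn(
            "unseen categorical level(s); routing to the larger child",
            stacklevel=2,
        )
    scale = getattr(posterior, "_tau_scale", 1.0)
    out = np.empty((posterior.n_draws, len(new_moderators)))
    for d, snap in enumerate(posterior._moderator_snapshots[arm]):
        out[d] = scale * snapshot_raw_prediction(snap, values, unseen)
    return out
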