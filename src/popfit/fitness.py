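"""Hierarchical Bayesian fitness inference from barcode count trajectories.

The generative model, per condition, follows exponential relative growth of
lineage frequencies between samplings separated by ``tau`` generations:

    f_{t+1}(j) = f_t(j) exp((s(j) - s̄_t) tau)

so the observed log-frequency increment of edit j in replicate n is

    y_{jnt} = log f_{t+1}(j,n) - log f_t(j,n)
            ~ Normal((s(j,n) - s̄_{tn}) tau,  V)

where V has three components: the delta-method covariance of log multinomial
proportions (variance 1/r_t + 1/r_{t+1}, covariance -1/r_t between the two
increments sharing timepoint t's counts), a count-scaled diagonal term
gamma^2 (1/r_t + 1/r_{t+1})/2 capturing transfer-bottleneck drift — whose
variance is inversely proportional to lineage abundance, like read noise —
and sequencing overdispersion, plus a homoskedastic floor sigma^2.
Replicate-level fitness values are drawn around an edit-level hyperfitness,
s(j,n) ~ Normal(phi(j), sigma_hyper^2), with weakly informative priors
phi ~ N(0, 0.5^2) and s̄_t ~ N(0, 0.5^2).  Non-editing neutral anchor
barcodes have s = 0 exactly, which identifies the mean-fitness nuisance
series s̄_t.

Conditional on the three variance hyperparameters (sigma, gamma,
sigma_hyper) this model is jointly Gaussian, so the posterior over
(phi, s, s̄) is available exactly by block elimination: each edit's (phi, s)
block is marginalized analytically to obtain the low-dimensional marginal of
s̄, and edit-level marginals are then recovered with their full sensitivity
to s̄ uncertainty.  The default ``gaussian`` engine estimates the
hyperparameters by maximizing the collapsed marginal posterior
(deterministic, no Monte Carlo); the ``mcmc`` engine samples them with emcee
and mixes the exact Gaussian conditionals, i.e. a Rao-Blackwellized sampler
of the full posterior.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "FitnessPosterior",
    "remove_outlier_barcodes",
    "aggregate",
    "naive_frequencies",
    "fit_hierarchical",
    "classify",
    "replicate_concordance",
]


@dataclass
class ModelConfig:
    """Priors, pseudocount and engine settings for the hierarchical model."""

    prior_scale_phi: float = 0.5
    prior_scale_mean_fitness: float = 0.5
    sigma_hyper_scale: float = 0.05  # HalfNormal prior scale on replicate deviation
    sigma_scale: float = 1.0  # HalfNormal prior scale on residual noise
    drift_scale: float = 2.0  # HalfNormal prior scale on the count-scaled noise factor
    pseudocount: float = 0.5
    interval_mass: float = 0.95
    # re-center effects on the empirical null estimated from the spike of
    # no-effect edits (in addition to the non-editing anchors)
    empirical_null: bool = True
    engine: str = "gaussian"  # or "mcmc"
    mcmc_walkers: int = 8
    mcmc_steps: int = 500
    mcmc_burn: int = 150
    mcmc_thin: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "prior_scale_phi",
            "prior_scale_mean_fitness",
            "sigma_hyper_scale",
            "sigma_scale",
            "drift_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.interval_mass < 1.0:
            raise ValueError("interval_mass must lie in (0, 1)")
        if self.engine not in ("gaussian", "mcmc"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class FitnessPosterior:
    """Posterior summaries of hyperfitness and per-replicate fitness.

    ``summary`` has one row per (edit_id, condition) with columns
    ``phi_mean``, ``phi_sd``, ``is_neutral_anchor`` and, after
    :func:`classify`, ``ci_lower``, ``ci_upper``, ``classification``.
    ``rep_fitness`` has one row per (edit_id, condition, replicate) with
    ``s_mean``, ``s_sd``.
    """

    summary: pd.DataFrame
    rep_fitness: pd.DataFrame
    interval_mass: float = 0.95
    edit_flags: pd.DataFrame | None = None

    def condition_table(self, condition: str) -> pd.DataFrame:
        return self.summary[self.summary.condition == condition]


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------


def remove_outlier_barcodes(
    table: pd.DataFrame,
    neutral_ids: Iterable[str] = (),
    per_stream: bool = True,
    return_log: bool = False,
):
    """Drop the highest-read-count barcode of every multi-barcode editing edit.

    Spontaneous beneficial mutations hitchhiking on a single barcode lineage
    can dominate an edit's reads; discarding the top barcode per edit removes
    most of that signal.  Edits with a single barcode and neutral anchors are
    untouched.  By default removal operates per (replicate, condition)
    stream on reads summed over timepoints; ``per_stream=False`` removes one
    barcode per edit globally.  Ties are broken by removing the
    lexicographically smallest barcode_id among the tied maxima.
    """
    neutral = set(neutral_ids)
    group_cols = ["edit_id", "replicate", "condition"] if per_stream else ["edit_id"]
    totals = (
        table.groupby(group_cols + ["barcode_id"], observed=True)["reads"].sum().reset_index()
    )
    drop_keys: list[tuple] = []
    for key, grp in totals.groupby(group_cols, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        if key[0] in neutral or len(grp) < 2:
            continue
        top = grp["reads"].max()
        victim = grp.loc[grp["reads"] == top, "barcode_id"].min()
        drop_keys.append(key + (victim,))
    if not drop_keys:
        out = table.copy()
        removal_log = pd.DataFrame(columns=group_cols + ["barcode_id"])
    else:
        removal_log = pd.DataFrame(drop_keys, columns=group_cols + ["barcode_id"])
        idx_cols = group_cols + ["barcode_id"]
        merged = table.merge(removal_log.assign(_drop=True), on=idx_cols, how="left")
        out = table.loc[merged["_drop"].isna().to_numpy()].reset_index(drop=True)
    logger.info(
        "outlier barcode removal: dropped %d barcode-stream combinations", len(drop_keys)
    )
    return (out, removal_log) if return_log else out


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Sum reads over each edit's retained barcodes per (replicate, condition, t).

    Returns a table with columns (edit_id, replicate, condition, timepoint,
    reads) on the full edit × stream × timepoint grid; edits absent at every
    timepoint of a stream are retained with zeros and logged.
    """
    agg = (
        table.groupby(["edit_id", "replicate", "condition", "timepoint"], observed=True)[
            "reads"
        ]
        .sum()
        .reset_index()
    )
    edits = sorted(table["edit_id"].unique())
    grid = pd.MultiIndex.from_product(
        [
            edits,
            sorted(table["replicate"].unique()),
            sorted(table["condition"].unique()),
            sorted(table["timepoint"].unique()),
        ],
        names=["edit_id", "replicate", "condition", "timepoint"],
    )
    agg = agg.set_index(["edit_id", "replicate", "condition", "timepoint"]).reindex(
        grid, fill_value=0
    ).reset_index()
    zero = agg.groupby("edit_id", observed=True)["reads"].sum()
    dead = zero[zero == 0].index.tolist()
    if dead:
        logger.warning("edits with zero reads everywhere: %s", dead)
    return agg


def naive_frequencies(agg: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Plug-in frequency estimates f_t(j) = (r + pc) / sum_k (r_k + pc).

    Raises when a (replicate, condition, timepoint) has zero total raw reads.
    """
    out = agg.copy()
    totals = out.groupby(["replicate", "condition", "timepoint"], observed=True)["reads"]
    raw_tot = totals.transform("sum")
    bad = out.loc[raw_tot == 0, ["replicate", "condition", "timepoint"]].drop_duplicates()
    if len(bad):
        r, c, t = bad.iloc[0]
        raise ValueError(f"all-zero timepoint: replicate={r} condition={c} t={t}")
    shifted = out["reads"] + pseudocount
    tot = shifted.groupby(
        [out["replicate"], out["condition"], out["timepoint"]], observed=True
    ).transform("sum")
    out["frequency"] = shifted / tot
    return out


# ---------------------------------------------------------------------------
# Gaussian machinery
# ---------------------------------------------------------------------------


class _ConditionData:
    """Increment observations for one condition, blocked per edit."""

    def __init__(self, agg: pd.DataFrame, condition: str, neutral: set, cfg: ModelConfig, tau: float):
        sub = agg[agg.condition == condition]
        self.edits = sorted(sub.edit_id.unique())
        self.reps = sorted(sub.replicate.unique())
        self.tps = sorted(sub.timepoint.unique())
        T, M = len(self.tps), len(self.reps)
        self.T, self.M = T, M
        self.tau = tau
        self.neutral_mask = np.array([e in neutral for e in self.edits])
        e_ix = {e: i for i, e in enumerate(self.edits)}
        r_ix = {r: i for i, r in enumerate(self.reps)}
        t_ix = {t: i for i, t in enumerate(self.tps)}

        r = np.full((len(self.edits), M, T), np.nan)
        r[
            sub.edit_id.map(e_ix).to_numpy(),
            sub.replicate.map(r_ix).to_numpy(),
            sub.timepoint.map(t_ix).to_numpy(),
        ] = sub.reads.to_numpy(dtype=float)
        rt = r + cfg.pseudocount
        with np.errstate(invalid="ignore", divide="ignore"):
            logf = np.log(rt) - np.log(np.nansum(rt, axis=0, keepdims=True))
        self.y = logf[:, :, 1:] - logf[:, :, :-1]  # (E, M, T-1)
        self.w = 1.0 / rt[:, :, 1:] + 1.0 / rt[:, :, :-1]
        self.valid = np.isfinite(self.y) & np.isfinite(self.w)
        self.d = M * (T - 1)

        # per-edit observation blocks; W is the delta-method covariance of the
        # log-frequency increments: Var = 1/r_t + 1/r_{t+1} and
        # Cov(y_t, y_{t+1}) = -1/r_{t+1} for consecutive transitions of the
        # same replicate (they share the middle timepoint's counts)
        self.blocks = []
        for e in range(len(self.edits)):
            n_idx, t_idx = np.nonzero(self.valid[e])
            y = self.y[e, n_idx, t_idx]
            upos = n_idx * (T - 1) + t_idx
            same_rep = (n_idx[:, None] == n_idx[None, :]).astype(float)
            W = np.diag(self.w[e, n_idx, t_idx])
            for i in range(len(y)):
                for j in range(i + 1, len(y)):
                    if n_idx[i] == n_idx[j] and abs(t_idx[i] - t_idx[j]) == 1:
                        mid = max(t_idx[i], t_idx[j])  # shared timepoint index
                        W[i, j] = W[j, i] = -1.0 / rt[e, n_idx[i], mid]
            # count-scaled diagonal for drift/overdispersion: bottleneck drift
            # variance is ~ 1/(f N_b) per transition, i.e. proportional to the
            # same 1/r terms as read noise but without the shared-timepoint
            # off-diagonal structure
            whalf = 0.5 * self.w[e, n_idx, t_idx]
            self.blocks.append((y, W, whalf, upos, n_idx, same_rep))


def _collapsed_logpost(theta: np.ndarray, data: _ConditionData, cfg: ModelConfig, want_posterior: bool = False):
    """Collapsed log posterior of the noise hyperparameters.

    theta = (log sigma, log gamma, log sigma_hyper): residual noise floor,
    count-scaled drift/overdispersion factor, and replicate-level fitness
    deviation.  (phi, s, s̄) are integrated out analytically.

    With ``want_posterior`` also returns the Gaussian posterior pieces needed
    to reconstruct all marginals at this hyperparameter value.
    """
    sigma2 = float(np.exp(2.0 * theta[0]))
    gamma2 = float(np.exp(2.0 * theta[1]))
    kappa2 = float(np.exp(2.0 * theta[2]))
    a2 = cfg.prior_scale_phi**2
    b2 = cfg.prior_scale_mean_fitness**2
    tau = data.tau
    d = data.d

    P = np.zeros((d, d))
    P[np.diag_indices(d)] += 1.0 / b2
    h = np.zeros(d)
    ll = 0.0
    cinv_cache = [] if want_posterior else None

    for e, (y, W, whalf, upos, n_idx, same_rep) in enumerate(data.blocks):
        if y.size == 0:
            if want_posterior:
                cinv_cache.append(None)
            continue
        V = W + np.diag(gamma2 * whalf + sigma2)
        if data.neutral_mask[e]:
            C = V
        else:
            C = tau**2 * (a2 + kappa2 * same_rep) + V
        try:
            cf = cho_factor(C, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf if not want_posterior else (-np.inf, None)
        Cinv = cho_solve(cf, np.eye(len(y)))
        ll -= float(np.sum(np.log(np.diag(cf[0])))) + 0.5 * float(y @ (Cinv @ y))
        P[np.ix_(upos, upos)] += tau**2 * Cinv
        h[upos] -= tau * (Cinv @ y)
        if want_posterior:
            cinv_cache.append(Cinv)

    cfP = cho_factor(P, lower=True)
    Pinv_h = cho_solve(cfP, h)
    ll += 0.5 * float(h @ Pinv_h) - float(np.sum(np.log(np.diag(cfP[0]))))
    ll -= 0.5 * d * np.log(b2)
    # HalfNormal hyperpriors (log-scale jacobians included)
    ll += -0.5 * sigma2 / cfg.sigma_scale**2 + 0.5 * np.log(sigma2)
    ll += -0.5 * gamma2 / cfg.drift_scale**2 + 0.5 * np.log(gamma2)
    ll += -0.5 * kappa2 / cfg.sigma_hyper_scale**2 + 0.5 * np.log(kappa2)
    if not want_posterior:
        return ll
    Pinv = cho_solve(cfP, np.eye(d))
    return ll, (sigma2, gamma2, kappa2, Pinv_h, Pinv, cinv_cache)


def _edit_posteriors(data: _ConditionData, cfg: ModelConfig, pieces):
    """Exact Gaussian marginals of phi and s given hyperparameters.

    Returns, besides the summaries, the decomposition of each phi variance
    into the per-edit (conditional on s̄) part and the part propagated from
    the mean-fitness posterior — the latter is shared noise across edits.
    """
    sigma2, gamma2, kappa2, m_u, Cov_u, _ = pieces
    a2 = cfg.prior_scale_phi**2
    tau = data.tau
    M = data.M
    phi_var_idio = np.zeros(len(data.edits))
    phi_var_common = np.zeros(len(data.edits))
    phi_mean = np.zeros(len(data.edits))
    phi_sd = np.zeros(len(data.edits))
    s_mean = np.zeros((len(data.edits), M))
    s_sd = np.zeros((len(data.edits), M))

    lam0 = np.zeros((M + 1, M + 1))
    lam0[0, 0] = 1.0 / a2 + M / kappa2
    lam0[0, 1:] = lam0[1:, 0] = -1.0 / kappa2
    lam0[np.arange(1, M + 1), np.arange(1, M + 1)] = 1.0 / kappa2

    for e, (y, W, whalf, upos, n_idx, _) in enumerate(data.blocks):
        if data.neutral_mask[e]:
            continue
        lam = lam0.copy()
        b = np.zeros(M + 1)
        Gw = np.zeros((M + 1, data.d))
        if y.size:
            Vinv = np.linalg.inv(W + np.diag(gamma2 * whalf + sigma2))
            A = np.zeros((len(y), M + 1))
            A[np.arange(len(y)), 1 + n_idx] = tau
            AtVinv = A.T @ Vinv
            lam += AtVinv @ A
            b += AtVinv @ (y + tau * m_u[upos])
            np.add.at(Gw.T, upos, tau * AtVinv.T)
        lam_inv = np.linalg.inv(lam)
        mean = lam_inv @ b
        G = lam_inv @ Gw
        cov = lam_inv + G @ Cov_u @ G.T
        phi_var_idio[e] = max(lam_inv[0, 0], 0.0)
        phi_var_common[e] = max(cov[0, 0] - lam_inv[0, 0], 0.0)
        phi_mean[e], phi_sd[e] = mean[0], np.sqrt(max(cov[0, 0], 0.0))
        s_mean[e] = mean[1:]
        s_sd[e] = np.sqrt(np.clip(np.diag(cov)[1:], 0.0, None))
    return phi_mean, phi_sd, s_mean, s_sd, phi_var_idio, phi_var_common


def _empirical_null_recenter(phi_mean, var_idio, var_common, neutral_mask):
    """Estimate the shared null-level offset from the spike of neutral edits.

    The mean-fitness level is identified only through the non-editing anchor
    lineages, so its estimation error shifts every edit's fitness by the
    same amount.  Screens of natural variants contain a large class of edits
    with no fitness effect; the center of that spike re-measures the null
    level far more precisely than the anchors alone.  A two-component EM
    (spike at the level with per-edit measurement noise; broad Gaussian slab
    for real effects) estimates the level with the anchor-based value as a
    Gaussian prior.  Returns (offset, offset variance, applied flag);
    skipped for small screens or when no credible spike is found.
    """
    x = phi_mean[~neutral_mask]
    v = np.maximum(var_idio[~neutral_mask], 1e-12)
    sigma_l2 = float(np.mean(var_common[~neutral_mask])) + 1e-12
    if len(x) < 20:
        return 0.0, sigma_l2, False
    level, p0 = 0.0, 0.5
    mu_slab = float(np.mean(x))
    b2 = max(float(np.var(x)), 1e-6)
    resp = np.full(len(x), 0.5)
    for _ in range(300):
        d0 = p0 * stats.norm.pdf(x, level, np.sqrt(v))
        d1 = (1.0 - p0) * stats.norm.pdf(x, mu_slab, np.sqrt(b2 + v))
        tot = d0 + d1
        tot[tot <= 0] = 1e-300
        resp = d0 / tot
        w = resp / v
        new_level = float(np.sum(w * x) / (np.sum(w) + 1.0 / sigma_l2))
        p0 = float(np.mean(resp))
        ws = 1.0 - resp
        if ws.sum() > 1e-9:
            mu_slab = float(np.sum(ws * x) / ws.sum())
            b2 = max(float(np.sum(ws * (x - mu_slab) ** 2) / ws.sum() - np.mean(v)), 1e-6)
        if abs(new_level - level) < 1e-10:
            level = new_level
            break
        level = new_level
    var_level = 1.0 / (np.sum(resp / v) + 1.0 / sigma_l2)
    credible_spike = resp.sum() >= 5.0 and p0 >= 0.02
    sane = abs(level) <= 6.0 * np.sqrt(sigma_l2)
    if not (credible_spike and sane):
        return 0.0, sigma_l2, False
    return float(level), float(var_level), True


def _fit_condition(data: _ConditionData, cfg: ModelConfig):
    """Hyperparameter estimation + exact marginals for one condition."""
    x0 = np.array([np.log(0.01), np.log(1.0), np.log(0.01)])
    res = optimize.minimize(
        lambda th: -_collapsed_logpost(th, data, cfg),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 600},
    )
    ll, pieces = _collapsed_logpost(res.x, data, cfg, want_posterior=True)
    diag = {
        "converged": bool(res.success),
        "engine": "gaussian",
        "sigma": float(np.exp(res.x[0])),
        "drift_factor": float(np.exp(res.x[1])),
        "sigma_hyper": float(np.exp(res.x[2])),
        "log_posterior": float(ll),
        "n_obs": int(data.valid.sum()),
        "n_opt_iterations": int(res.nit),
    }
    if cfg.engine == "gaussian":
        phi_mean, phi_sd, s_mean, s_sd, v_idio, v_common = _edit_posteriors(data, cfg, pieces)
        m_u, Cov_u = pieces[3], pieces[4]
        m_u = m_u.copy()
        if cfg.empirical_null:
            level, var_level, applied = _empirical_null_recenter(
                phi_mean, v_idio, v_common, data.neutral_mask
            )
            diag.update(
                null_level_offset=float(level),
                null_level_sd=float(np.sqrt(var_level)),
                empirical_null_applied=bool(applied),
            )
            if applied:
                phi_mean = phi_mean - level
                s_mean = s_mean - level
                m_u = m_u + level
                phi_sd = np.sqrt(v_idio + var_level)
                s_var = np.maximum(s_sd**2 - v_common[:, None] + var_level, 1e-16)
                s_sd = np.sqrt(s_var)
        return phi_mean, phi_sd, s_mean, s_sd, m_u, np.sqrt(np.diag(Cov_u)), diag

    # mcmc engine: sample (log sigma, log sigma_hyper), mix Gaussian conditionals
    import emcee

    nw = cfg.mcmc_walkers
    rng = np.random.default_rng(cfg.seed)
    p0 = res.x + 0.05 * rng.standard_normal((nw, 3))
    sampler = emcee.EnsembleSampler(nw, 3, _collapsed_logpost, args=(data, cfg))
    state = emcee.State(p0, random_state=np.random.RandomState(cfg.seed).get_state())
    sampler.run_mcmc(state, cfg.mcmc_steps, progress=False)
    chain = sampler.get_chain(discard=cfg.mcmc_burn, thin=cfg.mcmc_thin, flat=True)
    diag.update(
        engine="mcmc",
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        n_hyper_samples=int(len(chain)),
        converged=bool(0.1 < np.mean(sampler.acceptance_fraction) < 0.95),
    )
    # mixture over hyperparameter draws (cap the number of mixture components)
    take = chain[:: max(1, len(chain) // 40)]
    mixes = []
    for th in take:
        _, pieces_i = _collapsed_logpost(th, data, cfg, want_posterior=True)
        mixes.append(_edit_posteriors(data, cfg, pieces_i) + (pieces_i[3], np.sqrt(np.diag(pieces_i[4]))))
    pm = np.mean([m[0] for m in mixes], axis=0)
    pv = np.mean([m[1] ** 2 + m[0] ** 2 for m in mixes], axis=0) - pm**2
    sm = np.mean([m[2] for m in mixes], axis=0)
    sv = np.mean([m[3] ** 2 + m[2] ** 2 for m in mixes], axis=0) - sm**2
    um = np.mean([m[6] for m in mixes], axis=0)
    uv = np.mean([m[7] ** 2 + m[6] ** 2 for m in mixes], axis=0) - um**2
    pm, pv, sm, um = pm.copy(), pv.copy(), sm.copy(), um.copy()
    if cfg.empirical_null:
        v_idio = np.mean([m[4] for m in mixes], axis=0)
        v_common = np.mean([m[5] for m in mixes], axis=0)
        level, var_level, applied = _empirical_null_recenter(
            pm, v_idio + np.clip(pv - v_idio - v_common, 0, None), v_common, data.neutral_mask
        )
        diag.update(
            null_level_offset=float(level),
            null_level_sd=float(np.sqrt(var_level)),
            empirical_null_applied=bool(applied),
        )
        if applied:
            pm -= level
            sm -= level
            um += level
            pv = np.clip(pv - v_common, 1e-16, None) + var_level
            sv = np.clip(sv - v_common[:, None], 1e-16, None) + var_level
    return pm, np.sqrt(np.clip(pv, 0, None)), sm, np.sqrt(np.clip(sv, 0, None)), um, np.sqrt(
        np.clip(uv, 0, None)
    ), diag


def fit_hierarchical(
    agg: pd.DataFrame,
    neutral_ids: Iterable[str],
    cfg: ModelConfig | None = None,
    tau: float = 4.3,
) -> tuple[FitnessPosterior, pd.DataFrame, dict]:
    """Fit the hierarchical fitness model to aggregated counts.

    Conditions are fitted independently; all replicates of a condition enter
    one joint inference.  Returns the posterior, the mean-fitness series
    (one row per replicate × condition × transition) and a diagnostics dict
    keyed by condition.  Deterministic given ``cfg.seed`` and engine
    settings.
    """
    cfg = cfg or ModelConfig()
    cfg.validate()
    neutral = set(neutral_ids)
    if not neutral:
        raise ValueError("at least one neutral anchor edit is required")
    conditions = sorted(agg.condition.unique())

    sum_rows, rep_rows, sbar_rows = [], [], []
    diagnostics: dict[str, dict] = {}
    for cond in conditions:
        data = _ConditionData(agg, cond, neutral, cfg, tau)
        if data.T < 2:
            raise ValueError(f"condition {cond}: need >= 2 timepoints")
        phi_mean, phi_sd, s_mean, s_sd, m_u, sd_u, diag = _fit_condition(data, cfg)
        if not diag["converged"]:
            logger.warning("condition %s: inference did not converge", cond)
        diagnostics[cond] = diag
        for e, eid in enumerate(data.edits):
            anchor = bool(data.neutral_mask[e])
            sum_rows.append(
                (
                    eid,
                    cond,
                    0.0 if anchor else phi_mean[e],
                    0.0 if anchor else phi_sd[e],
                    anchor,
                )
            )
            for n, rep in enumerate(data.reps):
                rep_rows.append(
                    (
                        eid,
                        cond,
                        rep,
                        0.0 if anchor else s_mean[e, n],
                        0.0 if anchor else s_sd[e, n],
                    )
                )
        for n, rep in enumerate(data.reps):
            for t in range(data.T - 1):
                k = n * (data.T - 1) + t
                sbar_rows.append((rep, cond, t, m_u[k], sd_u[k]))

    posterior = FitnessPosterior(
        summary=pd.DataFrame(
            sum_rows, columns=["edit_id", "condition", "phi_mean", "phi_sd", "is_neutral_anchor"]
        ),
        rep_fitness=pd.DataFrame(
            rep_rows, columns=["edit_id", "condition", "replicate", "s_mean", "s_sd"]
        ),
        interval_mass=cfg.interval_mass,
    )
    mean_fitness = pd.DataFrame(
        sbar_rows, columns=["replicate", "condition", "timepoint", "mean_fitness", "sd"]
    )
    return posterior, mean_fitness, diagnostics


def classify(post: FitnessPosterior, interval_mass: float | None = None) -> FitnessPosterior:
    """Classify edits per condition by whether the credible interval excludes 0.

    Beneficial if the interval's lower bound is > 0, deleterious if the upper
    bound is < 0, neutral otherwise.  Also derives, per edit, the number of
    conditions with a non-neutral call and the "non-neutral in >= 1 / >= 2
    conditions" flags used to define focal variant sets.
    """
    mass = post.interval_mass if interval_mass is None else interval_mass
    if not 0.0 < mass < 1.0:
        raise ValueError("interval mass must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + mass / 2.0)
    s = post.summary.copy()
    s["ci_lower"] = s.phi_mean - z * s.phi_sd
    s["ci_upper"] = s.phi_mean + z * s.phi_sd
    s.loc[s.is_neutral_anchor, ["ci_lower", "ci_upper"]] = 0.0
    s["classification"] = "neutral"
    s.loc[s.ci_lower > 0, "classification"] = "beneficial"
    s.loc[s.ci_upper < 0, "classification"] = "deleterious"
    nn = (
        (s.classification != "neutral")
        .groupby(s.edit_id)
        .sum()
        .rename("n_conditions_non_neutral")
        .reset_index()
    )
    nn["non_neutral_ge1"] = nn.n_conditions_non_neutral >= 1
    nn["non_neutral_ge2"] = nn.n_conditions_non_neutral >= 2
    beneficial_any = (
        (s.classification == "beneficial").groupby(s.edit_id).any().rename("beneficial_ge1")
    )
    flags = nn.merge(beneficial_any.reset_index(), on="edit_id")
    return FitnessPosterior(
        summary=s, rep_fitness=post.rep_fitness, interval_mass=mass, edit_flags=flags
    )


def replicate_concordance(post: FitnessPosterior) -> pd.DataFrame:
    """Spearman rank correlation of per-replicate fitness between replicate pairs.

    Restricted to edits classified non-neutral in the given condition, as
    near-zero estimates carry no rank information.  Pairs with fewer than
    three non-neutral edits are reported with NaN and flagged.
    """
    if post.edit_flags is None or "classification" not in post.summary:
        raise ValueError("run classify() before replicate_concordance()")
    rows = []
    for cond, sub in post.rep_fitness.groupby("condition", observed=True):
        keep = post.summary[
            (post.summary.condition == cond)
            & (post.summary.classification != "neutral")
        ].edit_id
        wide = (
            sub[sub.edit_id.isin(keep)]
            .pivot(index="edit_id", columns="replicate", values="s_mean")
            .dropna()
        )
        reps = list(wide.columns)
        if len(reps) < 2:
            raise ValueError("replicate_concordance requires >= 2 replicates")
        for r1, r2 in itertools.combinations(reps, 2):
            if len(wide) < 3:
                rows.append((cond, r1, r2, np.nan, len(wide), True))
            else:
                rho = stats.spearmanr(wide[r1], wide[r2]).statistic
                rows.append((cond, r1, r2, float(rho), len(wide), False))
    return pd.DataFrame(
        rows,
        columns=["condition", "replicate_a", "replicate_b", "spearman_rho", "n_edits", "undefined"],
    )
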