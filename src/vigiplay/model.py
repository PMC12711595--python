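"""Bayesian Gaussian linear mixed model with crossed random intercepts.

Model
-----
``y = X beta + sum_k Z_k u_k + eps``, with ``u_k ~ N(0, tau_k^2 I)`` for each
crossed grouping factor k (individual, playback event, stimulus exemplar) and
``eps ~ N(0, sigma^2 I)``.  The grouping factors are additive and non-nested:
individuals recur across playback events, events capture several co-observed
individuals, and exemplars are reused across both.

Priors are weakly informative in the style of applied Bayesian regression
software: after internal scaling each slope gets ``N(0, 2.5 sd(y)/sd(x))``,
the intercept ``N(mean(y), 2.5 sd(y))``, and every scale parameter
(``tau_k`` and ``sigma``) a half-Student-t(3) with scale ``sd(y)``.

Inference is by a blocked, partially collapsed Gibbs sampler.  beta is
updated as a single Gaussian block and each random factor's intercepts are
conditionally independent across levels.  Each random-effect scale tau_k is
updated by slice sampling from its *marginal* conditional with its own
intercepts integrated out (closed form for an intercept-only factor:
``r_l ~ N(0, sigma^2 I + tau^2 J)`` per level), which breaks the tau-u
coupling that makes naive Gibbs mix poorly on crossed designs; u_k is then
redrawn conjugately.  The residual scale uses the Huang-Wand (2013)
inverse-gamma mixture so its update stays conjugate.  Because fixed effects
that are constant within individuals (site, sex-age) are confounded with the
individual intercepts, every few iterations the sampler additionally
refreshes (beta, u) with one *joint* Gaussian draw over all coefficients,
removing the beta-u random-walk behavior in that confounded subspace.

Convergence is checked with split-Rhat and bulk ESS (via arviz); a fit whose
worst Rhat exceeds the configured threshold after one automatic retry with
doubled iterations raises, carrying the offending diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignInfo, DesignMatrices, SEXAGE_LEVELS
from .ingest import SITES, STIMULI

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ContrastResult",
    "ConvergenceError",
    "fit_lmm",
    "diagnostics",
    "within_site_contrast",
    "between_site_contrast",
    "partial_dependence",
]

_HALF_T_NU = 3.0  # df of the half-t scale priors


class ConvergenceError(RuntimeError):
    """MCMC failed its Rhat check even after the automatic retry."""

    def __init__(self, message: str, diag: pd.DataFrame):
        super().__init__(message)
        self.diag = diag


@dataclass(frozen=True)
class ModelSpec:
    """Sampler and prior configuration."""

    response: str = "reaction_intensity"
    chains: int = 4
    iterations: int = 2000  # per chain, including warmup
    warmup: int = 1000
    seed: int = 20230701
    prior_beta_scale: float = 2.5
    prior_scale_df: float = _HALF_T_NU
    max_rhat: float = 1.01
    retry: bool = True

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split-Rhat")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")


@dataclass(frozen=True)
class ContrastResult:
    """Posterior expected difference between two conditions (mu_diff)."""

    label: str
    mu_diff: float
    cri_low: float
    cri_high: float
    supported: bool
    draws: np.ndarray = field(repr=False, compare=False)


@dataclass
class FittedModel:
    """Posterior draws plus design metadata needed for contrasts."""

    beta: np.ndarray  # (chains, draws, p)
    columns: tuple[str, ...]
    sigma: np.ndarray  # (chains, draws)
    tau: dict[str, np.ndarray]  # factor -> (chains, draws)
    info: DesignInfo
    summary: pd.DataFrame
    dropped_factors: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def linear_predictor_draws(self, row: np.ndarray) -> np.ndarray:
        """Posterior draws of x'beta for one condition row."""
        return self.beta_flat() @ np.asarray(row, dtype=float)


def _slice_sample(logpdf, x0: float, rng: np.random.Generator, w: float = 1.0) -> float:
    """One univariate stepping-out + shrinkage slice-sampling update."""
    logy = logpdf(x0) + np.log(rng.uniform())
    left = x0 - w * rng.uniform()
    right = left + w
    for _ in range(50):
        if logpdf(left) <= logy:
            break
        left -= w
    for _ in range(50):
        if logpdf(right) <= logy:
            break
        right += w
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logpdf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # degenerate slice; keep current value


def _tau_marginal_logpost(
    log_tau: float,
    counts: np.ndarray,
    level_sums: np.ndarray,
    sigma2: float,
    scale_A: float,
    nu: float,
) -> float:
    """log p(log tau | residuals) with the factor's own intercepts integrated out.

    Per level l with n_l observations and residual sum s_l,
    ``r_l ~ N(0, sigma^2 I + tau^2 J)``; only the tau-dependent terms are kept.
    """
    if log_tau > 20.0 or log_tau < -20.0:
        return -np.inf
    tau2 = np.exp(2.0 * log_tau)
    denom = sigma2 + counts * tau2
    loglik = -0.5 * float(np.sum(np.log(denom))) + 0.5 * float(
        np.sum(tau2 * level_sums**2 / (sigma2 * denom))
    )
    tau = np.exp(log_tau)
    log_prior = -0.5 * (nu + 1.0) * np.log1p(tau**2 / (nu * scale_A**2))
    return loglik + log_prior + log_tau  # + Jacobian of the log transform


def _gibbs_chain(
    X: np.ndarray,
    y: np.ndarray,
    groups: dict[str, np.ndarray],
    n_levels: dict[str, int],
    prior_mean: np.ndarray,
    prior_sd: np.ndarray,
    scale_A: float,
    nu: float,
    iterations: int,
    warmup: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    n, p = X.shape
    XtX = X.T @ X
    Xt = X.T
    prior_prec = 1.0 / prior_sd**2

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    sigma2 = max(float(np.var(y - X @ beta)), 1e-6)
    u = {k: np.zeros(n_levels[k]) for k in groups}
    tau = {k: 0.1 * scale_A for k in groups}
    a_sig = 1.0

    # combined [X | Z_1 | ... | Z_K] system for the periodic joint refresh
    keys = list(groups)
    blocks = []
    offset = p
    slices = {}
    for k in keys:
        q = n_levels[k]
        Z = np.zeros((n, q))
        Z[np.arange(n), groups[k]] = 1.0
        blocks.append(Z)
        slices[k] = slice(offset, offset + q)
        offset += q
    W = np.hstack([X] + blocks) if blocks else X
    WtW = W.T @ W
    Wty = W.T @ y
    m_total = offset
    prior_mean_full = np.concatenate([prior_mean, np.zeros(m_total - p)])
    joint_every = 2

    keep = iterations - warmup
    out_beta = np.empty((keep, p))
    out_sigma = np.empty(keep)
    out_tau = {k: np.empty(keep) for k in groups}

    counts = {k: np.bincount(groups[k], minlength=n_levels[k]).astype(float) for k in groups}

    for it in range(iterations):
        # --- beta | rest
        resid_re = np.zeros(n)
        for k, codes in groups.items():
            resid_re += u[k][codes]
        prec = XtX / sigma2 + np.diag(prior_prec)
        rhs = Xt @ (y - resid_re) / sigma2 + prior_prec * prior_mean
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(chol.T, z)

        # --- periodic joint (beta, u) refresh
        if it % joint_every == 0:
            d_full = np.empty(m_total)
            d_full[:p] = prior_prec
            for k in keys:
                d_full[slices[k]] = 1.0 / tau[k] ** 2
            P = WtW / sigma2
            P[np.diag_indices_from(P)] += d_full
            rhs_full = Wty / sigma2 + d_full * prior_mean_full
            L = np.linalg.cholesky(P)
            mean_full = np.linalg.solve(P, rhs_full)
            theta = mean_full + np.linalg.solve(L.T, rng.standard_normal(m_total))
            beta = theta[:p]
            for k in keys:
                u[k] = theta[slices[k]]
        fixed_part = X @ beta

        # --- per factor: collapsed tau update, then conjugate u redraw
        for k, codes in groups.items():
            partial = y - fixed_part
            for k2, codes2 in groups.items():
                if k2 != k:
                    partial = partial - u[k2][codes2]
            sums = np.bincount(codes, weights=partial, minlength=n_levels[k])

            logpdf = lambda lt: _tau_marginal_logpost(
                lt, counts[k], sums, sigma2, scale_A, nu
            )
            log_tau = np.log(tau[k])
            for _ in range(2):  # two cheap passes for better tau mixing
                log_tau = _slice_sample(logpdf, log_tau, rng)
            tau[k] = float(np.exp(log_tau))

            prec_l = counts[k] / sigma2 + 1.0 / tau[k] ** 2
            mean_l = (sums / sigma2) / prec_l
            u[k] = mean_l + rng.standard_normal(n_levels[k]) / np.sqrt(prec_l)

        # --- residual scale (Huang-Wand half-t mixture, conjugate)
        resid = y - fixed_part
        for k, codes in groups.items():
            resid = resid - u[k][codes]
        sigma2 = 1.0 / rng.gamma(
            (nu + n) / 2.0, 1.0 / (nu / a_sig + 0.5 * float(resid @ resid))
        )
        a_sig = 1.0 / rng.gamma(
            (nu + 1) / 2.0, 1.0 / (nu / sigma2 + 1.0 / scale_A**2)
        )

        if it >= warmup:
            j = it - warmup
            out_beta[j] = beta
            out_sigma[j] = np.sqrt(sigma2)
            for k in groups:
                out_tau[k][j] = tau[k]

    return {"beta": out_beta, "sigma": out_sigma, "tau": out_tau}


def _run_sampler(design: DesignMatrices, spec: ModelSpec, iterations: int):
    X = design.X.to_numpy(dtype=float)
    y = np.asarray(design.y, dtype=float)
    n, p = X.shape

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"design is rank deficient (rank {rank} < {p} columns)")

    groups, n_levels, dropped = {}, {}, []
    for k, codes in design.groups.items():
        q = len(design.group_levels[k])
        if q < 2:
            import warnings

            warnings.warn(f"random factor {k!r} has < 2 levels; dropped", stacklevel=3)
            dropped.append(k)
            continue
        groups[k] = codes
        n_levels[k] = q

    sd_y = float(np.std(y)) or 1.0
    mean_y = float(np.mean(y))
    prior_mean = np.zeros(p)
    prior_sd = np.empty(p)
    for j, col in enumerate(design.X.columns):
        x = X[:, j]
        if col == "Intercept":
            prior_mean[j] = mean_y
            prior_sd[j] = spec.prior_beta_scale * sd_y
        else:
            sd_x = float(np.std(x))
            prior_sd[j] = spec.prior_beta_scale * sd_y / (sd_x if sd_x > 0 else 1.0)

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chains = [
        _gibbs_chain(
            X,
            y,
            groups,
            n_levels,
            prior_mean,
            prior_sd,
            scale_A=sd_y,
            nu=spec.prior_scale_df,
            iterations=iterations,
            warmup=spec.warmup * iterations // spec.iterations,
            rng=np.random.default_rng(s),
        )
        for s in seeds
    ]
    beta = np.stack([c["beta"] for c in chains])  # (chains, keep, p)
    sigma = np.stack([c["sigma"] for c in chains])
    tau = {k: np.stack([c["tau"][k] for c in chains]) for k in groups}
    return beta, sigma, tau, tuple(dropped)


def _draw_dict(fit_beta, columns, sigma, tau) -> dict[str, np.ndarray]:
    d = {f"beta[{c}]": fit_beta[:, :, j] for j, c in enumerate(columns)}
    d["sigma"] = sigma
    for k, v in tau.items():
        d[f"tau[{k}]"] = v
    return d


def diagnostics(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    """Split-Rhat, bulk ESS and MCSE (posterior SD / sqrt(ESS)) per parameter.

    ``draws`` maps parameter name to a (chains, draws) array; >= 2 chains.
    """
    import arviz as az

    first = next(iter(draws.values()))
    if first.ndim != 2 or first.shape[0] < 2:
        raise ValueError("diagnostics needs arrays of shape (chains >= 2, draws)")
    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for k, v in draws.items():
        r = float(rhat[k].values)
        e = float(ess[k].values)
        sd = float(v.std())
        rows.append(
            {"parameter": k, "rhat": r, "ess": e, "mcse": sd / np.sqrt(e) if e > 0 else 0.0}
        )
    return pd.DataFrame(rows).set_index("parameter")


def _summarize(draws: dict[str, np.ndarray], diag: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for k, v in draws.items():
        flat = v.ravel()
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "parameter": k,
                "mean": float(flat.mean()),
                "cri_low": float(lo),
                "cri_high": float(hi),
                "rhat": diag.loc[k, "rhat"],
                "mcse": diag.loc[k, "mcse"],
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def fit_lmm(design: DesignMatrices, spec: ModelSpec | None = None) -> FittedModel:
    """Fit the crossed-random-intercepts LMM by blocked Gibbs sampling.

    Retries once with doubled iterations if any split-Rhat exceeds
    ``spec.max_rhat``; raises :class:`ConvergenceError` if it still does.
    """
    if spec is None:
        spec = ModelSpec()
    iterations = spec.iterations
    for attempt in (0, 1):
        beta, sigma, tau, dropped = _run_sampler(design, spec, iterations)
        draws = _draw_dict(beta, design.X.columns, sigma, tau)
        diag = diagnostics(draws)
        worst = float(diag["rhat"].max())
        if worst <= spec.max_rhat:
            break
        if attempt == 0 and spec.retry:
            iterations *= 2
            continue
        raise ConvergenceError(
            f"max Rhat {worst:.4f} > {spec.max_rhat} after retry", diag
        )
    summary = _summarize(draws, diag)
    return FittedModel(
        beta=beta,
        columns=tuple(design.X.columns),
        sigma=sigma,
        tau=tau,
        info=design.info,
        summary=summary,
        dropped_factors=dropped,
    )


def _contrast_from_rows(
    fit: FittedModel, row_a: np.ndarray, row_b: np.ndarray, label: str
) -> ContrastResult:
    draws = fit.linear_predictor_draws(row_a - row_b)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return ContrastResult(
        label=label,
        mu_diff=float(draws.mean()),
        cri_low=float(lo),
        cri_high=float(hi),
        supported=not (lo <= 0.0 <= hi),
        draws=draws,
    )


def within_site_contrast(
    fit: FittedModel, site: str, sound_a: str, sound_b: str
) -> ContrastResult:
    """E[Y | site, sound_a] - E[Y | site, sound_b], covariates at means,
    averaged with equal weights over the four sex-age levels."""
    row_a = fit.info.condition_row(site, sound_a)
    row_b = fit.info.condition_row(site, sound_b)
    return _contrast_from_rows(fit, row_a, row_b, f"{site}: {sound_a} - {sound_b}")


def between_site_contrast(
    fit: FittedModel, sound: str, site_a: str, site_b: str
) -> ContrastResult:
    """Same functional with the roles of site and sound swapped."""
    row_a = fit.info.condition_row(site_a, sound)
    row_b = fit.info.condition_row(site_b, sound)
    return _contrast_from_rows(fit, row_a, row_b, f"{sound}: {site_a} - {site_b}")


def partial_dependence(
    fit: FittedModel,
    sites=None,
    sounds=None,
    sexage: str | None = None,
) -> pd.DataFrame:
    """Posterior mean and 95% CrI of the expected response per grid cell.

    Continuous covariates are held at their sample means (0 on the
    standardized scale); sex-age is marginalized with equal weights unless a
    level is fixed.  One row per (site, sound) cell.
    """
    sites = list(SITES) if sites is None else list(sites)
    sounds = list(STIMULI) if sounds is None else list(sounds)
    if sexage is not None and sexage not in SEXAGE_LEVELS:
        raise ValueError(f"unknown sexage level {sexage!r}")
    rows = []
    for site in sites:
        for sound in sounds:
            x = fit.info.condition_row(site, sound, sexage)
            draws = fit.linear_predictor_draws(x)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "site": site,
                    "sound": sound,
                    "sexage": sexage or "averaged",
                    "mean": float(draws.mean()),
                    "cri_low": float(lo),
                    "cri_high": float(hi),
                }
            )
    return pd.DataFrame(rows)
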