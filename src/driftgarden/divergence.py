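"""Drift-null tests of adaptive divergence in quantitative traits.

A hierarchical animal model ties population additive means to the neutral
expectation from the coancestry matrix Theta: population effects are
``alpha ~ MVN(mu 1, 2 sigma2_A Theta)`` (the drift null), within-population
breeding values follow the half-sib pedigree, and observations add block
fixed effects, a seed-weight covariate and iid residuals.  Posterior
uncertainty in Theta is propagated by cycling one coancestry posterior draw
per sampler iteration.

From the fitted posterior this module computes:

* the global **S-test** — the posterior probability that the observed
  population means are more dispersed in the drift metric
  ``(2 sigma2_A Theta)^-1`` than a fresh draw from the drift null
  (0.5 = neutral, -> 1 diversifying, -> 0 homogenizing selection);
* the **population-wise S-test** — drift envelopes (central intervals of
  the null predictive of each population mean) and flags for populations
  whose posterior mass falls essentially outside their envelope;
* the **H/H*-test** — whether standardized trait divergences track an
  environmental driver beyond drift; H* standardizes by a driver
  permutation so that strong divergence uncorrelated with the tested
  driver no longer produces a false positive;
* a PCA of standardized divergences across traits, and population-level
  Pearson correlations with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Pedigree, PhenotypeTable, psrf
from .afm import CoancestryPosterior
from .env import EnvPCA, env_pca
from .quantgen import _extract_design, _inv_chi2, _NU0

__all__ = [
    "DivergenceResult", "fit_divergence_model", "s_test", "population_s_test",
    "h_star_test", "divergence_pca", "correlate_population_values",
    "standardized_divergence",
]


@dataclass
class DivergenceResult:
    """Posterior of the drift-constrained divergence model for one trait."""

    populations: list[str]
    mu: np.ndarray  # (chains, kept)
    alpha: np.ndarray  # (chains, kept, P)
    sigma2_A: np.ndarray  # (chains, kept)
    sigma2_E: np.ndarray  # (chains, kept)
    theta_draws: np.ndarray  # (n_theta, P, P) the cycled coancestry draws
    theta_idx: np.ndarray  # (kept,) draw used at each retained iteration
    psrf: dict[str, float] = field(default_factory=dict)
    trait: str = ""

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    def pooled(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def max_psrf(self) -> float:
        return max(self.psrf.values())

    @property
    def converged(self) -> bool:
        """Convergence label at the conventional 1.15 worst-case threshold."""
        return self.max_psrf <= 1.15

    def theta_for_draws(self) -> np.ndarray:
        """Theta draw aligned with each pooled retained sample, (T, P, P)."""
        n_chains = self.mu.shape[0]
        idx = np.tile(self.theta_idx, n_chains)
        return self.theta_draws[idx]


def _theta_draw_bank(theta, populations: list[str], max_draws: int = 400):
    """Coancestry draws aligned to the phenotype populations.

    Accepts a CoancestryPosterior (cycled draws) or a fixed P x P matrix.
    """
    if isinstance(theta, CoancestryPosterior):
        if list(theta.populations) != list(populations):
            order = [theta.populations.index(p) for p in populations]
            samples = theta.samples[:, order][:, :, order]
        else:
            samples = theta.samples
        if len(samples) > max_draws:
            sel = np.linspace(0, len(samples) - 1, max_draws).astype(int)
            samples = samples[sel]
        return np.asarray(samples, dtype=float)
    mat = np.asarray(theta, dtype=float)
    if mat.shape != (len(populations), len(populations)):
        raise ValueError("fixed theta has wrong shape for these populations")
    return mat[None, :, :]


def _safe_inv_chol(theta: np.ndarray):
    """Inverse and Cholesky of a coancestry draw, ridged if near-singular."""
    ridge = 0.0
    for _ in range(6):
        try:
            chol = np.linalg.cholesky(theta + ridge * np.eye(theta.shape[0]))
            break
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-8)
    else:
        raise np.linalg.LinAlgError("coancestry draw not repairable")
    inv = np.linalg.inv(theta + ridge * np.eye(theta.shape[0]))
    return inv, chol


def fit_divergence_model(y: PhenotypeTable, ped: Pedigree, theta,
                         trait: str | None = None, chains: int = 3,
                         burn_in: int = 3000, iters: int = 3000, thin: int = 10,
                         seed: int = 0, rho_sib: float = 0.25,
                         fixed_theta: bool = False) -> DivergenceResult:
    """Gibbs sampling of the drift-constrained divergence model.

    ``theta`` is a :class:`~driftgarden.afm.CoancestryPosterior` (posterior
    draws cycled, one per iteration) or a fixed P x P matrix;
    ``fixed_theta`` collapses a posterior to its mean.  Returns pooled
    posterior samples and a PSRF per monitored scalar (mu, sigma2_A,
    sigma2_E and each population effect).
    """
    df = y.for_trait(trait) if trait is not None else y.for_trait(y.traits[0])
    des = _extract_design(df, ped, use_seed_weight=True)
    if isinstance(theta, CoancestryPosterior) and fixed_theta:
        bank = _theta_draw_bank(theta.posterior_mean, des.pops)
    else:
        bank = _theta_draw_bank(theta, des.pops)
    n_theta = len(bank)
    inv_chol = [_safe_inv_chol(b) for b in bank]

    p_pops = des.n_pops
    vy = float(np.var(des.y))
    s0 = {"a": 0.25 * vy, "e": 0.25 * vy}
    n_kept = iters // thin
    mu_s = np.zeros((chains, n_kept))
    alpha_s = np.zeros((chains, n_kept, p_pops))
    s2a_s = np.zeros((chains, n_kept))
    s2e_s = np.zeros((chains, n_kept))
    theta_idx = np.zeros(n_kept, dtype=int)

    nb = np.bincount(des.block_idx, minlength=des.n_blocks).astype(float)
    npop = np.bincount(des.pop_idx, minlength=p_pops).astype(float)
    nf = np.bincount(des.fam_idx, minlength=des.n_fams).astype(float)
    ni = np.bincount(des.ind_idx, minlength=des.n_inds).astype(float)
    sw = des.sw
    sw_ss = float(sw @ sw) if sw is not None else 0.0
    rho = rho_sib

    for c in range(chains):
        rng = np.random.default_rng([seed % (2**31), 17, c])
        block = np.zeros(des.n_blocks)
        beta = 0.0
        mu = float(des.y.mean()) + 0.1 * rng.normal()
        alpha = np.full(p_pops, mu) + 0.05 * rng.normal(size=p_pops)
        u = np.zeros(des.n_fams)
        delta = np.zeros(des.n_inds)
        s2a = s0["a"] * 2 * np.exp(0.3 * rng.normal())
        s2e = s0["e"] * 2

        def fitted():
            f = block[des.block_idx] + alpha[des.pop_idx] + u[des.fam_idx] \
                + delta[des.ind_idx]
            if sw is not None:
                f = f + beta * sw
            return f

        res = des.y - fitted()
        k = 0
        for it in range(burn_in + iters):
            t_inv, t_chol = inv_chol[it % n_theta]
            # block fixed effects as contrasts to block 1 (flat prior); the
            # overall level is carried by mu/alpha, so block 1 is pinned at 0
            res += block[des.block_idx]
            sums = np.bincount(des.block_idx, weights=res, minlength=des.n_blocks)
            block = sums / nb + rng.normal(size=des.n_blocks) * np.sqrt(s2e / nb)
            block[0] = 0.0
            res -= block[des.block_idx]
            # seed-weight covariate
            if sw is not None:
                res += beta * sw
                beta = float(res @ sw) / sw_ss + rng.normal() * np.sqrt(s2e / sw_ss)
                res -= beta * sw
            # population additive means, drift-null MVN prior
            res += alpha[des.pop_idx]
            sums = np.bincount(des.pop_idx, weights=res, minlength=p_pops)
            prior_prec = t_inv / (2.0 * s2a)
            lam = prior_prec + np.diag(npop / s2e)
            rhs = prior_prec @ (mu * np.ones(p_pops)) + sums / s2e
            lam_chol = np.linalg.cholesky(lam)
            mean = np.linalg.solve(lam_chol.T, np.linalg.solve(lam_chol, rhs))
            alpha = mean + np.linalg.solve(lam_chol.T, rng.normal(size=p_pops))
            res -= alpha[des.pop_idx]
            # ancestral mean (flat prior)
            one = np.ones(p_pops)
            m_prec = float(one @ prior_prec @ one)
            m_mean = float(one @ prior_prec @ alpha) / m_prec
            mu = m_mean + rng.normal() / np.sqrt(m_prec)
            # family and individual genetic deviations
            res += u[des.fam_idx]
            sums = np.bincount(des.fam_idx, weights=res, minlength=des.n_fams)
            prec = nf / s2e + 1.0 / (rho * s2a)
            u = sums / s2e / prec + rng.normal(size=des.n_fams) / np.sqrt(prec)
            res -= u[des.fam_idx]
            res += delta[des.ind_idx]
            sums = np.bincount(des.ind_idx, weights=res, minlength=des.n_inds)
            prec = ni / s2e + 1.0 / ((1.0 - rho) * s2a)
            delta = sums / s2e / prec + rng.normal(size=des.n_inds) / np.sqrt(prec)
            res -= delta[des.ind_idx]
            # variance components: alpha prior + family + individual terms
            dev = alpha - mu
            ss_a = float(dev @ t_inv @ dev) / 2.0 + (u @ u) / rho \
                + (delta @ delta) / (1.0 - rho)
            s2a = _inv_chi2(rng, _NU0 + p_pops + des.n_fams + des.n_inds,
                            _NU0 * s0["a"] + ss_a)
            s2e = _inv_chi2(rng, _NU0 + len(des.y), _NU0 * s0["e"] + res @ res)
            if it >= burn_in and (it - burn_in + 1) % thin == 0 and k < n_kept:
                mu_s[c, k] = mu
                alpha_s[c, k] = alpha
                s2a_s[c, k] = s2a
                s2e_s[c, k] = s2e
                if c == 0:
                    theta_idx[k] = it % n_theta
                k += 1

    psrf_vals = {"mu": psrf(list(mu_s)), "sigma2_A": psrf(list(s2a_s)),
                 "sigma2_E": psrf(list(s2e_s))}
    for j, p in enumerate(des.pops):
        psrf_vals[f"alpha[{p}]"] = psrf(list(alpha_s[:, :, j]))
    return DivergenceResult(
        populations=des.pops, mu=mu_s, alpha=alpha_s, sigma2_A=s2a_s,
        sigma2_E=s2e_s, theta_draws=bank, theta_idx=theta_idx,
        psrf=psrf_vals, trait=df["trait"].iloc[0],
    )


# ---------------------------------------------------------------------------
# S-test
# ---------------------------------------------------------------------------

def s_test(res: DivergenceResult, seed: int = 0) -> float:
    """Global S statistic: P(observed dispersion > drift-null dispersion).

    Per retained draw ``t`` the Mahalanobis dispersion
    ``D = (alpha - mu 1)' (2 sigma2_A Theta)^-1 (alpha - mu 1)`` is compared
    with the dispersion of a fresh null draw from
    ``MVN(mu 1, 2 sigma2_A Theta)`` (whose dispersion is exactly
    chi-squared with P degrees of freedom); ties count as 0.
    """
    rng = np.random.default_rng([seed % (2**31), 19])
    mu = res.pooled("mu")
    alpha = res.pooled("alpha")
    s2a = res.pooled("sigma2_A")
    p = res.n_pops
    inv_cache = {i: _safe_inv_chol(res.theta_draws[i])[0]
                 for i in np.unique(res.theta_idx)}
    idx = np.tile(res.theta_idx, res.mu.shape[0])
    d_obs = np.empty(len(mu))
    for t in range(len(mu)):
        dev = alpha[t] - mu[t]
        d_obs[t] = dev @ inv_cache[idx[t]] @ dev / (2.0 * s2a[t])
    d_null = rng.chisquare(p, size=len(mu))
    return float((d_obs > d_null).mean())


def population_s_test(res: DivergenceResult, level: float = 0.95,
                      seed: int = 0) -> pd.DataFrame:
    """Population-wise S-test with drift envelopes.

    The envelope of population ``j`` is the central ``level`` interval of
    its null predictive ``mu + sqrt(2 sigma2_A theta_jj) z`` pooling
    posterior draws of (mu, sigma2_A, theta_jj).  A population is flagged
    "unusual" when at least ``level`` of its alpha posterior mass falls
    outside the envelope; the direction relative to the ancestral mean is
    reported.
    """
    rng = np.random.default_rng([seed % (2**31), 23])
    mu = res.pooled("mu")
    alpha = res.pooled("alpha")
    s2a = res.pooled("sigma2_A")
    thetas = res.theta_for_draws()
    diag = np.einsum("tjj->tj", thetas)
    sd = np.sqrt(np.maximum(2.0 * s2a[:, None] * diag, 1e-30))
    null_pred = mu[:, None] + sd * rng.normal(size=sd.shape)
    tail = (1.0 - level) / 2.0
    low = np.quantile(null_pred, tail, axis=0)
    high = np.quantile(null_pred, 1.0 - tail, axis=0)
    frac_above = (alpha > high[None, :]).mean(axis=0)
    frac_below = (alpha < low[None, :]).mean(axis=0)
    frac_outside = frac_above + frac_below
    unusual = frac_outside >= level
    direction = np.where(frac_above >= frac_below, "above", "below")
    return pd.DataFrame({
        "population": res.populations,
        "envelope_low": low,
        "envelope_high": high,
        "alpha_mean": alpha.mean(axis=0),
        "alpha_q025": np.quantile(alpha, 0.025, axis=0),
        "alpha_q975": np.quantile(alpha, 0.975, axis=0),
        "frac_outside": frac_outside,
        "unusual": unusual,
        "direction": [d if u else "none" for d, u in zip(direction, unusual)],
    })


def standardized_divergence(res: DivergenceResult) -> pd.DataFrame:
    """Posterior draws of z_j = (alpha_j - mu) / sqrt(2 sigma2_A theta_jj).

    Returns a draws x populations DataFrame; the posterior mean row is what
    the divergence PCA consumes.
    """
    mu = res.pooled("mu")
    alpha = res.pooled("alpha")
    s2a = res.pooled("sigma2_A")
    diag = np.einsum("tjj->tj", res.theta_for_draws())
    z = (alpha - mu[:, None]) / np.sqrt(np.maximum(2.0 * s2a[:, None] * diag, 1e-30))
    return pd.DataFrame(z, columns=res.populations)


def h_star_test(res: DivergenceResult, driver, n_permutations: int = 1,
                seed: int = 0) -> dict[str, float]:
    """H and H* statistics for one candidate environmental driver.

    H asks whether trait divergence is more similar to the environmental
    values than drift predicts: per retained draw the absolute covariance
    between standardized divergences and the driver is compared against the
    same quantity for a drift-null draw of the population effects.  Because
    the covariance grows with the magnitude of divergence, H can approach 1
    under strong divergence even when the driver is irrelevant.

    H* removes that false-positive mode: the absolute Pearson correlation
    (scale-free) is compared against the correlation with a freshly permuted
    driver, so H* ~ 0.5 whenever the driver explains no more of the
    divergence than a random relabelling, however strong the divergence.
    """
    driver = np.asarray(driver, dtype=float)
    if driver.shape != (res.n_pops,):
        raise ValueError("driver needs one value per population")
    if np.std(driver) == 0:
        raise ValueError("constant driver")
    rng = np.random.default_rng([seed % (2**31), 29])
    z = standardized_divergence(res).to_numpy()
    t_n, p = z.shape
    dcs = (driver - driver.mean()) / driver.std()

    def abs_corr(v: np.ndarray, d: np.ndarray) -> float:
        sv = v.std()
        if sv == 0:
            return 0.0
        return abs(float(((v - v.mean()) / sv) @ d) / p)

    def abs_cov(v: np.ndarray, d: np.ndarray) -> float:
        return abs(float((v - v.mean()) @ d) / p)

    chol_cache = {i: _safe_inv_chol(res.theta_draws[i])[1]
                  for i in np.unique(res.theta_idx)}
    idx = np.tile(res.theta_idx, res.mu.shape[0])
    wins_star = np.zeros(t_n)
    wins_null = np.zeros(t_n)
    signed = np.zeros(t_n)
    for t in range(t_n):
        c_obs = abs_corr(z[t], dcs)
        signed[t] = np.corrcoef(z[t], driver)[0, 1] if z[t].std() > 0 else 0.0
        best = 0.0
        for _ in range(max(1, n_permutations)):
            c_perm = abs_corr(z[t], dcs[rng.permutation(p)])
            best = max(best, c_perm)
        wins_star[t] = 1.0 if c_obs > best else 0.0
        # raw H: drift-null draw of alpha, standardized the same way, but
        # compared on the scale-sensitive covariance
        diag = np.diag(res.theta_draws[idx[t]])
        x = chol_cache[idx[t]] @ rng.normal(size=p)
        z_null = x / np.sqrt(np.maximum(diag, 1e-30))
        wins_null[t] = 1.0 if abs_cov(z[t], dcs) > abs_cov(z_null, dcs) else 0.0
    return {
        "H_star": float(wins_star.mean()),
        "H": float(wins_null.mean()),
        "signed_correlation": float(signed.mean()),
    }


# ---------------------------------------------------------------------------
# multi-trait summaries
# ---------------------------------------------------------------------------

def divergence_pca(z_table: pd.DataFrame) -> EnvPCA:
    """PCA of standardized divergences (populations x traits).

    Values are already on the drift-standardized scale, so they are centred
    but not rescaled before decomposition.
    """
    if z_table.shape[1] < 2:
        raise ValueError("need at least 2 traits for a divergence PCA")
    if z_table.isna().any().any():
        missing = z_table.columns[z_table.isna().any()].tolist()
        raise ValueError(f"missing divergences for trait(s) {missing}")
    return env_pca(z_table, scale=False)


def correlate_population_values(x, y, correction: str = "none",
                                m: int = 1) -> tuple[float, float]:
    """Population-level Pearson correlation with optional Bonferroni correction.

    Returns ``(r, p)``; ``p`` is two-sided from the t transform, multiplied
    by ``m`` tests (capped at 1) under ``correction="bonferroni"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of >= 3 populations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")
    r, p = stats.pearsonr(x, y)
    if correction == "bonferroni":
        if m < 1:
            raise ValueError("m must be >= 1")
        p = min(1.0, p * m)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return float(r), float(p)
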