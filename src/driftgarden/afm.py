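"""Admixture F-model: posterior coancestry ("drift distance") estimation.

Populations descend from a common ancestral gene pool.  Per locus ``l`` an
ancestral frequency ``pi_l`` drifts within each source ``s`` to
``p_sl ~ Beta(pi_l (1-a_s)/a_s, (1-pi_l)(1-a_s)/a_s)`` (mean ``pi_l``,
variance ``a_s pi_l (1-pi_l)``); population allele frequencies are mixtures
``q_jl = sum_s w_js p_sl`` over sources, and observed genotypes are
``Binomial(2, q_jl)``.  The pairwise coancestry is
``theta_jk = sum_s w_js w_ks a_s``, which parameterises the expected
neutral divergence of both allele frequencies and additive trait means.

Inference is multi-chain component-wise random-walk Metropolis (logit scale
for ``pi``, ``p`` and ``a``; Dirichlet proposals on the weight simplex for
rows of W), with proposal scales adapted toward 20-40% acceptance during
burn-in only and frozen afterwards.  Priors: ``pi ~ U(0,1)``,
``a ~ U(0.001, 0.999)``, W rows symmetric Dirichlet(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core_io import MISSING, GenotypeMatrix

__all__ = ["AFMParams", "CoancestryPosterior", "afm_loglik", "fit_afm"]

_ALPHA_LO, _ALPHA_HI = 0.001, 0.999


@dataclass
class AFMParams:
    """One state of the admixture F-model parameter vector."""

    ancestral_freqs: np.ndarray  # (L,) in (0,1)
    source_drift: np.ndarray  # (S,) in (0,1)
    admixture: np.ndarray  # (P, S), rows sum to 1
    source_freqs: np.ndarray  # (S, L) in (0,1)

    def __post_init__(self) -> None:
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        self.source_drift = np.asarray(self.source_drift, dtype=float)
        self.admixture = np.asarray(self.admixture, dtype=float)
        self.source_freqs = np.asarray(self.source_freqs, dtype=float)
        if not np.allclose(self.admixture.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("admixture rows must sum to 1")

    def theta(self) -> np.ndarray:
        w, a = self.admixture, self.source_drift
        return (w * a[None, :]) @ w.T


@dataclass
class CoancestryPosterior:
    """Multi-chain posterior of the P x P coancestry matrix."""

    populations: list[str]
    samples_by_chain: np.ndarray  # (n_chains, n_kept, P, P)
    psrf_per_entry: np.ndarray  # (P, P)
    posterior_mean: np.ndarray  # (P, P)
    acceptance: dict[str, float]
    burn_in: int
    thin: int

    @property
    def samples(self) -> np.ndarray:
        """Pooled post-burn-in samples, (n_chains*n_kept, P, P)."""
        m, k, p, _ = self.samples_by_chain.shape
        return self.samples_by_chain.reshape(m * k, p, p)

    @property
    def mean_psrf(self) -> float:
        return float(self.psrf_per_entry.mean())

    def credible_interval(self, j: int, k: int, level: float = 0.95) -> tuple[float, float]:
        s = self.samples[:, j, k]
        tail = (1.0 - level) / 2.0
        return (float(np.quantile(s, tail)), float(np.quantile(s, 1.0 - tail)))


# ---------------------------------------------------------------------------
# sufficient statistics and likelihood
# ---------------------------------------------------------------------------

def _sufficient_stats(g: GenotypeMatrix):
    """Per population x locus: alt-allele counts, total allele counts, het count."""
    pops = g.populations
    calls = g.calls
    obs = calls != MISSING
    y = np.zeros((len(pops), g.n_loci))
    n = np.zeros((len(pops), g.n_loci))
    pop_arr = np.asarray(g.population)
    for j, pop in enumerate(pops):
        rows = pop_arr == pop
        y[j] = np.where(obs[rows], calls[rows], 0).sum(axis=0)
        n[j] = 2.0 * obs[rows].sum(axis=0)
    n_het = int((calls == 1).sum())
    return pops, y, n, n_het


def _beta_ab(pi: np.ndarray, alpha: np.ndarray):
    """Beta drift shape parameters a, b for each (source, locus)."""
    c = (1.0 - alpha) / alpha  # (S,)
    a = c[:, None] * pi[None, :]
    b = c[:, None] * (1.0 - pi[None, :])
    return a, b


def afm_loglik(params: AFMParams, g: GenotypeMatrix) -> float:
    """Joint log density: genotype likelihood + drift (Beta) terms + priors.

    Missing genotypes contribute nothing; a mixture frequency outside (0,1)
    returns -inf (rejection) rather than raising.
    """
    pops, y, n, n_het = _sufficient_stats(g)
    p_mat = params.source_freqs
    w = params.admixture
    pi, alpha = params.ancestral_freqs, params.source_drift
    if w.shape[0] != len(pops):
        raise ValueError("admixture rows must match populations in g")
    q = w @ p_mat
    if (q <= 0).any() or (q >= 1).any():
        return -np.inf
    ll = float((y * np.log(q) + (n - y) * np.log1p(-q)).sum()) + n_het * np.log(2.0)
    a, b = _beta_ab(pi, alpha)
    lbeta = gammaln(a) + gammaln(b) - gammaln(a + b)
    ll += float(((a - 1.0) * np.log(p_mat) + (b - 1.0) * np.log1p(-p_mat) - lbeta).sum())
    # priors: pi ~ U(0,1) -> 0; alpha ~ U(lo,hi); W rows ~ Dirichlet(1)
    if ((alpha < _ALPHA_LO) | (alpha > _ALPHA_HI)).any():
        return -np.inf
    ll += -alpha.size * np.log(_ALPHA_HI - _ALPHA_LO)
    ll += w.shape[0] * gammaln(w.shape[1])  # log Dirichlet(1) normaliser per row
    return ll


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _dirichlet_logpdf(x: np.ndarray, conc: np.ndarray) -> float:
    return float(gammaln(conc.sum()) - gammaln(conc).sum()
                 + ((conc - 1.0) * np.log(x)).sum())


class _AFMChain:
    """One Metropolis chain over (pi, p, alpha, W) with burn-in adaptation."""

    def __init__(self, y, n, n_sources, rng, shared_source=False):
        self.y, self.n = y, n
        self.rng = rng
        p_pops, n_loci = y.shape
        self.P, self.S, self.L = p_pops, n_sources, n_loci
        pooled = y.sum(axis=0) / np.maximum(n.sum(axis=0), 1.0)
        self.pi = np.clip(pooled, 0.02, 0.98)
        self.pi = _expit(_logit(self.pi) + 0.05 * rng.normal(size=n_loci))
        self.alpha = np.clip(0.05 * np.exp(0.2 * rng.normal(size=n_sources)),
                             _ALPHA_LO + 1e-6, 0.5)
        self.p = np.clip(np.tile(self.pi, (n_sources, 1)), 0.02, 0.98)
        self.p = _expit(_logit(self.p) + 0.05 * rng.normal(size=self.p.shape))
        w = np.full((p_pops, n_sources), 0.0)
        if shared_source:
            own = 0.85
            w[:, :] = (1.0 - own - 0.10) / max(n_sources - 2, 1)
            for j in range(p_pops):
                w[j, j] = own
            w[:, -1] = 0.10
        elif n_sources == 1:
            w[:, 0] = 1.0
        else:
            off = 0.06 / (n_sources - 1)
            w[:, :] = off
            for j in range(min(p_pops, n_sources)):
                w[j, j] = 1.0 - 0.06
        w = w / w.sum(axis=1, keepdims=True)
        self.w = w
        self.q = self.w @ self.p
        self._refresh_caches()
        # adaptive proposal scales
        self.step_p = np.full(n_sources, 0.3)
        self.step_pi = 0.3
        self.step_alpha = np.full(n_sources, 0.5)
        self.kappa_w = np.full(p_pops, 200.0)
        self.accept_counts = {"p": 0, "pi": 0, "alpha": 0, "w": 0}
        self.proposal_counts = {"p": 0, "pi": 0, "alpha": 0, "w": 0}

    def _refresh_caches(self):
        self.ln_q = np.log(self.q)
        self.ln_1mq = np.log1p(-self.q)
        self.ln_p = np.log(self.p)
        self.ln_1mp = np.log1p(-self.p)
        self.a, self.b = _beta_ab(self.pi, self.alpha)
        # gammaln(a+b) depends only on alpha (per source)
        self.c = (1.0 - self.alpha) / self.alpha
        self.gammaln_c = gammaln(self.c)
        self.gammaln_a = gammaln(self.a)
        self.gammaln_b = gammaln(self.b)

    # -- updates ------------------------------------------------------------

    def update_p(self):
        """Random-walk logit update of source frequencies, per source, all loci."""
        y, n = self.y, self.n
        for s in range(self.S):
            z = self.rng.normal(size=self.L)
            lp_new = _logit(self.p[s]) + self.step_p[s] * z
            p_new = _expit(lp_new)
            p_new = np.clip(p_new, 1e-12, 1.0 - 1e-12)
            dq = self.w[:, s][:, None] * (p_new - self.p[s])[None, :]
            q_new = np.clip(self.q + dq, 1e-12, 1.0 - 1e-12)
            ln_qn, ln_1mqn = np.log(q_new), np.log1p(-q_new)
            d_geno = (y * (ln_qn - self.ln_q) + (n - y) * (ln_1mqn - self.ln_1mq)).sum(axis=0)
            ln_pn, ln_1mpn = np.log(p_new), np.log1p(-p_new)
            d_prior = ((self.a[s] - 1.0) * (ln_pn - self.ln_p[s])
                       + (self.b[s] - 1.0) * (ln_1mpn - self.ln_1mp[s]))
            d_jac = ln_pn + ln_1mpn - self.ln_p[s] - self.ln_1mp[s]
            accept = np.log(self.rng.uniform(size=self.L)) < d_geno + d_prior + d_jac
            if accept.any():
                self.p[s, accept] = p_new[accept]
                self.ln_p[s, accept] = ln_pn[accept]
                self.ln_1mp[s, accept] = ln_1mpn[accept]
                self.q[:, accept] = q_new[:, accept]
                self.ln_q[:, accept] = ln_qn[:, accept]
                self.ln_1mq[:, accept] = ln_1mqn[:, accept]
            self.accept_counts["p"] += int(accept.sum())
            self.proposal_counts["p"] += self.L

    def update_pi(self):
        """Random-walk logit update of ancestral frequencies, all loci at once."""
        z = self.rng.normal(size=self.L)
        pi_new = _expit(_logit(self.pi) + self.step_pi * z)
        pi_new = np.clip(pi_new, 1e-12, 1.0 - 1e-12)
        a_new = self.c[:, None] * pi_new[None, :]
        b_new = self.c[:, None] * (1.0 - pi_new[None, :])
        gammaln_a_new, gammaln_b_new = gammaln(a_new), gammaln(b_new)
        d_prior = ((a_new - self.a) * self.ln_p + (b_new - self.b) * self.ln_1mp
                   - (gammaln_a_new - self.gammaln_a)
                   - (gammaln_b_new - self.gammaln_b)).sum(axis=0)
        d_jac = (np.log(pi_new) + np.log1p(-pi_new)
                 - np.log(self.pi) - np.log1p(-self.pi))
        accept = np.log(self.rng.uniform(size=self.L)) < d_prior + d_jac
        if accept.any():
            self.pi[accept] = pi_new[accept]
            self.a[:, accept] = a_new[:, accept]
            self.b[:, accept] = b_new[:, accept]
            self.gammaln_a[:, accept] = gammaln_a_new[:, accept]
            self.gammaln_b[:, accept] = gammaln_b_new[:, accept]
        self.accept_counts["pi"] += int(accept.sum())
        self.proposal_counts["pi"] += self.L

    def update_alpha(self):
        """Random-walk update of per-source drift on the logit of (lo, hi)."""
        lo, hi = _ALPHA_LO, _ALPHA_HI
        for s in range(self.S):
            u = (self.alpha[s] - lo) / (hi - lo)
            u_new = _expit(_logit(u) + self.step_alpha[s] * self.rng.normal())
            alpha_new = lo + (hi - lo) * u_new
            c_new = (1.0 - alpha_new) / alpha_new
            a_new = c_new * self.pi
            b_new = c_new * (1.0 - self.pi)
            gammaln_a_new, gammaln_b_new = gammaln(a_new), gammaln(b_new)
            gammaln_c_new = gammaln(c_new)
            d = ((a_new - self.a[s]) * self.ln_p[s]
                 + (b_new - self.b[s]) * self.ln_1mp[s]
                 - gammaln_a_new + self.gammaln_a[s]
                 - gammaln_b_new + self.gammaln_b[s]).sum()
            d += self.L * (gammaln_c_new - self.gammaln_c[s])
            d += np.log(u_new) + np.log1p(-u_new) - np.log(u) - np.log1p(-u)
            self.proposal_counts["alpha"] += 1
            if np.log(self.rng.uniform()) < d:
                self.alpha[s] = alpha_new
                self.c[s] = c_new
                self.a[s], self.b[s] = a_new, b_new
                self.gammaln_a[s], self.gammaln_b[s] = gammaln_a_new, gammaln_b_new
                self.gammaln_c[s] = gammaln_c_new
                self.accept_counts["alpha"] += 1

    def update_w(self):
        """Dirichlet-proposal Metropolis update of each admixture row."""
        if self.S == 1:
            return
        floor = 0.05
        for j in range(self.P):
            conc = self.kappa_w[j] * self.w[j] + floor
            w_new = self.rng.dirichlet(conc)
            w_new = np.clip(w_new, 1e-10, None)
            w_new = w_new / w_new.sum()
            q_new = np.clip(w_new @ self.p, 1e-12, 1.0 - 1e-12)
            ln_qn, ln_1mqn = np.log(q_new), np.log1p(-q_new)
            d = (self.y[j] * (ln_qn - self.ln_q[j])
                 + (self.n[j] - self.y[j]) * (ln_1mqn - self.ln_1mq[j])).sum()
            conc_rev = self.kappa_w[j] * w_new + floor
            d += _dirichlet_logpdf(self.w[j], conc_rev) - _dirichlet_logpdf(w_new, conc)
            self.proposal_counts["w"] += 1
            if np.log(self.rng.uniform()) < d:
                self.w[j] = w_new
                self.q[j] = q_new
                self.ln_q[j] = ln_qn
                self.ln_1mq[j] = ln_1mqn
                self.accept_counts["w"] += 1

    def sweep(self):
        self.update_p()
        self.update_pi()
        self.update_alpha()
        self.update_w()

    def adapt(self, window: int):
        """Robbins-Monro step-size adaptation toward ~30% acceptance."""
        target = 0.30
        rates = {k: self.accept_counts[k] / max(self.proposal_counts[k], 1)
                 for k in self.accept_counts}
        gain = 0.6
        self.step_p *= np.exp(gain * (rates["p"] - target))
        self.step_pi *= np.exp(gain * (rates["pi"] - target))
        self.step_alpha *= np.exp(gain * (rates["alpha"] - target))
        # larger kappa = smaller simplex moves
        self.kappa_w *= np.exp(gain * (target - rates["w"]))
        self.kappa_w = np.clip(self.kappa_w, 5.0, 1e6)
        self.step_p = np.clip(self.step_p, 1e-3, 5.0)
        self.step_pi = float(np.clip(self.step_pi, 1e-3, 5.0))
        self.step_alpha = np.clip(self.step_alpha, 1e-3, 5.0)
        for k in self.accept_counts:
            self.accept_counts[k] = 0
            self.proposal_counts[k] = 0

    def theta(self) -> np.ndarray:
        return (self.w * self.alpha[None, :]) @ self.w.T

    def acceptance_rates(self) -> dict[str, float]:
        return {k: self.accept_counts[k] / max(self.proposal_counts[k], 1)
                for k in self.accept_counts}


def _psrf_array(x: np.ndarray) -> np.ndarray:
    """Vectorised classical Gelman-Rubin over leading (chains, samples) axes."""
    m, n = x.shape[:2]
    within = x.var(axis=1, ddof=1)
    w = within.mean(axis=0)
    b = n * x.mean(axis=1).var(axis=0, ddof=1)
    out = np.ones_like(w)
    ok = w > 0
    out[ok] = np.sqrt(((n - 1) / n * w[ok] + b[ok] / n) / w[ok])
    return out


def fit_afm(g: GenotypeMatrix, n_chains: int = 10, burn_in: int = 5000,
            iters: int = 2500, thin: int = 5, seed: int = 0,
            n_sources: int | None = None, shared_source: bool = False,
            progress: bool = False) -> CoancestryPosterior:
    """Multi-chain Metropolis sampling of the coancestry posterior.

    ``iters`` post-burn-in iterations are run per chain, every ``thin``-th
    retained.  Sources default to one per population; ``shared_source`` adds
    one extra source shared by all populations (admixed preset analogue).
    Monomorphic loci are dropped with a warning: they carry no drift
    information.  Returns pooled samples, per-entry PSRF across chains and
    the chain-averaged posterior mean.
    """
    if n_chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    pops, y, n, _ = _sufficient_stats(g)
    pooled = y.sum(axis=0) / np.maximum(n.sum(axis=0), 1.0)
    poly = (pooled > 0) & (pooled < 1)
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic loci", stacklevel=2)
        y, n = y[:, poly], n[:, poly]
    if y.shape[1] == 0:
        raise ValueError("no polymorphic loci available")
    p_pops = len(pops)
    s_sources = n_sources if n_sources is not None else p_pops
    if shared_source and n_sources is None:
        s_sources = p_pops + 1

    n_kept = iters // thin
    kept = np.empty((n_chains, n_kept, p_pops, p_pops))
    acc_all: dict[str, float] = {}
    adapt_window = 50
    for c in range(n_chains):
        rng = np.random.default_rng([seed % (2**31), 7, c])
        chain = _AFMChain(y, n, s_sources, rng, shared_source=shared_source)
        for it in range(burn_in):
            chain.sweep()
            if (it + 1) % adapt_window == 0:
                chain.adapt(adapt_window)
        k = 0
        for it in range(iters):
            chain.sweep()
            if (it + 1) % thin == 0 and k < n_kept:
                kept[c, k] = chain.theta()
                k += 1
        for key, rate in chain.acceptance_rates().items():
            acc_all[key] = acc_all.get(key, 0.0) + rate / n_chains
        if progress:
            print(f"chain {c + 1}/{n_chains} done", flush=True)
    psrf_entries = _psrf_array(kept)
    posterior_mean = kept.mean(axis=(0, 1))  # chain-averaged, as in practice
    return CoancestryPosterior(
        populations=pops,
        samples_by_chain=kept,
        psrf_per_entry=psrf_entries,
        posterior_mean=posterior_mean,
        acceptance=acc_all,
        burn_in=burn_in,
        thin=thin,
    )
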