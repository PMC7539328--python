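"""Bayesian animal model for the half-sib common garden.

Phenotypes decompose as ``y = Xb + Z_p p + Z_m m + Z_a a + e`` with block
fixed effects (and optionally seed weight as a fixed covariate), a random
population-of-origin effect, an optional random maternal term, breeding
values ``a`` with covariance ``A * V_A`` from the pedigree relationship
matrix, and iid residuals.  Estimation is by Gibbs sampling with conjugate
updates: normal draws for location effects, scaled-inverse-chi-squared draws
for variance components (weak default priors), and an inverse-Wishart prior
on the 2x2 additive covariance in the bivariate model.

For sampling, breeding values of phenotyped offspring use the exact marginal
family decomposition of A under unknown, unrelated sires: a family component
with variance ``rho_sib * V_A`` (sib-sib covariance) plus an individual
component with variance ``(1 - rho_sib) * V_A``.  ``rho_sib`` defaults to
0.25 (half-sibs) and can be raised toward 0.5 (full sibs) or ~1 (selfing)
for mating-system sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Pedigree, PhenotypeTable, psrf

__all__ = [
    "RelationshipMatrix", "VarianceComponents", "build_A", "fit_animal_model",
    "heritability", "heritability_samples", "cv_a", "genetic_correlation",
    "GeneticCorrelationResult",
]

_NU0 = 1.0  # prior degrees of freedom for every variance component


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix A in a fixed individual order."""

    individual_order: list[str]
    A: np.ndarray

    def loc(self, i: str, j: str) -> float:
        idx = {ind: k for k, ind in enumerate(self.individual_order)}
        return float(self.A[idx[i], idx[j]])


@dataclass
class VarianceComponents:
    """Posterior variance components of a univariate animal model fit."""

    V_A: float
    V_pop: float
    V_M: float
    V_E: float
    trait_mean: float
    samples: dict[str, np.ndarray] = field(default_factory=dict)
    psrf: dict[str, float] = field(default_factory=dict)
    family_effects: "pd.Series | None" = None  # posterior mean family (genetic) effects

    @property
    def V_T(self) -> float:
        return self.V_A + self.V_pop + self.V_M + self.V_E


def build_A(ped: Pedigree, rho_sib: float = 0.25) -> RelationshipMatrix:
    """Tabular-method additive relationships with unknown, unrelated sires.

    Non-inbred diagonal 1; mother-offspring 0.5; maternal sibs ``rho_sib``
    (0.25 under half-sib open pollination; the option rescales sib-sib
    entries for mating-system sensitivity analyses).
    """
    t = ped.table
    order = t["individual_id"].tolist()
    idx = {ind: k for k, ind in enumerate(order)}
    mothers = dict(zip(t["individual_id"], t["mother_id"]))
    # founders first is guaranteed by the Pedigree invariant check; still,
    # verify mothers precede their offspring to rule out cycles
    n = len(order)
    a = np.zeros((n, n))
    for k, ind in enumerate(order):
        mid = mothers[ind]
        if mid is not None:
            m = idx.get(mid)
            if m is None or m >= k:
                raise ValueError(f"pedigree not sorted or cyclic at {ind!r}")
            a[k, :k] = 0.5 * a[m, :k]
            a[:k, k] = a[k, :k]
        a[k, k] = 1.0
    if rho_sib != 0.25:
        # rescale maternal-sib entries only
        for mid in set(m for m in mothers.values() if m is not None):
            sibs = [idx[i] for i, m in mothers.items() if m == mid]
            for x in sibs:
                for z in sibs:
                    if x != z:
                        a[x, z] = rho_sib
    return RelationshipMatrix(individual_order=order, A=a)


# ---------------------------------------------------------------------------
# design extraction
# ---------------------------------------------------------------------------

@dataclass
class _Design:
    y: np.ndarray
    block_idx: np.ndarray
    pop_idx: np.ndarray
    fam_idx: np.ndarray  # per observation
    ind_idx: np.ndarray  # per observation
    ind_fam: np.ndarray  # family of each individual
    sw: np.ndarray | None  # centred seed weight, or None
    n_blocks: int
    n_pops: int
    n_fams: int
    n_inds: int
    blocks: list[str]
    pops: list[str]
    fams: list[str]
    inds: list[str]


def _extract_design(df: pd.DataFrame, ped: Pedigree, use_seed_weight: bool) -> _Design:
    t = ped.table.set_index("individual_id")
    missing = set(df["individual_id"]) - set(t.index)
    if missing:
        raise ValueError(f"phenotyped individuals absent from pedigree: {sorted(missing)[:5]}")
    mother = t.loc[df["individual_id"], "mother_id"].to_numpy()
    pop = t.loc[df["individual_id"], "population"].astype(str).to_numpy()
    # founders with records act as their own singleton family
    fam = np.where(pd.isna(mother), df["individual_id"].to_numpy(), mother)

    def codes(values):
        labels = list(dict.fromkeys(values))
        lut = {v: i for i, v in enumerate(labels)}
        return np.array([lut[v] for v in values]), labels

    block_idx, blocks = codes(df["block"].astype(str).tolist())
    pop_idx, pops = codes(list(pop))
    fam_idx, fams = codes(list(fam))
    ind_idx, inds = codes(df["individual_id"].astype(str).tolist())
    if len(blocks) < 2:
        warnings.warn("fewer than 2 blocks; block effects barely identified", stacklevel=3)
    ind_fam = np.zeros(len(inds), dtype=int)
    ind_fam[ind_idx] = fam_idx
    sw = None
    if use_seed_weight:
        sw_raw = df["seed_weight"].to_numpy(dtype=float)
        if np.isnan(sw_raw).any() or np.nanstd(sw_raw) < 1e-10:
            warnings.warn("seed weight missing or constant; covariate dropped", stacklevel=3)
        else:
            sw = sw_raw - sw_raw.mean()
    # warn on confounded designs (population nested in one block)
    for j, p in enumerate(pops):
        if len(set(block_idx[pop_idx == j])) == 1 and len(blocks) > 1:
            warnings.warn(f"population {p} observed in a single block", stacklevel=3)
    return _Design(
        y=df["value"].to_numpy(dtype=float),
        block_idx=block_idx, pop_idx=pop_idx, fam_idx=fam_idx, ind_idx=ind_idx,
        ind_fam=ind_fam, sw=sw,
        n_blocks=len(blocks), n_pops=len(pops), n_fams=len(fams), n_inds=len(inds),
        blocks=blocks, pops=pops, fams=fams, inds=inds,
    )


def _inv_chi2(rng, df, scale_sum):
    """Draw from the scaled-inverse-chi-squared full conditional."""
    return scale_sum / rng.chisquare(df)


# ---------------------------------------------------------------------------
# univariate Gibbs sampler
# ---------------------------------------------------------------------------

def fit_animal_model(y: PhenotypeTable, ped: Pedigree, trait: str | None = None,
                     chains: int = 2, burn_in: int = 1000, iters: int = 2000,
                     thin: int = 2, seed: int = 0, rho_sib: float = 0.25,
                     seed_weight: str = "covariate") -> VarianceComponents:
    """Gibbs sampling of the univariate animal model.

    ``seed_weight`` is ``"covariate"`` (fixed regression, default),
    ``"maternal"`` (random maternal term with variance ``V_M`` instead) or
    ``"none"``.  Returns posterior means and samples of the variance
    components plus multi-chain PSRF per component.
    """
    df = y.for_trait(trait) if trait is not None else y.for_trait(y.traits[0])
    des = _extract_design(df, ped, use_seed_weight=(seed_weight == "covariate"))
    use_maternal = seed_weight == "maternal"
    vy = float(np.var(des.y))
    s0 = {"a": 0.25 * vy, "p": 0.1 * vy, "m": 0.1 * vy, "e": 0.25 * vy}

    n_kept = iters // thin
    names = ["V_A", "V_pop", "V_M", "V_E"]
    store = {k: np.zeros((chains, n_kept)) for k in names}
    fam_mean = np.zeros(des.n_fams)
    for c in range(chains):
        rng = np.random.default_rng([seed % (2**31), 11, c])
        s = _gibbs_univariate(des, rho_sib, use_maternal, s0, burn_in, iters,
                              thin, rng)
        for k in names:
            store[k][c] = s[k]
        fam_mean += s["u_mean"] / chains
    psrf_vals = {}
    for k in names:
        if chains < 2 or np.ptp(store[k]) == 0:  # constant (e.g. unused V_M)
            psrf_vals[k] = 1.0 if chains >= 2 else float("nan")
        else:
            psrf_vals[k] = psrf(list(store[k]))
    pooled = {k: store[k].reshape(-1) for k in names}
    return VarianceComponents(
        V_A=float(pooled["V_A"].mean()),
        V_pop=float(pooled["V_pop"].mean()),
        V_M=float(pooled["V_M"].mean()),
        V_E=float(pooled["V_E"].mean()),
        trait_mean=float(des.y.mean()),
        samples=pooled,
        psrf=psrf_vals,
        family_effects=pd.Series(fam_mean, index=des.fams),
    )


def _gibbs_univariate(des: _Design, rho: float, use_maternal: bool, s0: dict,
                      burn_in: int, iters: int, thin: int, rng) -> dict:
    y = des.y
    n_obs = len(y)
    block = np.zeros(des.n_blocks)
    beta = 0.0
    pop = np.zeros(des.n_pops)
    u = np.zeros(des.n_fams)
    mat = np.zeros(des.n_fams)
    delta = np.zeros(des.n_inds)
    s2a, s2p, s2m, s2e = s0["a"] * 2, s0["p"], s0["m"], s0["e"] * 2

    nb = np.bincount(des.block_idx, minlength=des.n_blocks).astype(float)
    npop = np.bincount(des.pop_idx, minlength=des.n_pops).astype(float)
    nf = np.bincount(des.fam_idx, minlength=des.n_fams).astype(float)
    ni = np.bincount(des.ind_idx, minlength=des.n_inds).astype(float)
    sw = des.sw
    sw_ss = float(sw @ sw) if sw is not None else 0.0

    def fitted():
        f = block[des.block_idx] + pop[des.pop_idx] + u[des.fam_idx] + delta[des.ind_idx]
        if sw is not None:
            f = f + beta * sw
        if use_maternal:
            f = f + mat[des.fam_idx]
        return f

    res = y - fitted()
    n_kept = iters // thin
    out = {k: np.zeros(n_kept) for k in ("V_A", "V_pop", "V_M", "V_E")}
    u_accum = np.zeros(des.n_fams)
    k = 0
    for it in range(burn_in + iters):
        # block fixed effects (flat prior)
        res += block[des.block_idx]
        sums = np.bincount(des.block_idx, weights=res, minlength=des.n_blocks)
        block = sums / nb + rng.normal(size=des.n_blocks) * np.sqrt(s2e / nb)
        res -= block[des.block_idx]
        # seed-weight covariate (flat prior)
        if sw is not None:
            res += beta * sw
            beta = float(res @ sw) / sw_ss + rng.normal() * np.sqrt(s2e / sw_ss)
            res -= beta * sw
        # population random effect
        res += pop[des.pop_idx]
        sums = np.bincount(des.pop_idx, weights=res, minlength=des.n_pops)
        prec = npop / s2e + 1.0 / s2p
        pop = sums / s2e / prec + rng.normal(size=des.n_pops) / np.sqrt(prec)
        res -= pop[des.pop_idx]
        # family genetic component (rho * V_A)
        res += u[des.fam_idx]
        sums = np.bincount(des.fam_idx, weights=res, minlength=des.n_fams)
        prec = nf / s2e + 1.0 / (rho * s2a)
        u = sums / s2e / prec + rng.normal(size=des.n_fams) / np.sqrt(prec)
        res -= u[des.fam_idx]
        # maternal random effect
        if use_maternal:
            res += mat[des.fam_idx]
            sums = np.bincount(des.fam_idx, weights=res, minlength=des.n_fams)
            prec = nf / s2e + 1.0 / s2m
            mat = sums / s2e / prec + rng.normal(size=des.n_fams) / np.sqrt(prec)
            res -= mat[des.fam_idx]
        # individual genetic component ((1 - rho) * V_A)
        res += delta[des.ind_idx]
        sums = np.bincount(des.ind_idx, weights=res, minlength=des.n_inds)
        prec = ni / s2e + 1.0 / ((1.0 - rho) * s2a)
        delta = sums / s2e / prec + rng.normal(size=des.n_inds) / np.sqrt(prec)
        res -= delta[des.ind_idx]
        # variance components
        ss_a = (u @ u) / rho + (delta @ delta) / (1.0 - rho)
        s2a = _inv_chi2(rng, _NU0 + des.n_fams + des.n_inds, _NU0 * s0["a"] + ss_a)
        s2p = _inv_chi2(rng, _NU0 + des.n_pops, _NU0 * s0["p"] + pop @ pop)
        if use_maternal:
            s2m = _inv_chi2(rng, _NU0 + des.n_fams, _NU0 * s0["m"] + mat @ mat)
        s2e = _inv_chi2(rng, _NU0 + n_obs, _NU0 * s0["e"] + res @ res)
        if it >= burn_in and (it - burn_in + 1) % thin == 0 and k < n_kept:
            out["V_A"][k] = s2a
            out["V_pop"][k] = s2p
            out["V_M"][k] = s2m if use_maternal else 0.0
            out["V_E"][k] = s2e
            u_accum += u
            k += 1
    out["u_mean"] = u_accum / max(k, 1)
    return out


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def heritability_samples(vc: VarianceComponents) -> np.ndarray:
    """Posterior draws of h^2 = V_A / V_T."""
    s = vc.samples
    if not s:
        raise ValueError("no posterior samples stored")
    vt = s["V_A"] + s["V_pop"] + s["V_M"] + s["V_E"]
    return s["V_A"] / vt


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability h^2 = V_A / V_T (posterior mean if sampled)."""
    if vc.samples:
        return float(heritability_samples(vc).mean())
    if vc.V_T <= 0:
        raise ValueError("total phenotypic variance must be > 0")
    return vc.V_A / vc.V_T


def cv_a(vc: VarianceComponents) -> float:
    """Additive genetic coefficient of variation sqrt(V_A) / trait mean."""
    if vc.trait_mean <= 0:
        raise ValueError("CV_A requires a positive trait mean")
    if vc.samples:
        return float((np.sqrt(vc.samples["V_A"]) / vc.trait_mean).mean())
    return float(np.sqrt(vc.V_A) / vc.trait_mean)


# ---------------------------------------------------------------------------
# bivariate model / genetic correlation
# ---------------------------------------------------------------------------

@dataclass
class GeneticCorrelationResult:
    """Posterior of the additive genetic correlation between two traits."""

    traits: tuple[str, str]
    samples: np.ndarray  # r_g draws, all in [-1, 1]
    G_samples: np.ndarray  # (T, 2, 2) additive covariance draws
    low_va_warning: bool

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        tail = (1.0 - level) / 2.0
        return (float(np.quantile(self.samples, tail)),
                float(np.quantile(self.samples, 1.0 - tail)))


def _chol2(s11, s12, s22):
    """Batched Cholesky of 2x2 covariance matrices."""
    l11 = np.sqrt(s11)
    l21 = s12 / l11
    l22 = np.sqrt(np.maximum(s22 - l21**2, 1e-12))
    return l11, l21, l22


def genetic_correlation(y2: PhenotypeTable, ped: Pedigree,
                        traits: tuple[str, str] | None = None,
                        chains: int = 2, burn_in: int = 1000, iters: int = 2000,
                        thin: int = 2, seed: int = 0, rho_sib: float = 0.25,
                        ) -> GeneticCorrelationResult:
    """Bivariate Gibbs animal model; returns the posterior of r_g.

    The 2x2 additive covariance G carries an inverse-Wishart prior, so every
    draw is positive definite and every r_g draw lies in [-1, 1].  Residuals
    are modelled independent between traits (the simulated common-garden
    residuals are trait-specific measurement noise), so traits need only
    share families, not residual structure.  A near-zero additive variance in
    either trait triggers a warning and an honestly wide interval.
    """
    tr = traits if traits is not None else tuple(y2.traits[:2])
    if len(tr) != 2:
        raise ValueError("need exactly two traits")
    t1, t2 = y2.for_trait(tr[0]), y2.for_trait(tr[1])
    d1 = t1.set_index("individual_id")["value"]
    d2 = t2.set_index("individual_id")["value"]
    blk_map: dict[str, str] = {}
    for sub in (t1, t2):
        blk_map.update(dict(zip(sub["individual_id"].astype(str), sub["block"].astype(str))))
    inds = sorted(set(d1.index) | set(d2.index))
    t = ped.table.set_index("individual_id")
    missing = set(inds) - set(t.index)
    if missing:
        raise ValueError(f"phenotyped individuals absent from pedigree: {sorted(missing)[:5]}")
    mother = t.loc[inds, "mother_id"]
    fam = np.where(mother.isna(), inds, mother)
    fams = list(dict.fromkeys(fam))
    fam_lut = {f: i for i, f in enumerate(fams)}
    fam_idx = np.array([fam_lut[f] for f in fam])
    n_ind, n_fam = len(inds), len(fams)

    blocks = list(dict.fromkeys(blk_map.values()))
    blk_lut = {b: i for i, b in enumerate(blocks)}
    blk_idx = np.array([blk_lut[blk_map[i]] for i in inds])
    n_blk = len(blocks)

    yv = np.full((n_ind, 2), np.nan)
    yv[:, 0] = d1.reindex(inds).to_numpy()
    yv[:, 1] = d2.reindex(inds).to_numpy()
    obs = ~np.isnan(yv)
    if not (obs.any(axis=0).all()):
        raise ValueError("each trait needs at least one observation")
    shared_fams = set(fam[obs[:, 0]]) & set(fam[obs[:, 1]])
    if not shared_fams:
        raise ValueError("traits share no families; r_g not identifiable")
    yv0 = np.where(obs, yv, 0.0)
    vy = np.nanvar(yv, axis=0)
    means = np.nanmean(yv, axis=0)

    rho = rho_sib
    df0 = 4.0  # inverse-Wishart prior df (weakly informative, proper)
    S0 = np.diag(0.25 * vy) * (df0 - 3.0)  # prior mean 0.25 * phenotypic variance

    n_kept = iters // thin
    all_rg = np.zeros((chains, n_kept))
    all_g = np.zeros((chains, n_kept, 2, 2))
    from scipy.stats import invwishart

    for c in range(chains):
        rng = np.random.default_rng([seed % (2**31), 13, c])
        b_eff = np.tile(means, (n_blk, 1))  # per-block intercepts, each trait
        u = np.zeros((n_fam, 2))
        delta = np.zeros((n_ind, 2))
        g = np.diag(0.5 * vy)
        s2e = 0.5 * vy
        nfam_t = np.stack([np.bincount(fam_idx[obs[:, t_]], minlength=n_fam)
                           for t_ in range(2)], axis=1).astype(float)
        nblk_t = np.stack([np.bincount(blk_idx[obs[:, t_]], minlength=n_blk)
                           for t_ in range(2)], axis=1).astype(float)
        nobs_t = obs.sum(axis=0).astype(float)
        k = 0
        for it in range(burn_in + iters):
            # block fixed effects (flat prior), residuals independent by trait
            res = np.where(obs, yv0 - (b_eff[blk_idx] + u[fam_idx] + delta), 0.0)
            for t_ in range(2):
                sums = np.bincount(blk_idx, weights=(res[:, t_] + b_eff[blk_idx, t_])
                                   * obs[:, t_], minlength=n_blk)
                nb = np.maximum(nblk_t[:, t_], 1.0)
                b_eff[:, t_] = sums / nb + rng.normal(size=n_blk) * np.sqrt(s2e[t_] / nb)
            # family additive component u ~ N(0, rho G)
            res = np.where(obs, yv0 - (b_eff[blk_idx] + u[fam_idx] + delta), 0.0)
            res_u = res + np.where(obs, u[fam_idx], 0.0)
            rhs = np.stack([np.bincount(fam_idx, weights=res_u[:, t_] * obs[:, t_],
                                        minlength=n_fam) / s2e[t_]
                            for t_ in range(2)], axis=1)
            g_inv = np.linalg.inv(rho * g)
            p11 = nfam_t[:, 0] / s2e[0] + g_inv[0, 0]
            p22 = nfam_t[:, 1] / s2e[1] + g_inv[1, 1]
            p12 = np.full(n_fam, g_inv[0, 1])
            det = p11 * p22 - p12**2
            c11, c12, c22 = p22 / det, -p12 / det, p11 / det
            m1 = c11 * rhs[:, 0] + c12 * rhs[:, 1]
            m2 = c12 * rhs[:, 0] + c22 * rhs[:, 1]
            l11, l21, l22 = _chol2(c11, c12, c22)
            z = rng.normal(size=(n_fam, 2))
            u = np.stack([m1 + l11 * z[:, 0], m2 + l21 * z[:, 0] + l22 * z[:, 1]], axis=1)
            # individual additive component delta ~ N(0, (1-rho) G)
            res = np.where(obs, yv0 - (b_eff[blk_idx] + u[fam_idx] + delta), 0.0)
            res_d = res + np.where(obs, delta, 0.0)
            g_inv = np.linalg.inv((1.0 - rho) * g)
            rhs = np.stack([res_d[:, t_] * obs[:, t_] / s2e[t_] for t_ in range(2)], axis=1)
            p11 = obs[:, 0] / s2e[0] + g_inv[0, 0]
            p22 = obs[:, 1] / s2e[1] + g_inv[1, 1]
            p12 = np.full(n_ind, g_inv[0, 1])
            det = p11 * p22 - p12**2
            c11, c12, c22 = p22 / det, -p12 / det, p11 / det
            m1 = c11 * rhs[:, 0] + c12 * rhs[:, 1]
            m2 = c12 * rhs[:, 0] + c22 * rhs[:, 1]
            l11, l21, l22 = _chol2(c11, c12, c22)
            z = rng.normal(size=(n_ind, 2))
            delta = np.stack([m1 + l11 * z[:, 0], m2 + l21 * z[:, 0] + l22 * z[:, 1]], axis=1)
            # G | u, delta  (inverse-Wishart)
            s_mat = (u.T @ u) / rho + (delta.T @ delta) / (1.0 - rho)
            g = invwishart.rvs(df=df0 + n_fam + n_ind, scale=S0 + s_mat, random_state=rng)
            # residual variances per trait
            res = np.where(obs, yv0 - (b_eff[blk_idx] + u[fam_idx] + delta), 0.0)
            for t_ in range(2):
                ss = float(res[obs[:, t_], t_] @ res[obs[:, t_], t_])
                s2e[t_] = _inv_chi2(rng, _NU0 + nobs_t[t_], _NU0 * 0.25 * vy[t_] + ss)
            if it >= burn_in and (it - burn_in + 1) % thin == 0 and k < n_kept:
                all_g[c, k] = g
                all_rg[c, k] = g[0, 1] / np.sqrt(g[0, 0] * g[1, 1])
                k += 1
    rg = all_rg.reshape(-1)
    g_pooled = all_g.reshape(-1, 2, 2)
    low_va = bool((np.median(g_pooled[:, 0, 0]) < 1e-3 * vy[0])
                  or (np.median(g_pooled[:, 1, 1]) < 1e-3 * vy[1]))
    if low_va:
        warnings.warn("near-zero additive variance in one trait; r_g weakly identified",
                      stacklevel=2)
    return GeneticCorrelationResult(traits=tr, samples=rg, G_samples=g_pooled,
                                    low_va_warning=low_va)
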