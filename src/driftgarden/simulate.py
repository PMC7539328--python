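"""Truth-known simulator emulating the common-garden study design.

Generates SNP genotypes under the admixture F-model, half-sib pedigrees,
seedling phenotypes under the drift-null (or with planted selection shifts
tied to an environmental driver), and population-level environment tables.
Every generator is deterministic under the scenario seed, and every dataset
can be regenerated from the serialized :class:`ScenarioTruth`.

The emulated study samples 16 populations, genotypes 20 adults per
population at ~357 SNPs, and raises ~30 open-pollinated maternal families
of ~17 seedlings per population in 4 greenhouse blocks across 2 greenhouses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, Pedigree, PhenotypeTable

__all__ = [
    "ScenarioTruth", "star_scenario", "admixed_scenario", "study_scenario",
    "simulate_genotypes", "simulate_pedigree", "simulate_phenotypes",
    "simulate_environment",
]


@dataclass
class ScenarioTruth:
    """Ground-truth parameters of one simulated scenario.

    ``theta_true`` is the coancestry matrix realised by the admixture
    factorization ``theta = W diag(alpha) W^T`` stored alongside it; the
    drift-null population additive means have covariance
    ``2 * sigma2_A * theta_true`` and selection scenarios add
    ``driver_slope * driver`` on top.
    """

    n_pops: int
    theta_true: np.ndarray  # (P, P)
    admixture_W: np.ndarray  # (P, S) rows sum to 1
    source_alpha: np.ndarray  # (S,) drift intensity per source
    sigma2_A: float = 0.4
    sigma2_E: float = 0.6
    sigma2_M: float = 0.0
    block_effects: np.ndarray | None = None
    ancestral_mean: float = 10.0
    pop_shifts: np.ndarray | None = None
    driver: np.ndarray | None = None
    driver_slope: float = 0.0
    seed: int = 0
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        self.admixture_W = np.asarray(self.admixture_W, dtype=float)
        self.source_alpha = np.asarray(self.source_alpha, dtype=float)
        p = self.n_pops
        if self.theta_true.shape != (p, p):
            raise ValueError("theta_true must be P x P")
        if not np.allclose(self.theta_true, self.theta_true.T):
            raise ValueError("theta_true must be symmetric")
        if not np.allclose(self.admixture_W.sum(axis=1), 1.0):
            raise ValueError("admixture weight rows must sum to 1")
        if ((self.source_alpha < 0) | (self.source_alpha >= 1)).any():
            raise ValueError("source drift alpha must be in [0, 1)")
        implied = self.admixture_W @ np.diag(self.source_alpha) @ self.admixture_W.T
        if not np.allclose(implied, self.theta_true, atol=1e-10):
            raise ValueError(
                "theta_true is not realised by the stored (W, alpha) factorization; "
                "use the star or admixed scenario presets"
            )
        if self.pop_shifts is None:
            self.pop_shifts = np.zeros(p)
        self.pop_shifts = np.asarray(self.pop_shifts, dtype=float)
        if self.driver is None:
            self.driver = np.zeros(p)
        self.driver = np.asarray(self.driver, dtype=float)
        if self.block_effects is None:
            self.block_effects = np.array([0.0, 0.3, -0.2, 0.5])
        self.block_effects = np.asarray(self.block_effects, dtype=float)
        if not self.populations:
            self.populations = [f"pop{j + 1:02d}" for j in range(p)]
        if self.sigma2_E <= 0:
            raise ValueError("sigma2_E must be > 0")

    @property
    def scenario(self) -> str:
        """'neutral' when no selection shift is planted, else 'selection'."""
        neutral = self.driver_slope == 0 and not np.any(self.pop_shifts)
        return "neutral" if neutral else "selection"

    def effective_shifts(self) -> np.ndarray:
        """Planted population shifts: explicit shifts plus driver_slope * driver."""
        return self.pop_shifts + self.driver_slope * self.driver

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator for one simulation stream."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    def to_json(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("theta_true", "admixture_W", "source_alpha", "block_effects",
                  "pop_shifts", "driver"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def star_scenario(n_pops: int, drift, seed: int = 0, **kwargs) -> ScenarioTruth:
    """Star topology: every population drifts independently from the ancestor.

    ``drift`` is a scalar or per-population vector of coancestry diagonals;
    off-diagonal coancestry is zero (no admixture, W = I).
    """
    alpha = np.broadcast_to(np.asarray(drift, dtype=float), (n_pops,)).copy()
    w = np.eye(n_pops)
    theta = np.diag(alpha)
    return ScenarioTruth(n_pops=n_pops, theta_true=theta, admixture_W=w,
                         source_alpha=alpha, seed=seed, **kwargs)


def admixed_scenario(n_pops: int, own_drift, shared_drift: float = 0.05,
                     admix_weight: float = 0.2, seed: int = 0, **kwargs) -> ScenarioTruth:
    """Each population mixes its own drifted source with one shared source.

    Produces positive off-diagonal coancestry (regional-cluster analogue);
    setting ``admix_weight`` to 0 for one population isolates it (the
    island-population analogue).
    """
    own = np.broadcast_to(np.asarray(own_drift, dtype=float), (n_pops,)).copy()
    m = np.broadcast_to(np.asarray(admix_weight, dtype=float), (n_pops,)).copy()
    w = np.zeros((n_pops, n_pops + 1))
    for j in range(n_pops):
        w[j, j] = 1.0 - m[j]
        w[j, n_pops] = m[j]
    alpha = np.concatenate([own, [shared_drift]])
    theta = w @ np.diag(alpha) @ w.T
    return ScenarioTruth(n_pops=n_pops, theta_true=theta, admixture_W=w,
                         source_alpha=alpha, seed=seed, **kwargs)


def study_scenario(seed: int = 0, selection: bool = False,
                   driver_slope: float = 0.0, **kwargs) -> ScenarioTruth:
    """Study-scale scenario: 16 populations with heterogeneous drift.

    Fifteen populations carry moderate drift (0.02-0.12) and one isolated
    island analogue carries strong drift (0.30).  A standardized environmental
    driver is attached; ``selection`` plants shifts ``driver_slope * driver``.
    """
    rng = np.random.default_rng(seed)
    drift = np.concatenate([np.linspace(0.02, 0.12, 15), [0.30]])
    driver = rng.normal(size=16)
    driver = (driver - driver.mean()) / driver.std()
    slope = driver_slope if selection else 0.0
    return star_scenario(16, drift, seed=seed, driver=driver,
                         driver_slope=slope, **kwargs)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def population_allele_frequencies(truth: ScenarioTruth, n_loci: int):
    """Ancestral and population allele frequencies of the genotype stream.

    Returns ``(pi, q)`` with ``q`` of shape (P, n_loci); drawn from the same
    reproducible stream :func:`simulate_genotypes` consumes, so the returned
    frequencies are exactly those underlying the genotypes for this truth.
    """
    rng = truth.rng(1)
    alpha, w = truth.source_alpha, truth.admixture_W
    n_sources = alpha.shape[0]
    pi = rng.uniform(0.05, 0.95, size=n_loci)
    p_src = np.empty((n_sources, n_loci))
    for s in range(n_sources):
        a = alpha[s]
        if a == 0:
            p_src[s] = pi
        else:
            c = (1.0 - a) / a
            p_src[s] = rng.beta(pi * c, (1.0 - pi) * c)
    return pi, w @ p_src


def simulate_genotypes(truth: ScenarioTruth, n_loci: int = 357,
                       n_per_pop: int = 20) -> GenotypeMatrix:
    """SNP genotypes under the admixture F-model.

    Per locus: ancestral frequency ``pi ~ U(0.05, 0.95)``; each source drifts
    to ``p_s ~ Beta(pi(1-a_s)/a_s, (1-pi)(1-a_s)/a_s)`` (mean ``pi``,
    variance ``a_s pi(1-pi)``; ``a_s = 0`` keeps ``pi`` exactly); population
    frequencies mix sources through W; individuals are Binomial(2, q).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    p_pops = truth.n_pops
    _, q = population_allele_frequencies(truth, n_loci)
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    rng = truth.rng(4)  # genotype stream, separate from the frequency stream
    calls = np.empty((p_pops * n_per_pop, n_loci), dtype=np.int8)
    individuals, pops = [], []
    for j in range(p_pops):
        rows = slice(j * n_per_pop, (j + 1) * n_per_pop)
        calls[rows] = rng.binomial(2, q[j], size=(n_per_pop, n_loci))
        individuals += [f"{truth.populations[j]}_A{i + 1:02d}" for i in range(n_per_pop)]
        pops += [truth.populations[j]] * n_per_pop
    return GenotypeMatrix(individual_id=individuals, population=pops,
                          locus_id=[f"snp{l + 1:04d}" for l in range(n_loci)],
                          calls=calls)


def simulate_pedigree(truth: ScenarioTruth, mothers_per_pop: int = 30,
                      offspring_per_mother: int = 17) -> Pedigree:
    """Half-sib pedigree: unrelated founder mothers, open-pollinated offspring."""
    if mothers_per_pop < 1 or offspring_per_mother < 0:
        raise ValueError("counts must be >= 1 mother and >= 0 offspring")
    rows = []
    for pop in truth.populations:
        for m in range(mothers_per_pop):
            mid = f"{pop}_M{m + 1:02d}"
            rows.append({"individual_id": mid, "mother_id": None,
                         "population": pop, "generation": "founder"})
            for o in range(offspring_per_mother):
                rows.append({"individual_id": f"{mid}_O{o + 1:02d}", "mother_id": mid,
                             "population": pop, "generation": "offspring"})
    return Pedigree(pd.DataFrame(rows))


def simulate_phenotypes(truth: ScenarioTruth, ped: Pedigree, n_blocks: int = 4,
                        trait: str = "height", year: int = 1998,
                        return_details: bool = False):
    """Seedling phenotypes under the drift-null with optional selection shifts.

    Population additive means are ``ancestral_mean + MVN(0, 2 sigma2_A theta)
    + shifts``; mothers deviate ``N(0, sigma2_A)`` around their population
    mean, offspring inherit half the maternal deviation plus a Mendelian /
    paternal term ``N(0, 0.75 sigma2_A)`` (open-pollinated sires from the
    same population), so sibs covary at ``0.25 sigma2_A`` and the full
    population mean is transmitted.  Observations add a block effect, a
    latent maternal effect (``N(0, sigma2_M)``, proxied by seed weight) and
    residual ``N(0, sigma2_E)``.
    """
    if truth.sigma2_E <= 0:
        raise ValueError("sigma2_E must be > 0")
    pops = truth.populations
    if set(ped.table["population"]) - set(pops):
        raise ValueError("pedigree populations unknown to the scenario")
    rng = truth.rng(2)
    p = truth.n_pops
    cov = 2.0 * truth.sigma2_A * truth.theta_true
    drift_draw = rng.multivariate_normal(np.zeros(p), cov, method="svd")
    alpha_pop = truth.ancestral_mean + drift_draw + truth.effective_shifts()
    pop_index = {name: j for j, name in enumerate(pops)}

    founders = ped.founders["individual_id"].tolist()
    u_mother = {m: rng.normal(0.0, np.sqrt(truth.sigma2_A)) for m in founders}
    m_eff = {m: rng.normal(0.0, np.sqrt(truth.sigma2_M)) if truth.sigma2_M > 0 else 0.0
             for m in founders}
    # thousand-seed weight as a noisy monotone proxy of the maternal effect
    sd_m = np.sqrt(truth.sigma2_M) if truth.sigma2_M > 0 else 1.0
    seed_weight = {m: max(1.0, 50.0 + 8.0 * m_eff[m] / sd_m + rng.normal(0.0, 2.0))
                   for m in founders}

    off = ped.offspring
    n = len(off)
    if truth.block_effects.shape[0] < n_blocks:
        raise ValueError("not enough block effects for n_blocks")
    blocks = rng.permutation(np.arange(n) % n_blocks)
    rows = []
    mendelian_sd = np.sqrt(0.75 * truth.sigma2_A)
    resid_sd = np.sqrt(truth.sigma2_E)
    details = {"alpha_pop": alpha_pop, "drift_draw": drift_draw}
    for k, r in enumerate(off.itertuples()):
        j = pop_index[r.population]
        a_val = alpha_pop[j] + 0.5 * u_mother[r.mother_id] + rng.normal(0.0, mendelian_sd)
        b = blocks[k]
        value = (truth.block_effects[b] + a_val + m_eff[r.mother_id]
                 + rng.normal(0.0, resid_sd))
        rows.append({
            "individual_id": r.individual_id, "trait": trait, "value": value,
            "block": f"B{b + 1}", "greenhouse": 1 if b < (n_blocks + 1) // 2 else 2,
            "year": year, "seed_weight": seed_weight[r.mother_id],
        })
    table = PhenotypeTable(pd.DataFrame(rows))
    table.table.attrs["scenario"] = truth.scenario
    return (table, details) if return_details else table


def simulate_environment(truth: ScenarioTruth, n_vars: int = 31,
                         n_correlated: int = 4, noise_sd: float = 0.5):
    """Per-population environment table with known driver structure.

    ``n_correlated`` variables are noisy linear images of ``truth.driver``
    (expected r-squared ``1/(1+noise_sd^2)`` recorded in the metadata); the
    remainder are independent standard normal noise.  Returns
    ``(table, metadata)``.
    """
    if n_correlated > n_vars:
        raise ValueError("n_correlated must be <= n_vars")
    rng = truth.rng(3)
    p = truth.n_pops
    cols = {}
    names = [f"env{v + 1:02d}" for v in range(n_vars)]
    for v in range(n_vars):
        if v < n_correlated:
            cols[names[v]] = truth.driver + noise_sd * rng.normal(size=p)
        else:
            cols[names[v]] = rng.normal(size=p)
    table = pd.DataFrame(cols, index=truth.populations)
    meta = {
        "correlated_variables": names[:n_correlated],
        "expected_r2": 1.0 / (1.0 + noise_sd**2),
        "noise_sd": noise_sd,
        "scenario": truth.scenario,
    }
    return table, meta
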