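"""Data model, file I/O, SNP filtering and MCMC convergence diagnostics.

The in-memory containers are thin dataclasses around numpy arrays and pandas
DataFrames.  Missing genotypes are encoded with the sentinel ``MISSING`` (-1)
everywhere in memory, written as ``NA`` in CSV and ``./.`` in VCF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("driftgarden")

#: in-memory sentinel for a missing genotype call
MISSING: int = -1


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci alt-allele counts with population labels.

    ``calls`` holds values in {0, 1, 2} or :data:`MISSING`; row ``i`` is
    individual ``individual_id[i]`` from population ``population[i]``.
    """

    individual_id: list[str]
    population: list[str]
    locus_id: list[str]
    calls: np.ndarray  # (n_individuals, n_loci) int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if len(self.individual_id) != n or len(self.population) != n:
            raise ValueError("individual/population labels do not match call rows")
        if len(self.locus_id) != m:
            raise ValueError("locus ids do not match call columns")
        if len(set(self.individual_id)) != n:
            raise ValueError("individual ids must be unique")
        if len(set(self.locus_id)) != m:
            raise ValueError("locus ids must be unique")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid genotype calls: {bad.tolist()}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        return list(dict.fromkeys(self.population))

    def maf(self) -> np.ndarray:
        """Pooled minor-allele frequency per locus, over non-missing calls."""
        obs = self.calls != MISSING
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        tot = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls.astype(object), columns=self.locus_id)
        df[df == MISSING] = pd.NA
        df.insert(0, "population", self.population)
        df.insert(0, "individual_id", self.individual_id)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")


@dataclass
class Pedigree:
    """Half-sib pedigree: founder mothers and open-pollinated offspring.

    Sires are always unknown (open pollination); ``mother_id`` is ``None``
    for founders.
    """

    table: pd.DataFrame  # columns: individual_id, mother_id, population, generation

    REQUIRED = ("individual_id", "mother_id", "population", "generation")

    def __post_init__(self) -> None:
        t = self.table
        missing = set(self.REQUIRED) - set(t.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        if t["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        founders = set(t.loc[t["generation"] == "founder", "individual_id"])
        off = t[t["generation"] == "offspring"]
        named = set(off["mother_id"].dropna())
        unknown = named - founders
        if unknown:
            raise ValueError(f"offspring reference unknown mothers: {sorted(unknown)[:5]}")
        if t.loc[t["generation"] == "founder", "mother_id"].notna().any():
            raise ValueError("founders must not have parents")

    @property
    def founders(self) -> pd.DataFrame:
        return self.table[self.table["generation"] == "founder"]

    @property
    def offspring(self) -> pd.DataFrame:
        return self.table[self.table["generation"] == "offspring"]

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        t = pd.read_csv(path, dtype={"individual_id": str, "population": str})
        t["mother_id"] = t["mother_id"].astype(object).where(t["mother_id"].notna(), None)
        return cls(t)


@dataclass
class PhenotypeTable:
    """Long-format trait observations: one row per (individual, trait, year)."""

    table: pd.DataFrame  # individual_id, trait, value, block, greenhouse, year, seed_weight

    REQUIRED = ("individual_id", "trait", "value", "block")

    def __post_init__(self) -> None:
        t = self.table
        missing = set(self.REQUIRED) - set(t.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        for col, default in (("greenhouse", 1), ("year", 0), ("seed_weight", np.nan)):
            if col not in t.columns:
                t[col] = default
        if (t["block"].astype(str).str.len() == 0).any():
            raise ValueError("empty block labels")
        sw = t["seed_weight"].dropna()
        if (sw <= 0).any():
            raise ValueError("seed_weight must be > 0 when present")
        key = t[["individual_id", "trait", "year"]]
        if key.duplicated().any():
            raise ValueError("duplicate (individual, trait, year) rows")

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.table["trait"]))

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.table[self.table["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no observations for trait {trait!r}")
        return sub.reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def read_csv(cls, path) -> "PhenotypeTable":
        t = pd.read_csv(path, dtype={"individual_id": str, "block": str})
        return cls(t)


@dataclass
class ChainSet:
    """Equal-length post-burn-in, post-thinning sample vectors from >=2 chains."""

    parameter_name: str
    chains: list[np.ndarray]
    burn_in: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        self.chains = [np.asarray(c, dtype=float) for c in self.chains]
        lengths = {len(c) for c in self.chains}
        if len(lengths) != 1:
            raise ValueError("all chains must have equal length")
        if lengths.pop() < 2:
            raise ValueError("chains must have length > 1")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "csv",
                   sample_populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from CSV or VCF.

    CSV dialect: header of locus ids after the two leading columns
    ``individual_id, population``; calls are 0/1/2 or ``NA``.  VCF input keeps
    biallelic SNV records only (multi-allelic records are dropped and logged)
    and requires a ``sample_populations`` map from sample name to population.
    """
    fmt = format.lower()
    if fmt == "csv":
        return _read_genotypes_csv(path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path, sample_populations)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_csv(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, dtype={0: str, 1: str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty genotype file") from exc
    if df.shape[1] < 3 or list(df.columns[:2]) != ["individual_id", "population"]:
        raise ParseError(
            f"{path}: expected leading columns 'individual_id,population' "
            f"then locus ids, got {list(df.columns[:3])}"
        )
    loci = [str(c) for c in df.columns[2:]]
    raw = df.iloc[:, 2:]
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(raw.columns):
        vals = raw[col]
        ok = vals.notna()
        try:
            numeric = pd.to_numeric(vals[ok])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric genotype in column {col!r}") from exc
        if not numeric.isin((0, 1, 2)).all():
            bad_row = numeric.index[~numeric.isin((0, 1, 2))][0]
            raise ParseError(
                f"{path}: invalid call at data line {bad_row + 2}, column {col!r}"
            )
        calls[ok.to_numpy(), j] = numeric.to_numpy()
    return GenotypeMatrix(
        individual_id=df["individual_id"].astype(str).tolist(),
        population=df["population"].astype(str).tolist(),
        locus_id=loci,
        calls=calls,
    )


def _read_genotypes_vcf(path, sample_populations: dict[str, str] | None) -> GenotypeMatrix:
    if sample_populations is None:
        raise ValueError("VCF input requires a sample -> population map")
    from cyvcf2 import VCF  # optional dependency, lazy import

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sample_populations]
    if unknown:
        raise ParseError(f"samples with unknown population: {unknown}")
    loci, columns = [], []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_dropped += 1
            logger.info("dropping multi-allelic record %s:%d", rec.CHROM, rec.POS)
            continue
        gts = rec.genotype.array()[:, :2]
        col = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        loci.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        columns.append(col.astype(np.int8))
    if n_dropped:
        logger.warning("dropped %d multi-allelic VCF records", n_dropped)
    if not loci:
        raise ParseError(f"{path}: no biallelic records")
    calls = np.column_stack(columns)
    return GenotypeMatrix(
        individual_id=samples,
        population=[sample_populations[s] for s in samples],
        locus_id=loci,
        calls=calls,
    )


def write_genotypes_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal single-contig VCF (missing calls as ``./.``)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=1>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individual_id) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, locus in enumerate(g.locus_id):
            cells = "\t".join(gt_map[int(c)] for c in g.calls[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t{cells}\n")


def read_genotypes_csv(path) -> GenotypeMatrix:
    return read_genotypes(path, "csv")


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

def filter_snps(g: GenotypeMatrix, maf_min: float = 0.05,
                missing_max: float = 0.10) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci with pooled MAF below ``maf_min`` or missingness above ``missing_max``.

    Boundary loci (MAF exactly ``maf_min``, missingness exactly ``missing_max``)
    are retained.  Returns the filtered matrix and an exclusion report with one
    row per dropped locus and its reason(s).
    """
    if g.n_loci == 0 or g.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    maf = g.maf()
    miss = g.missing_fraction()
    low_maf = ~(maf >= maf_min)  # NaN (all-missing locus) fails too
    high_miss = miss > missing_max
    drop = low_maf | high_miss
    rows = []
    for j in np.flatnonzero(drop):
        reasons = []
        if low_maf[j]:
            reasons.append("maf")
        if high_miss[j]:
            reasons.append("missing")
        rows.append({"locus_id": g.locus_id[j], "maf": maf[j],
                     "missing_fraction": miss[j], "reason": "+".join(reasons)})
    report = pd.DataFrame(rows, columns=["locus_id", "maf", "missing_fraction", "reason"])
    keep = ~drop
    if not keep.any():
        warnings.warn("all loci excluded by SNP filters", stacklevel=2)
    filtered = GenotypeMatrix(
        individual_id=list(g.individual_id),
        population=list(g.population),
        locus_id=[l for l, k in zip(g.locus_id, keep) if k],
        calls=g.calls[:, keep],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def psrf(chains: ChainSet | list | np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    Classical (non-rank-normalised) form
    ``sqrt(((n-1)/n * W + B/n) / W)`` with ``W`` the mean within-chain
    variance and ``B`` the between-chain variance of chain means times ``n``.
    """
    if isinstance(chains, ChainSet):
        arrs = chains.chains
    else:
        arrs = [np.asarray(c, dtype=float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("PSRF requires at least 2 chains")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("chains must have equal length")
    if n < 2:
        raise ValueError("chains too short")
    mat = np.stack(arrs)  # (m, n)
    within = mat.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0.0:
        warnings.warn("zero within-chain variance in all chains; PSRF set to 1.0",
                      stacklevel=2)
        return 1.0
    b = n * mat.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))
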