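"""Synthetic cohorts, genotypes, eQTL tables and RNA-seq counts with planted signals.

The generator emulates the structure of the study data the pipeline was
designed for: a tumor cohort with ethnicity/age/stage/subtype metadata,
per-population SNP allele frequencies, Hardy-Weinberg genotypes, and
negative-binomial expression counts in which planted eQTLs act additively
per alternate allele on the log2 scale of normalized expression. A
GroundTruth record of everything planted makes parameter recovery testable
without any external download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("I", "II", "III", "IV")
SUBTYPES = ("LA", "LB", "H2", "TN")

# Defaults mirror a matched breast-tumor cohort: Caucasian-American,
# African-American and Asian-American groups at roughly the matched sizes of
# the motivating study, with stage and subtype mixes typical of BRCA series.
DEFAULT_POPULATIONS = {"CA": 552, "AA": 138, "AS": 57}
DEFAULT_STAGE_PROBS = {"I": 0.18, "II": 0.55, "III": 0.22, "IV": 0.05}
DEFAULT_SUBTYPE_PROBS = {"LA": 0.50, "LB": 0.20, "H2": 0.10, "TN": 0.20}


@dataclass(frozen=True)
class PlantedEQTL:
    """One planted SNP->gene effect: ``beta`` log2 units per alternate allele."""

    snp_id: str
    gene_id: str
    beta: float
    freqs: dict  # population -> alternate-allele frequency


@dataclass
class SimulationConfig:
    populations: dict = field(default_factory=lambda: dict(DEFAULT_POPULATIONS))
    age_range: tuple = (30, 80)
    stage_probs: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_PROBS))
    subtype_probs: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PROBS))
    n_genes: int = 30
    n_snps: int = 50
    planted_eqtls: list = field(default_factory=list)
    baseline_log_mean: float = 5.0  # log2 of expected relative count level
    dispersion: float = 0.1  # NB dispersion alpha: var = mu + alpha*mu^2
    library_size_range: tuple = (800_000, 1_200_000)
    # Optional non-genetic per-population log2 expression shift applied to all
    # genes (confounding); off by default so null calibration stays clean.
    population_shift: dict = field(default_factory=dict)
    chrom: str = "22"
    snp_start: int = 42_000_000
    snp_spacing: int = 5_000
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.populations.values()):
            raise ValueError("population sample counts must be non-negative")
        for name, probs in (("stage_probs", self.stage_probs), ("subtype_probs", self.subtype_probs)):
            vals = np.asarray(list(probs.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must lie in [0,1] and sum to 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ValueError("invalid age_range")
        for pq in self.planted_eqtls:
            for f in pq.freqs.values():
                if not 0.0 <= f <= 1.0:
                    raise ValueError("planted frequencies must be in [0,1]")


@dataclass
class GenotypeMatrix:
    """Dosage matrix (SNPs x samples, values 0/1/2; -1 = missing) plus positions."""

    dosages: pd.DataFrame
    positions: pd.DataFrame  # index snp_id, columns chrom, pos

    def __post_init__(self):
        vals = self.dosages.to_numpy()
        if not np.isin(vals, (-1, 0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")


@dataclass
class GroundTruth:
    planted: list  # of PlantedEQTL
    frequencies: pd.DataFrame  # snp_id x population true alt-allele frequency
    true_log2fc: dict  # (gene_id, pop_test, pop_ref) -> expected log2 FC


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw sample metadata: one row per patient sample.

    Ages are uniform integers over ``age_range``; stage and subtype follow the
    configured categorical distributions. Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    stage_labels = list(config.stage_probs)
    stage_p = np.array([config.stage_probs[s] for s in stage_labels])
    sub_labels = list(config.subtype_probs)
    sub_p = np.array([config.subtype_probs[s] for s in sub_labels])
    lo, hi = config.age_range
    for pop in sorted(config.populations):
        n = config.populations[pop]
        ages = rng.integers(lo, hi + 1, size=n)
        stages = rng.choice(stage_labels, size=n, p=stage_p)
        subs = rng.choice(sub_labels, size=n, p=sub_p)
        for i in range(n):
            rows.append(
                dict(
                    sample_id=f"{pop}_{i:04d}",
                    population=pop,
                    age=int(ages[i]),
                    stage=str(stages[i]),
                    subtype=str(subs[i]),
                    condition="tumor",
                )
            )
    return pd.DataFrame(rows, columns=["sample_id", "population", "age", "stage", "subtype", "condition"])


def make_frequency_table(config: SimulationConfig) -> pd.DataFrame:
    """True per-population alternate-allele frequencies for every SNP.

    Planted SNPs use their configured frequencies; the remaining (null) SNPs
    share a single frequency across populations, drawn uniform on
    [0.05, 0.95], so their between-population frequency difference is exactly
    zero. Index: snp_id; columns: one per population, plus chrom and pos.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    pops = sorted(config.populations)
    planted_ids = [p.snp_id for p in config.planted_eqtls]
    snp_ids = planted_ids + [f"snp{i:04d}" for i in range(config.n_snps - len(planted_ids))]
    freqs = pd.DataFrame(index=pd.Index(snp_ids, name="snp_id"), columns=pops, dtype=float)
    for p in config.planted_eqtls:
        for pop in pops:
            freqs.loc[p.snp_id, pop] = p.freqs[pop]
    null_ids = snp_ids[len(planted_ids):]
    shared = rng.uniform(0.05, 0.95, size=len(null_ids))
    for pop in pops:
        freqs.loc[null_ids, pop] = shared
    freqs["chrom"] = config.chrom
    freqs["pos"] = [config.snp_start + i * config.snp_spacing for i in range(len(snp_ids))]
    return freqs


def simulate_genotypes(samples: pd.DataFrame, freqs: pd.DataFrame, seed: int) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, f_{pop,snp})."""
    rng = np.random.default_rng(seed)
    pops = sorted(samples["population"].unique())
    missing = [p for p in pops if p not in freqs.columns]
    if missing:
        raise ValueError(f"no frequencies for population(s): {missing}")
    n_snps = len(freqs)
    dosages = np.empty((n_snps, len(samples)), dtype=np.int64)
    for j, pop in enumerate(samples["population"]):
        f = freqs[pop].to_numpy(dtype=float)
        dosages[:, j] = rng.binomial(2, f)
    dmat = pd.DataFrame(dosages, index=freqs.index, columns=list(samples["sample_id"]))
    return GenotypeMatrix(dosages=dmat, positions=freqs[["chrom", "pos"]].copy())


def simulate_counts(
    samples: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial counts with planted per-allele log2 expression effects.

    For a planted (snp, gene, beta), the gene's log2 relative expression rises
    by ``beta`` per alternate allele of the SNP; unplanted genes carry no
    genotype dependence. Relative expression levels are converted to expected
    counts by scaling to each sample's library size, then NB noise with the
    configured dispersion is added (gamma-Poisson mixture).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    planted_genes = [p.gene_id for p in config.planted_eqtls]
    gene_ids = planted_genes + [f"gene{i:04d}" for i in range(config.n_genes - len(planted_genes))]
    n_genes, n_samples = len(gene_ids), len(samples)

    # per-gene baseline spread mimics the wide dynamic range of real RNA-seq
    base = config.baseline_log_mean + rng.uniform(-2.0, 2.0, size=n_genes)
    log2_expr = np.tile(base[:, None], (1, n_samples))

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for p in config.planted_eqtls:
        dos = genotypes.dosages.loc[p.snp_id, list(samples["sample_id"])].to_numpy(dtype=float)
        log2_expr[gene_index[p.gene_id], :] += p.beta * dos
    if config.population_shift:
        shift = samples["population"].map(lambda q: config.population_shift.get(q, 0.0)).to_numpy()
        log2_expr += shift[None, :]

    rel = np.power(2.0, log2_expr)
    frac = rel / rel.sum(axis=0, keepdims=True)
    lib_lo, lib_hi = config.library_size_range
    libs = rng.integers(int(lib_lo), int(lib_hi) + 1, size=n_samples)
    mu = frac * libs[None, :]

    alpha = config.dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=list(samples["sample_id"]))

    pops = sorted(samples["population"].unique())
    true_freqs = pd.DataFrame(index=genotypes.dosages.index, columns=pops, dtype=float)
    for p in config.planted_eqtls:
        for pop in pops:
            true_freqs.loc[p.snp_id, pop] = p.freqs.get(pop, np.nan)
    true_fc = {}
    for p in config.planted_eqtls:
        for a in pops:
            for b in pops:
                if a != b and a in p.freqs and b in p.freqs:
                    true_fc[(p.gene_id, a, b)] = 2.0 * p.beta * (p.freqs[a] - p.freqs[b])
    truth = GroundTruth(planted=list(config.planted_eqtls), frequencies=true_freqs, true_log2fc=true_fc)
    return counts_df, truth


def make_eqtl_table(config: SimulationConfig, freqs: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """eQTL records for every SNP: planted SNPs keep their true beta; null SNPs
    get a nonzero beta (uniform +-[0.2, 0.6]) and a significant eQTL p-value, so
    they exercise the discovery filters and can only be excluded by the
    frequency-difference statistic itself."""
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    planted = {p.snp_id: p for p in config.planted_eqtls}
    gene_default = config.planted_eqtls[0].gene_id if config.planted_eqtls else "gene0000"
    rows = []
    for snp_id, row in freqs.iterrows():
        if snp_id in planted:
            beta = planted[snp_id].beta
            gene = planted[snp_id].gene_id
        else:
            beta = rng.uniform(0.2, 0.6) * rng.choice([-1.0, 1.0])
            gene = gene_default
        rows.append(
            dict(
                snp_id=snp_id,
                chrom=row["chrom"],
                pos=int(row["pos"]),
                gene_id=gene,
                effect_size=float(beta),
                pvalue=float(rng.uniform(1e-8, 0.009)),
                tissue="Breast_Mammary_Tissue",
            )
        )
    return pd.DataFrame(rows)
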