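"""Core inference: allele-frequency differences x eQTL effect sizes -> candidate SNPs.

For each SNP with an eQTL effect size beta (standardized expression change per
alternate allele) and alternate-allele frequencies f1, f2 in two populations,
the *calculated differential expression* is

    d = beta * (f1 - f2)

which approximates the standardized mean difference (X1-bar - X2-bar)/s of the
gene's expression between the populations. Scaling by the two-sample design
factor gives an approximate t-statistic

    t = d / sqrt(1/n1 + 1/n2)

so d must exceed z_{1-alpha} * sqrt(1/n1 + 1/n2) to reach significance alpha
(one-sided normal reference by default; at alpha = 0.01, n1 = 552, n2 = 138
this threshold is 0.2214, i.e. 0.22 at two decimals). Candidates must also
agree in sign with the observed differential expression, are optionally
confirmed against a held-out validation population, and are grouped into
linkage-disequilibrium proxy clusters by genomic proximity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestContext:
    """Sample sizes and significance settings for the t approximation."""

    n1: int
    n2: int
    alpha: float = 0.01
    sidedness: str = "one-sided"  # or "two-sided"
    reference: str = "normal"  # or "t" (Student t with n1+n2-2 df)

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("sample sizes must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sidedness not in ("one-sided", "two-sided"):
            raise ValueError("sidedness must be 'one-sided' or 'two-sided'")
        if self.reference not in ("normal", "t"):
            raise ValueError("reference must be 'normal' or 't'")


@dataclass
class CandidateSNP:
    snp_id: str
    chrom: str
    pos: int
    gene_id: str
    beta: float
    freqs: dict  # population -> alternate-allele frequency
    calculated_effect: float
    t_approx: float
    passes_threshold: bool
    sign_consistent: bool
    validated: bool | None = None
    cluster_id: int | None = None
    distance_kb: int | None = None


def allele_frequency(genotypes, member_ids: list) -> pd.Series:
    """Alternate-allele frequency per SNP over the given samples.

    f = (sum of dosages) / (2 x genotyped members); missing genotypes (coded
    -1) leave both numerator and denominator. SNPs with no genotyped member
    are dropped with a log entry.
    """
    if not member_ids:
        raise ValueError("member list is empty")
    d = genotypes.dosages[list(member_ids)].to_numpy(dtype=float)
    obs = d >= 0
    n_obs = obs.sum(axis=1)
    alt = np.where(obs, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        f = alt / (2.0 * n_obs)
    out = pd.Series(f, index=genotypes.dosages.index, name="alt_freq")
    dropped = out.index[n_obs == 0]
    if len(dropped):
        logger.warning("dropping %d SNP(s) with no genotyped member", len(dropped))
        out = out.drop(dropped)
    return out


def calculated_effect_size(beta: float, f1: float, f2: float) -> float:
    """beta x (f1 - f2): the predicted standardized expression difference."""
    for f in (f1, f2):
        if not 0.0 <= f <= 1.0:
            raise ValueError("allele frequencies must be in [0, 1]")
    return beta * (f1 - f2)


def t_approximation(calculated_effect: float, ctx: TTestContext) -> float:
    """Approximate two-sample t-statistic for the calculated effect."""
    return calculated_effect / math.sqrt(1.0 / ctx.n1 + 1.0 / ctx.n2)


def min_effect_threshold(ctx: TTestContext) -> float:
    """Smallest |calculated effect| reaching the critical value at ctx.alpha."""
    tail = ctx.alpha if ctx.sidedness == "one-sided" else ctx.alpha / 2.0
    if ctx.reference == "normal":
        crit = stats.norm.ppf(1.0 - tail)
    else:
        crit = stats.t.ppf(1.0 - tail, df=ctx.n1 + ctx.n2 - 2)
    return float(crit * math.sqrt(1.0 / ctx.n1 + 1.0 / ctx.n2))


def discover_candidates(
    eqtls: pd.DataFrame,
    freqs: pd.DataFrame,
    ctx: TTestContext,
    pop1: str,
    pop2: str,
    observed_sign: int,
    eqtl_p_max: float | None = 0.01,
    apply_threshold: bool = True,
) -> list:
    """Screen eQTL records for SNPs predicting the observed expression difference.

    Parameters
    ----------
    eqtls
        Columns snp_id, chrom, pos, gene_id, effect_size, pvalue.
    freqs
        Indexed by snp_id with one column per population.
    observed_sign
        +1 or -1: the sign of the gene's observed pop1-minus-pop2 differential
        expression, from the expression screen.
    eqtl_p_max
        Pre-filter on the eQTL association p-value (None disables).
    apply_threshold
        Whether to require |calculated effect| >= min_effect_threshold(ctx).

    Returns CandidateSNPs with passes_threshold AND sign_consistent, sorted by
    |calculated effect| descending, ties by genomic position.
    """
    if observed_sign not in (1, -1):
        raise ValueError("observed_sign must be +1 or -1")
    thr = min_effect_threshold(ctx)
    out = []
    for _, rec in eqtls.iterrows():
        if eqtl_p_max is not None and rec["pvalue"] > eqtl_p_max:
            continue
        snp = rec["snp_id"]
        if snp not in freqs.index or pd.isna(freqs.loc[snp, pop1]) or pd.isna(freqs.loc[snp, pop2]):
            logger.warning("SNP %s missing frequency for %s/%s; skipped", snp, pop1, pop2)
            continue
        f1, f2 = float(freqs.loc[snp, pop1]), float(freqs.loc[snp, pop2])
        d = calculated_effect_size(float(rec["effect_size"]), f1, f2)
        passes = (abs(d) >= thr) if apply_threshold else True
        consistent = d != 0 and (1 if d > 0 else -1) == observed_sign
        if passes and consistent:
            fdict = {p: float(freqs.loc[snp, p]) for p in freqs.columns if p not in ("chrom", "pos") and not pd.isna(freqs.loc[snp, p])}
            out.append(
                CandidateSNP(
                    snp_id=snp,
                    chrom=str(rec["chrom"]),
                    pos=int(rec["pos"]),
                    gene_id=str(rec["gene_id"]),
                    beta=float(rec["effect_size"]),
                    freqs=fdict,
                    calculated_effect=d,
                    t_approx=t_approximation(d, ctx),
                    passes_threshold=abs(d) >= thr,
                    sign_consistent=consistent,
                )
            )
    out.sort(key=lambda c: (-abs(c.calculated_effect), c.chrom, c.pos))
    return out


def validate_candidates(
    candidates: list,
    freqs: pd.DataFrame,
    pop1: str,
    validation_pop: str,
    observed_sign_val: int,
    ctx_val: TTestContext | None = None,
) -> list:
    """Flag candidates whose predicted pop1-vs-validation effect matches the
    observed sign in the held-out population.

    validated = sign(beta x (f_pop1 - f_val)) == observed_sign_val; if
    ``ctx_val`` is given, the predicted effect must also clear the threshold at
    the validation comparison's sample sizes. Missing validation frequency ->
    validated = None, logged.
    """
    if observed_sign_val not in (1, -1):
        raise ValueError("observed_sign_val must be +1 or -1")
    thr = min_effect_threshold(ctx_val) if ctx_val is not None else 0.0
    out = []
    for c in candidates:
        if c.snp_id not in freqs.index or pd.isna(freqs.loc[c.snp_id, validation_pop]):
            logger.warning("no %s frequency for %s; validation unknown", validation_pop, c.snp_id)
            out.append(replace(c, validated=None))
            continue
        f1 = c.freqs.get(pop1, float(freqs.loc[c.snp_id, pop1]))
        fv = float(freqs.loc[c.snp_id, validation_pop])
        pred = c.beta * (f1 - fv)
        ok = pred != 0 and (1 if pred > 0 else -1) == observed_sign_val and abs(pred) >= thr
        out.append(replace(c, validated=bool(ok)))
    return out


def cluster_by_proximity(candidates: list, max_gap_bp: int = 40_000) -> list:
    """Single-linkage positional clustering as a linkage-disequilibrium proxy.

    Within a chromosome, consecutive sorted positions at most ``max_gap_bp``
    apart share a cluster (boundary inclusive). Cluster ids are assigned from 1
    in order of (chromosome, leftmost position); SNPs on different chromosomes
    never share a cluster.
    """
    ordered = sorted(candidates, key=lambda c: (c.chrom, c.pos))
    out = []
    cid = 0
    prev = None
    for c in ordered:
        if prev is None or c.chrom != prev.chrom or c.pos - prev.pos > max_gap_bp:
            cid += 1
        out.append(replace(c, cluster_id=cid))
        prev = c
    return out


def distance_to_gene(snp_pos: int, gene_start: int, gene_end: int) -> int:
    """Distance in bp from a SNP to a gene interval (0 if inside, 1-based inclusive)."""
    if gene_start > gene_end:
        raise ValueError("gene_start must be <= gene_end")
    if gene_start <= snp_pos <= gene_end:
        return 0
    return gene_start - snp_pos if snp_pos < gene_start else snp_pos - gene_end


def tss_distance_kb(snp_pos: int, gene_start: int) -> int:
    """Display distance in kb, measured from the gene start coordinate and
    rounded to the nearest integer (the convention used for reporting)."""
    return round(abs(snp_pos - gene_start) / 1000.0)


def candidates_to_frame(candidates: list, gene_start: int | None = None) -> pd.DataFrame:
    """Tabulate candidates in the reporting layout (one row per SNP)."""
    rows = []
    for c in candidates:
        row = dict(
            snp_id=c.snp_id,
            location=f"{c.chrom}:{c.pos}",
            calculated_effect=c.calculated_effect,
            effect_size=c.beta,
            t_approx=c.t_approx,
            passes_threshold=c.passes_threshold,
            sign_consistent=c.sign_consistent,
            validated=c.validated,
            cluster_id=c.cluster_id,
        )
        for pop, f in sorted(c.freqs.items()):
            row[f"alt_freq_{pop}"] = f
        if gene_start is not None:
            row["distance_kb"] = tss_distance_kb(c.pos, gene_start)
        rows.append(row)
    if not rows:
        cols = ["snp_id", "location", "calculated_effect", "effect_size", "t_approx",
                "passes_threshold", "sign_consistent", "validated", "cluster_id"]
        if gene_start is not None:
            cols.append("distance_kb")
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
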