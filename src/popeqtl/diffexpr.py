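"""RPM normalization, two-group differential expression, BH-FDR and enrichment.

Counts are normalized to reads per million (RPM). Per-gene differential
expression between two matched patient groups — overall or restricted to a
stage group (ES = stages I-II, LS = III-IV) or molecular subtype
(LA/LB/H2/TN) — uses an unequal-variance (Welch) two-sample test on
log2(RPM + 1); fold changes are oriented to a stated reference group.
Significance applies the joint filter fold change >= 2 (either direction)
and BH-adjusted p <= 0.05. Gene-set enrichment of the significant genes is
an upper-tail hypergeometric test against a configurable background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

STRATA = ("All", "ES", "LS", "LA", "LB", "H2", "TN")
_STAGE_GROUPS = {"ES": ("I", "II"), "LS": ("III", "IV")}


@dataclass(frozen=True)
class Comparison:
    reference: str  # population label used as FC denominator
    test: str
    stratum: str = "All"

    def __post_init__(self):
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}; expected one of {STRATA}")


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (column) to one million reads.

    An all-zero library yields an all-zero column and a logged warning rather
    than an error, so degenerate simulated samples do not abort a run.
    """
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    totals = vals.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning("%d sample(s) have zero total counts; RPM set to 0", int(zero.sum()))
        totals[zero] = 1.0
    return counts * (1e6 / totals)


def _stratum_mask(meta: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "All":
        return pd.Series(True, index=meta.index)
    if stratum in _STAGE_GROUPS:
        return meta["stage"].isin(_STAGE_GROUPS[stratum])
    return meta["subtype"] == stratum


def de_test(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: Comparison,
    matched_ids: set | None = None,
    eps: float = 1.0,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch test between the comparison groups within a stratum.

    Parameters
    ----------
    expr
        RPM expression matrix, genes x samples.
    metadata
        Sample table with sample_id, population, stage, subtype columns.
    matched_ids
        Optional restriction to the samples retained by cohort matching.

    Returns a DataFrame with per-group mean RPM, fold_change (larger over
    smaller), log2fc oriented test-vs-reference, pvalue, padj and the
    significance flag. Genes with zero variance in both groups get p = 1.
    """
    meta = metadata.set_index("sample_id", drop=False)
    mask = _stratum_mask(meta, comparison.stratum)
    if matched_ids is not None:
        mask &= meta["sample_id"].isin(matched_ids)
    ref_ids = meta.index[mask & (meta["population"] == comparison.reference)]
    test_ids = meta.index[mask & (meta["population"] == comparison.test)]
    ref_ids = [s for s in ref_ids if s in expr.columns]
    test_ids = [s for s in test_ids if s in expr.columns]
    if len(ref_ids) < 2 or len(test_ids) < 2:
        logger.warning(
            "comparison %s vs %s stratum %s skipped: group sizes %d/%d",
            comparison.test, comparison.reference, comparison.stratum, len(test_ids), len(ref_ids),
        )
        return pd.DataFrame(
            columns=["gene_id", "mean_ref", "mean_test", "fold_change", "log2fc", "pvalue", "padj", "significant"]
        )

    ref = expr[ref_ids].to_numpy(dtype=float)
    tst = expr[test_ids].to_numpy(dtype=float)
    mean_ref = ref.mean(axis=1)
    mean_test = tst.mean(axis=1)
    log2fc = np.log2((mean_test + eps) / (mean_ref + eps))

    lref = np.log2(ref + 1.0)
    ltst = np.log2(tst + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(ltst, lref, axis=1, equal_var=False)
    zero_var = (lref.var(axis=1) == 0) & (ltst.var(axis=1) == 0)
    pvals = np.where(zero_var | ~np.isfinite(pvals), 1.0, pvals)

    padj = bh_adjust(pvals)
    fold = np.power(2.0, np.abs(log2fc))
    significant = (fold >= fc_threshold) & (padj <= p_threshold)
    return pd.DataFrame(
        dict(
            gene_id=expr.index,
            mean_ref=mean_ref,
            mean_test=mean_test,
            fold_change=fold,
            log2fc=log2fc,
            pvalue=pvals,
            padj=padj,
            significant=significant,
        )
    ).reset_index(drop=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_genes(results: pd.DataFrame, fc_threshold: float = 2.0, p_threshold: float = 0.05) -> pd.DataFrame:
    """Apply the joint filter |fold change| >= threshold and padj <= threshold (both inclusive)."""
    keep = (results["fold_change"] >= fc_threshold) & (results["padj"] <= p_threshold)
    return results.loc[keep].reset_index(drop=True)


def enrich(significant: list, gene_sets: dict, universe: list) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``significant`` in each gene set.

    Sets are intersected with the universe; p = P(overlap >= observed) when
    drawing len(significant) genes without replacement; BH across sets.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    sig = set(significant) & universe_set
    if set(significant) - universe_set:
        raise ValueError("significant genes must be a subset of the universe")
    big_n = len(universe_set)
    n_draw = len(sig)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe_set
        k = len(members & sig)
        # sf(k-1) = P(X >= k) for X ~ Hypergeom(N, |set|, n_draw)
        p = float(stats.hypergeom.sf(k - 1, big_n, len(members), n_draw))
        rows.append(dict(gene_set=name, overlap=k, set_size=len(members), universe_size=big_n, n_significant=n_draw, pvalue=min(p, 1.0)))
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["padj"] = []
    return out
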