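"""Packaged worked example: the CYP2D6 candidate-SNP screen.

Six chromosome-22 SNPs associated with CYP2D6 expression in breast tissue,
with their eQTL effect sizes and alternate-allele frequencies in
African-American (AA), Caucasian-American (CA) and Asian-American (AS)
populations. CYP2D6 is higher-expressed in AA than CA tumors, so discovery
uses observed_sign = +1 for the AA-vs-CA comparison at the matched cohort
sizes n_CA = 552, n_AA = 138; the AS population is held out for validation.
"""

from __future__ import annotations

import pandas as pd

CYP2D6_GENE = dict(gene_id="CYP2D6", chrom="22", start=42_126_499, end=42_130_906)
CYP2D6_N_CA = 552
CYP2D6_N_AA = 138

_ROWS = [
    # snp_id, pos, f_AA, f_CA, f_AS, effect_size
    ("rs72452", 42_481_849, 0.97, 0.54, 0.61, 0.53),
    ("rs5751220", 42_516_205, 0.97, 0.54, 0.62, 0.52),
    ("rs6002626", 42_517_989, 0.97, 0.54, 0.61, 0.53),
    ("rs714002", 42_569_024, 0.70, 0.21, 0.28, 0.52),
    ("rs713811", 42_569_870, 0.69, 0.21, 0.27, 0.52),
    ("rs2011944", 42_569_999, 0.68, 0.21, 0.27, 0.52),
]


def cyp2d6_eqtls() -> pd.DataFrame:
    """eQTL records for the six example SNPs (breast-tissue associations,
    all with eQTL p-value below the 0.01 screening cut)."""
    return pd.DataFrame(
        [
            dict(snp_id=s, chrom="22", pos=p, gene_id="CYP2D6", effect_size=b, pvalue=1e-4, tissue="Breast_Mammary_Tissue")
            for s, p, _, _, _, b in _ROWS
        ]
    )


def cyp2d6_frequencies() -> pd.DataFrame:
    """Alternate-allele frequencies per population, indexed by snp_id."""
    df = pd.DataFrame(
        [dict(snp_id=s, chrom="22", pos=p, AA=faa, CA=fca, AS=fas) for s, p, faa, fca, fas, _ in _ROWS]
    ).set_index("snp_id")
    return df
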