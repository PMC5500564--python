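"""Stage orchestration: simulate -> match -> DE -> discover -> validate.

``run_pipeline`` drives the stages from a single config mapping and writes a
JSON manifest (inputs, outputs, parameters, seeds, content hashes) so any run
is reproducible. ``end_to_end_discovery`` is the in-memory variant used for
parameter-recovery experiments: it simulates a cohort with planted eQTLs and
pushes it through matching, differential expression and SNP discovery.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from popeqtl import io as pio
from popeqtl.diffexpr import Comparison, de_test, enrich, rpm_normalize, significant_genes
from popeqtl.matching import MatchSpec, optimal_ratio_match
from popeqtl.simulate import (
    GroundTruth,
    PlantedEQTL,
    SimulationConfig,
    make_eqtl_table,
    make_frequency_table,
    simulate_cohort,
    simulate_counts,
    simulate_genotypes,
)
from popeqtl.snp_assoc import (
    TTestContext,
    allele_frequency,
    candidates_to_frame,
    cluster_by_proximity,
    discover_candidates,
    validate_candidates,
)

logger = logging.getLogger(__name__)

_STAGE_ORDER = ("simulate", "match", "de", "enrich", "snp_assoc")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (below 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    planted = [PlantedEQTL(**p) for p in d.pop("planted_eqtls", [])]
    for key in ("age_range", "library_size_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(planted_eqtls=planted, **d)


def end_to_end_discovery(
    config: SimulationConfig,
    pop1: str,
    pop2: str,
    gene_id: str,
    validation_pop: str | None = None,
    match_spec: MatchSpec = MatchSpec(),
    alpha: float = 0.01,
    eqtl_p_max: float | None = 0.01,
) -> dict:
    """Simulate, match, test expression, and discover candidate SNPs for one gene.

    Frequencies entering discovery are *estimated* from the simulated
    genotypes (as they would be from a reference panel), not the generator's
    true values. The t-approximation sample sizes are the matched group sizes,
    and the observed expression sign is taken from the Welch screen on the
    matched cohort. Returns a dict with the intermediate artifacts and the
    validated candidate list.
    """
    samples = simulate_cohort(config)
    true_freqs = make_frequency_table(config)
    genotypes = simulate_genotypes(samples, true_freqs, seed=stage_seed(config.seed, "genotypes"))
    counts, truth = simulate_counts(samples, genotypes, config)
    eqtls = make_eqtl_table(config, true_freqs)

    group1 = samples[samples["population"] == pop1]
    group2 = samples[samples["population"] == pop2]
    match = optimal_ratio_match(group1, group2, match_spec)
    matched_ids = {a for a, _ in match.pairs} | {b for _, b in match.pairs}

    expr = rpm_normalize(counts)
    comp = Comparison(reference=pop2, test=pop1, stratum="All")
    de = de_test(expr, samples, comp, matched_ids=matched_ids)
    gene_row = de[de["gene_id"] == gene_id]
    if gene_row.empty:
        raise ValueError(f"gene {gene_id} absent from expression screen")
    observed_sign = 1 if float(gene_row["log2fc"].iloc[0]) >= 0 else -1

    n1 = len({a for a, _ in match.pairs} & set(group1["sample_id"])) or len(group1)
    n2 = len(matched_ids - set(group1["sample_id"])) or len(group2)
    ctx = TTestContext(n1=max(n1, 2), n2=max(n2, 2), alpha=alpha)

    pops = sorted(samples["population"].unique())
    est = {p: allele_frequency(genotypes, list(samples.loc[samples["population"] == p, "sample_id"])) for p in pops}
    est_freqs = pd.DataFrame(est)
    est_freqs["chrom"] = genotypes.positions["chrom"]
    est_freqs["pos"] = genotypes.positions["pos"]

    gene_eqtls = eqtls[eqtls["gene_id"] == gene_id]
    candidates = discover_candidates(gene_eqtls, est_freqs, ctx, pop1, pop2, observed_sign, eqtl_p_max=eqtl_p_max)
    if validation_pop is not None and validation_pop in est_freqs.columns:
        candidates = validate_candidates(candidates, est_freqs, pop1, validation_pop, observed_sign)
    candidates = cluster_by_proximity(candidates)
    return dict(
        samples=samples,
        genotypes=genotypes,
        counts=counts,
        truth=truth,
        eqtls=eqtls,
        match=match,
        de=de,
        observed_sign=observed_sign,
        ctx=ctx,
        est_freqs=est_freqs,
        candidates=candidates,
    )


def run_pipeline(config: dict, outdir, seed: int) -> dict:
    """Execute the configured stages in dependency order and write a manifest.

    ``config['stages']`` selects the stages (default: all applicable). File
    outputs land under ``outdir``; the manifest records parameters, per-stage
    seeds and sha256 hashes of every file consumed or produced.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(_STAGE_ORDER))
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in _STAGE_ORDER if s in stages]
    manifest = dict(seed=seed, stages=stages, parameters=config, inputs={}, outputs={})

    paths = dict(config.get("paths", {}))

    def _out(name, default):
        p = Path(paths.get(name, outdir / default))
        return p

    if "simulate" in stages:
        sim_cfg = simulation_config_from_dict({**config.get("simulate", {}), "seed": stage_seed(seed, "simulate")})
        samples = simulate_cohort(sim_cfg)
        freqs = make_frequency_table(sim_cfg)
        genotypes = simulate_genotypes(samples, freqs, seed=stage_seed(seed, "genotypes"))
        counts, truth = simulate_counts(samples, genotypes, sim_cfg)
        eqtls = make_eqtl_table(sim_cfg, freqs)
        pio.write_metadata(samples, _out("metadata", "metadata.tsv"))
        pio.write_counts(counts, _out("counts", "counts.tsv"))
        pio.write_frequency_table(freqs, _out("freqs", "frequencies.tsv"))
        pio.write_vcf(genotypes, _out("vcf", "genotypes.vcf"))
        pio.write_eqtls(eqtls, _out("eqtls", "eqtls.tsv"))
        truth_rows = [dict(snp_id=p.snp_id, gene_id=p.gene_id, beta=p.beta, **{f"freq_{k}": v for k, v in p.freqs.items()}) for p in truth.planted]
        pd.DataFrame(truth_rows).to_csv(_out("truth", "ground_truth.tsv"), sep="\t", index=False)
        for key, default in [("metadata", "metadata.tsv"), ("counts", "counts.tsv"), ("freqs", "frequencies.tsv"), ("vcf", "genotypes.vcf"), ("eqtls", "eqtls.tsv"), ("truth", "ground_truth.tsv")]:
            paths.setdefault(key, str(_out(key, default)))

    meta = pio.read_metadata(paths["metadata"]) if "metadata" in paths else None

    match_res = None
    if "match" in stages:
        mc = config.get("match", {})
        spec = MatchSpec(
            exact_fields=tuple(mc.get("exact", ["stage"])),
            caliper_field=mc.get("caliper_field", "age"),
            caliper=mc.get("caliper", 10),
            max_ratio=mc.get("max_ratio", 8),
        )
        field = mc.get("group_field", "population")
        ga = meta[meta[field] == mc["group_a"]]
        gb = meta[meta[field] == mc["group_b"]]
        match_res = optimal_ratio_match(ga, gb, spec)
        pio.write_pairs(match_res.pairs, _out("pairs", "matched_pairs.tsv"))
        paths.setdefault("pairs", str(_out("pairs", "matched_pairs.tsv")))
        manifest["match"] = dict(n=match_res.n, m=match_res.m, ratio=match_res.ratio, objective=match_res.objective)

    de_res = None
    if "de" in stages:
        dc = config.get("de", {})
        counts = pio.read_counts(paths["counts"])
        expr = rpm_normalize(counts)
        matched_ids = None
        if "pairs" in paths:
            pairs = pio.read_pairs(paths["pairs"])
            matched_ids = {a for a, _ in pairs} | {b for _, b in pairs}
        comp = Comparison(reference=dc["reference"], test=dc["test"], stratum=dc.get("stratum", "All"))
        de_res = de_test(expr, meta, comp, matched_ids=matched_ids,
                         fc_threshold=dc.get("fc_threshold", 2.0), p_threshold=dc.get("p_threshold", 0.05))
        de_res.to_csv(_out("de", "de_results.tsv"), sep="\t", index=False)
        paths.setdefault("de", str(_out("de", "de_results.tsv")))

    if "enrich" in stages:
        ec = config.get("enrich", {})
        de_tab = de_res if de_res is not None else pd.read_csv(paths["de"], sep="\t")
        sig = significant_genes(de_tab)["gene_id"].tolist()
        gene_sets = pio.read_gmt(ec["gmt"])
        universe = ec.get("universe") or pd.read_csv(paths["counts"], sep="\t")["gene_id"].tolist()
        enr = enrich(sig, gene_sets, universe)
        enr.to_csv(_out("enrichment", "enrichment.tsv"), sep="\t", index=False)

    if "snp_assoc" in stages:
        sc = config.get("snp_assoc", {})
        eqtls = pio.read_eqtls(paths["eqtls"])
        freqs = pio.read_frequency_table(paths["freqs"])
        ctx = TTestContext(n1=sc["n1"], n2=sc["n2"], alpha=sc.get("alpha", 0.01), sidedness=sc.get("sidedness", "one-sided"))
        gene = sc["gene"]
        observed_sign = sc.get("observed_sign")
        if observed_sign is None and de_res is not None:
            row = de_res[de_res["gene_id"] == gene]
            observed_sign = 1 if float(row["log2fc"].iloc[0]) >= 0 else -1
        cands = discover_candidates(
            eqtls[eqtls["gene_id"] == gene], freqs, ctx, sc["pop1"], sc["pop2"], observed_sign,
            eqtl_p_max=sc.get("eqtl_p_max", 0.01),
        )
        if sc.get("validation_pop"):
            cands = validate_candidates(cands, freqs, sc["pop1"], sc["validation_pop"], sc.get("observed_sign_val", observed_sign))
        cands = cluster_by_proximity(cands, max_gap_bp=sc.get("max_gap_bp", 40_000))
        tab = candidates_to_frame(cands, gene_start=sc.get("gene_start"))
        tab.to_csv(_out("candidates", "candidates.tsv"), sep="\t", index=False)
        paths.setdefault("candidates", str(_out("candidates", "candidates.tsv")))
        manifest["n_candidates"] = len(cands)

    for key, p in paths.items():
        p = Path(p)
        if p.exists():
            manifest["outputs"][key] = dict(path=str(p), sha256=_sha256(p))
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
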