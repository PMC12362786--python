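"""End-to-end orchestration of the analysis stages.

Stages run in dependency order (simulate -> catalog -> ptv -> hotspot ->
prioritize -> concordance) under a single YAML/JSON config and one global
seed.  Per-stage seeds are derived from the global seed by stable hashing,
so rerunning a single stage reproduces its outputs.  Every run writes a
manifest recording the config hash, the derived seeds and the SHA-256 of
each output file; identical config + seed gives a byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .catalog import (VariantRecord, classify_consequence, conflict_report,
                      consensus_and_conflict, frequency_bin, summarize_catalog)
from .concordance import species_correlation
from .exceptions import InvalidConfigError
from .hotspot import HotspotScanConfig, kde_profile, scan_gene
from .prioritize import FeatureMatrix, PrioritizerConfig, fit_ensemble
from .ptv import gene_ptv_summary, is_ptv, nmd_escape_call, ptv_vs_cds_fit
from .simulate import (FeatureSimConfig, SimulationConfig,
                       gen_domain_annotations, gen_expression_pair,
                       gen_feature_matrix, gen_transcript_models,
                       gen_variant_catalog)

STAGES = ("simulate", "catalog", "ptv", "hotspot", "prioritize", "concordance")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    out_dir: str = "deafscape_run"
    seed: int = 0
    stages: tuple = STAGES
    # synthetic-data block (used when the simulate stage is enabled)
    simulate: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    expression: dict = field(default_factory=lambda: {"n_genes": 2000, "rho": 0.75})
    # external inputs (used when simulate is disabled)
    variants_path: Optional[str] = None
    transcripts_path: Optional[str] = None
    domains_path: Optional[str] = None
    features_path: Optional[str] = None
    expression_a_path: Optional[str] = None
    expression_b_path: Optional[str] = None
    # per-stage parameters
    nmd_window: int = 50
    alpha: float = 0.05
    n_boot: int = 2000
    correction: str = "bonferroni"
    k_subsets: int = 10
    smote_k: int = 5
    n_trees: int = 150
    benign_max_maf: float = 1e-4

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["stages"] = list(self.stages)
        return out

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def split_missense_strata(records: Sequence[VariantRecord],
                          benign_max_maf: float = 1e-4
                          ) -> tuple[list[int], list[int]]:
    """Pathogenic vs population missense aa positions for the hotspot scan.

    Pathogenic: consensus P/LP from any source; benign: missense not P/LP
    with maximum population MAF below ``benign_max_maf``.
    """
    path_pos, benign_pos = [], []
    for r in records:
        from .catalog import ConsequenceClass
        if r.consequence is not ConsequenceClass.MISSENSE or r.aa_pos is None:
            continue
        plp = (bool(r.source_labels)
               and consensus_and_conflict(r.source_labels).consensus == "P/LP")
        if plp:
            path_pos.append(r.aa_pos)
        else:
            maf = r.max_maf()
            if maf is not None and maf < benign_max_maf:
                benign_pos.append(r.aa_pos)
    return path_pos, benign_pos


def _validate(config: PipelineConfig) -> None:
    enabled = set(config.stages)
    unknown = enabled - set(STAGES)
    if unknown:
        raise InvalidConfigError(f"unknown stages: {sorted(unknown)}")
    simulated = "simulate" in enabled

    def _need(stage: str, attr: str, produced: bool) -> None:
        if stage not in enabled:
            return
        path = getattr(config, attr)
        if simulated and produced:
            return
        if path is None or not Path(path).exists():
            raise InvalidConfigError(
                f"stage '{stage}' needs {attr} (not simulated, not found)")

    _need("catalog", "variants_path", True)
    _need("catalog", "transcripts_path", True)
    _need("ptv", "variants_path", True)
    _need("ptv", "transcripts_path", True)
    _need("hotspot", "variants_path", True)
    _need("hotspot", "domains_path", True)
    _need("prioritize", "features_path", True)
    _need("concordance", "expression_a_path", True)
    _need("concordance", "expression_b_path", True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the manifest dict."""
    _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    files: dict[str, Path] = {}
    seeds = {stage: derive_seed(config.seed, stage) for stage in STAGES}

    transcripts = domains = records = features = None
    expr_a = expr_b = None

    if "simulate" in enabled:
        sim_cfg = SimulationConfig(**{**config.simulate,
                                      "seed": seeds["simulate"]})
        feat_cfg = FeatureSimConfig(**{**config.features,
                                       "seed": seeds["simulate"]})
        transcripts = gen_transcript_models(sim_cfg)
        domains = gen_domain_annotations(transcripts, sim_cfg)
        records = gen_variant_catalog(transcripts, domains, sim_cfg)
        features = gen_feature_matrix(feat_cfg)
        expr_a, expr_b = gen_expression_pair(
            int(config.expression.get("n_genes", 2000)),
            float(config.expression.get("rho", 0.75)),
            seed=seeds["simulate"])
        dio.write_transcripts_json(transcripts, out / "transcripts.json")
        dio.write_transcripts_gff3(transcripts, out / "transcripts.gff3")
        dio.write_domains_bed(domains, out / "domains.tsv")
        dio.write_variants_tsv(records, out / "variants.tsv")
        dio.write_vcf(records, out / "variants.vcf")
        dio.write_feature_matrix(features, out / "features.tsv")
        dio.write_expression_tsv(expr_a, out / "expression_a.tsv")
        dio.write_expression_tsv(expr_b, out / "expression_b.tsv")
        for name in ("transcripts.json", "transcripts.gff3", "domains.tsv",
                     "variants.tsv", "variants.vcf", "features.tsv",
                     "features.tsv.blocks", "expression_a.tsv",
                     "expression_b.tsv"):
            files[name] = out / name

    def _load_variants():
        return dio.read_variants_tsv(config.variants_path)

    def _load_transcripts():
        return dio.read_transcripts_json(config.transcripts_path)

    if "catalog" in enabled:
        recs = records if records is not None else _load_variants()
        txs = transcripts if transcripts is not None else _load_transcripts()
        tx_by_gene = {t.gene: t for t in txs}
        rows = []
        for r in recs:
            csq = classify_consequence(r, tx_by_gene[r.gene])
            cons = (consensus_and_conflict(r.source_labels)
                    if r.source_labels else None)
            rows.append({
                "gene": r.gene, "chrom": r.chrom, "pos": r.pos,
                "ref": r.ref, "alt": r.alt,
                "consequence": csq.value,
                "consensus": cons.consensus if cons else "unclassified",
                "conflict_class": cons.conflict_class.value if cons else "none",
                "frequency_bin": frequency_bin(
                    r.allele_count.get("gnomad", 0),
                    r.allele_frequency.get("gnomad", 0.0)).value,
            })
        pd.DataFrame(rows).to_csv(out / "catalog.tsv", sep="\t", index=False)
        conflict_report(recs).to_csv(out / "conflicts.tsv", sep="\t", index=False)
        summarize_catalog(recs).to_csv(out / "catalog_summary.tsv",
                                       sep="\t", index=False)
        files.update({n: out / n for n in ("catalog.tsv", "conflicts.tsv",
                                           "catalog_summary.tsv")})

    if "ptv" in enabled:
        recs = records if records is not None else _load_variants()
        txs = transcripts if transcripts is not None else _load_transcripts()
        tx_by_gene = {t.gene: t for t in txs}
        nmd_rows, gene_rows = [], []
        by_gene: dict[str, list[VariantRecord]] = {}
        for r in recs:
            by_gene.setdefault(r.gene, []).append(r)
        for gene, gene_recs in sorted(by_gene.items()):
            t = tx_by_gene[gene]
            for r in gene_recs:
                if r.consequence is None or not is_ptv(r.consequence):
                    continue
                call = nmd_escape_call(r, t, window=config.nmd_window)
                nmd_rows.append({"gene": gene, "pos": r.pos,
                                 "cds_pos": call.ptc_cds_pos,
                                 "escape": call.escape,
                                 "reason": call.reason.value})
            summary = gene_ptv_summary(gene_recs)
            gene_rows.append({
                "gene": gene, "n_ptv": summary.n_ptv, "n_plp": summary.n_plp,
                "n_plp_ptv": summary.n_plp_ptv,
                "plp_ratio_of_ptvs": summary.plp_ratio_of_ptvs,
                "ptv_ratio_of_plp": summary.ptv_ratio_of_plp,
                "quadrant": summary.quadrant.value,
                "cds_length": t.cds_length})
        pd.DataFrame(nmd_rows).to_csv(out / "nmd_calls.tsv", sep="\t", index=False)
        gene_df = pd.DataFrame(gene_rows)
        if len(gene_df) >= 3 and gene_df["cds_length"].nunique() > 1:
            fit = ptv_vs_cds_fit(gene_df["n_ptv"], gene_df["cds_length"],
                                 genes=list(gene_df["gene"]))
            gene_df["fit_residual"] = fit.residuals.to_numpy()
            gene_df.attrs["r_squared"] = fit.r_squared
        gene_df.to_csv(out / "gene_ptv_summary.tsv", sep="\t", index=False)
        files.update({n: out / n for n in ("nmd_calls.tsv",
                                           "gene_ptv_summary.tsv")})

    if "hotspot" in enabled:
        recs = records if records is not None else _load_variants()
        doms = domains if domains is not None else dio.read_domains_bed(
            config.domains_path)
        txs = transcripts if transcripts is not None else _load_transcripts()
        tx_by_gene = {t.gene: t for t in txs}
        dom_by_gene: dict[str, list] = {}
        for d in doms:
            dom_by_gene.setdefault(d.gene, []).append(d)
        scan_cfg = HotspotScanConfig(alpha=config.alpha, n_boot=config.n_boot,
                                     correction=config.correction)
        rng = np.random.default_rng(seeds["hotspot"])
        call_rows, track_rows = [], []
        by_gene = {}
        for r in recs:
            by_gene.setdefault(r.gene, []).append(r)
        for gene in sorted(by_gene):
            path_pos, benign_pos = split_missense_strata(
                by_gene[gene], config.benign_max_maf)
            gene_domains = dom_by_gene.get(gene, [])
            if not gene_domains or not path_pos or not benign_pos:
                continue
            L = tx_by_gene[gene].protein_length
            calls = scan_gene(path_pos, benign_pos, gene_domains, L,
                              gene=gene, config=scan_cfg, rng=rng)
            for c in calls:
                call_rows.append({
                    "gene": gene, "domain": c.domain_name,
                    "start_aa": c.region[0], "end_aa": c.region[1],
                    "dna_binding": c.is_dna_binding,
                    "plp_in": c.counts.plp_in, "plp_out": c.counts.plp_out,
                    "nonp_in": c.counts.nonp_in, "nonp_out": c.counts.nonp_out,
                    "lr_plus": c.lr_plus, "lr_lb": c.lr_lb, "lr_ub": c.lr_ub,
                    "odds_ratio": c.or_value, "fisher_p": c.fisher_p,
                    "adjusted_p": c.adjusted_p, "significant": c.significant,
                    "strength": c.strength.value})
            profile = kde_profile(path_pos, benign_pos, L, gene=gene)
            for i, aa in enumerate(profile.grid):
                track_rows.append({
                    "gene": gene, "aa": int(aa),
                    "density_pathogenic": profile.density_pathogenic[i],
                    "density_benign": profile.density_benign[i]})
        pd.DataFrame(call_rows).to_csv(out / "hotspot_calls.tsv",
                                       sep="\t", index=False)
        pd.DataFrame(track_rows).to_csv(out / "density_tracks.tsv",
                                        sep="\t", index=False)
        files.update({n: out / n for n in ("hotspot_calls.tsv",
                                           "density_tracks.tsv")})

    if "prioritize" in enabled:
        feats = features if features is not None else dio.read_feature_matrix(
            config.features_path)
        prio_cfg = PrioritizerConfig(k_subsets=config.k_subsets,
                                     smote_k=config.smote_k,
                                     n_trees=config.n_trees)
        result = fit_ensemble(feats, config=prio_cfg, seed=seeds["prioritize"])
        pd.DataFrame([{"gene": s.gene, "votes": s.votes,
                       "predictions": ",".join(s.per_model_prediction)}
                      for s in result.scores]).to_csv(
            out / "scores.tsv", sep="\t", index=False)
        result.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
        result.importance.to_csv(out / "importance.tsv", sep="\t", index=False)
        files.update({n: out / n for n in ("scores.tsv", "metrics.tsv",
                                           "importance.tsv")})

    if "concordance" in enabled:
        a = expr_a if expr_a is not None else dio.read_expression_tsv(
            config.expression_a_path)
        b = expr_b if expr_b is not None else dio.read_expression_tsv(
            config.expression_b_path)
        comp = species_correlation(a, b)
        summary = pd.DataFrame([{
            "species_a": comp.species_a, "species_b": comp.species_b,
            "n_shared": len(comp.shared_genes), "r_all": comp.r_all,
            "r_subset": comp.r_subset}])
        summary.to_csv(out / "concordance.tsv", sep="\t", index=False)
        comp.relative_difference.rename_axis("gene").to_frame().to_csv(
            out / "relative_difference.tsv", sep="\t")
        files.update({n: out / n for n in ("concordance.tsv",
                                           "relative_difference.tsv")})

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: seeds[s] for s in STAGES if s in enabled},
        "outputs": {name: hashlib.sha256(path.read_bytes()).hexdigest()
                    for name, path in sorted(files.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
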