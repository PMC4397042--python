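"""End-to-end orchestration: QC -> residualization -> network ->
eQTL scan -> eigengene scan -> hotspot/candidate integration.

:func:`analyze` is the in-memory pipeline over aligned tables;
:func:`run_pipeline` is the file-based wrapper that loads (or
simulates) inputs, writes every stage's TSV outputs and a JSON run
manifest with content hashes.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .errors import ConfigError, ModqtlError
from .eqtl import ScanConfig, scan_eqtl, summarize_counts
from .integrate import (
    IntegrationConfig,
    candidate_regulators,
    detect_hotspots,
    eigengene_qtl_scan,
    window_counts,
)
from .network import (
    NetworkConfig,
    adjacency,
    build_module_set,
    connectivity_table,
    detect_modules,
    merge_modules,
    module_trait_correlation,
    rank_hubs,
    residualize_expression,
    tom_similarity,
)
from .qc import QcConfig, apply_qc
from .simulate import SimConfig, config_from_dict, simulate_dataset, write_truth


class PipelineStageError(ModqtlError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "modqtl_out"
    simulate: SimConfig | None = None
    genotype_path: str | None = None
    snp_map_path: str | None = None
    expression_path: str | None = None
    probe_map_path: str | None = None
    covariates_path: str | None = None
    phenotypes_path: str | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulate is None:
            required = [
                self.genotype_path, self.snp_map_path,
                self.expression_path, self.probe_map_path,
                self.covariates_path,
            ]
            if any(p is None for p in required):
                raise ConfigError(
                    "either a 'simulate' section or paths to genotype, SNP map,"
                    " expression, probe map and covariate tables are required"
                )
            for p in required + [self.phenotypes_path]:
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"input file does not exist: {p}")
        self.qc.validate()
        self.network.validate()
        self.scan.validate()
        self.integration.validate()


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "simulate" in kwargs and kwargs["simulate"] is not None:
        kwargs["simulate"] = config_from_dict(kwargs["simulate"])
    for key, cls in (
        ("qc", QcConfig), ("network", NetworkConfig),
        ("scan", ScanConfig), ("integration", IntegrationConfig),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = kwargs[key]
            if key == "scan" and "p_thresholds" in sub:
                sub["p_thresholds"] = tuple(sub["p_thresholds"])
            kwargs[key] = cls(**sub)
    return PipelineConfig(**kwargs)


@dataclass
class AnalysisResult:
    genotypes: pd.DataFrame
    qc_report: pd.DataFrame
    residual_expression: pd.DataFrame
    module_set: object
    connectivity: pd.DataFrame
    hub_ranking: pd.DataFrame
    module_trait: pd.DataFrame
    eqtl_records: pd.DataFrame
    eqtl_counts: pd.DataFrame
    eqtl_drops: pd.DataFrame
    eigengene_qtl: pd.DataFrame
    hotspots: pd.DataFrame
    candidates: pd.DataFrame


def analyze(geno: pd.DataFrame, snp_map: pd.DataFrame, expr: pd.DataFrame,
            probe_map: pd.DataFrame, cov: pd.DataFrame,
            pheno: pd.DataFrame | None = None,
            qc_config: QcConfig | None = None,
            net_config: NetworkConfig | None = None,
            scan_config: ScanConfig | None = None,
            int_config: IntegrationConfig | None = None) -> AnalysisResult:
    """Run the full analysis chain on aligned in-memory tables."""
    qc_config = qc_config or QcConfig()
    net_config = net_config or NetworkConfig()
    scan_config = scan_config or ScanConfig()
    int_config = int_config or IntegrationConfig()

    qc_res = apply_qc(geno, qc_config)
    samples = qc_res.genotypes.index
    expr = expr.loc[samples]
    cov = cov.loc[samples]
    pheno = pheno.loc[samples] if pheno is not None else None

    resid = residualize_expression(expr, cov)
    adj = adjacency(resid, net_config.beta)
    tom = tom_similarity(adj)
    assignment = detect_modules(tom, net_config)
    module_set = build_module_set(resid, assignment)
    if module_set.eigengenes.shape[1] > 1:
        module_set = merge_modules(
            resid, module_set, net_config.merge_dissim_threshold
        )

    conn = connectivity_table(resid, adj, module_set, probe_map)
    hub_rows = []
    for m in module_set.modules():
        ranked = rank_hubs(conn[conn["module"] == m])
        hub_rows.append(ranked)
    hubs = (
        pd.concat(hub_rows, ignore_index=True)
        if hub_rows
        else pd.DataFrame(columns=["probe", "gene", "module", "mm", "k", "rank"])
    )

    trait_rows = []
    if pheno is not None:
        for m in module_set.modules():
            for trait in pheno.columns:
                r, p = module_trait_correlation(
                    module_set.eigengenes[m], pheno[trait]
                )
                trait_rows.append({"module": m, "trait": trait, "r": r, "p": p})
    module_trait = pd.DataFrame(trait_rows, columns=["module", "trait", "r", "p"])

    records = scan_eqtl(resid, qc_res.genotypes, cov, snp_map, probe_map,
                        scan_config)
    counts, drops = summarize_counts(records, scan_config.p_thresholds)

    eig_rows, hot_rows, cand_rows = [], [], []
    for m in module_set.modules():
        me = module_set.eigengenes[m]
        eig = eigengene_qtl_scan(me, qc_res.genotypes, cov, snp_map, int_config,
                                 scan_config)
        eig.insert(0, "module", m)
        eig_rows.append(eig)

        member_probes = set(module_set.probes_in(m))
        member_records = records[
            records["probe"].isin(member_probes)
            & (records["cis_trans"] == "trans")
        ]
        wc = window_counts(member_records, snp_map, int_config.window_bp)
        hot = detect_hotspots(wc, eig.drop(columns="module"), int_config)
        hot.insert(0, "module", m)
        hot_rows.append(hot)
        for _, region in hot.iterrows():
            cand = candidate_regulators(region, probe_map, resid, me, int_config)
            cand.insert(0, "module", m)
            cand_rows.append(cand)

    empty_eig = pd.DataFrame(
        columns=["module", "snp", "chrom", "pos", "p", "variance_explained"]
    )
    empty_hot = pd.DataFrame(columns=mio.SCHEMAS["hotspots"])
    empty_cand = pd.DataFrame(columns=mio.SCHEMAS["candidates"])
    return AnalysisResult(
        genotypes=qc_res.genotypes,
        qc_report=qc_res.report,
        residual_expression=resid,
        module_set=module_set,
        connectivity=conn,
        hub_ranking=hubs,
        module_trait=module_trait,
        eqtl_records=records,
        eqtl_counts=counts,
        eqtl_drops=drops,
        eigengene_qtl=(
            pd.concat(eig_rows, ignore_index=True) if eig_rows else empty_eig
        ),
        hotspots=pd.concat(hot_rows, ignore_index=True) if hot_rows else empty_hot,
        candidates=(
            pd.concat(cand_rows, ignore_index=True) if cand_rows else empty_cand
        ),
    )


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # analysis identity is independent of output path
    blob = json.dumps(d, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write all outputs under ``config.out_dir``
    and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "modqtl",
        "version": __version__,
        "config_hash": _config_hash(config),
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {},
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, paths: list[Path]) -> None:
        rel = [str(p.relative_to(out)) for p in paths]
        manifest["stages"][stage] = sorted(rel)
        for p, r in zip(paths, rel):
            manifest["outputs"][r] = mio.sha256_of(p)

    try:
        if config.simulate is not None:
            sim_cfg = config.simulate
            if config.seed is not None:
                sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
            geno_sim, esim, pheno = simulate_dataset(sim_cfg)
            geno, snp_map = geno_sim
            expr, probe_map, cov, truth = esim
            paths = [
                mio.write_matrix(geno, out / "genotypes.tsv"),
                mio.write_table(snp_map, out / "snp_map.tsv", "snp_map"),
                mio.write_matrix(expr, out / "expression.tsv"),
                mio.write_table(probe_map, out / "probe_map.tsv", "probe_map"),
                mio.write_table(cov.reset_index(), out / "covariates.tsv",
                                "covariates"),
                mio.write_matrix(pheno, out / "phenotypes.tsv"),
            ]
            write_truth(truth, out / "truth")
            paths += sorted((out / "truth").glob("*"))
            record("simulate", paths)
        else:
            geno = mio.read_matrix(config.genotype_path)
            snp_map = mio.read_table(config.snp_map_path, "snp_map")
            snp_map["mapped"] = snp_map["mapped"].astype(str).str.lower().isin(
                ["true", "1"]
            )
            expr = mio.read_matrix(config.expression_path)
            probe_map = mio.read_table(config.probe_map_path, "probe_map")
            probe_map["mapped"] = probe_map["mapped"].astype(str).str.lower().isin(
                ["true", "1"]
            )
            cov = mio.read_table(config.covariates_path, "covariates").set_index(
                "sample"
            )
            pheno = (
                mio.read_matrix(config.phenotypes_path)
                if config.phenotypes_path else None
            )
            for p in [config.genotype_path, config.snp_map_path,
                      config.expression_path, config.probe_map_path,
                      config.covariates_path, config.phenotypes_path]:
                if p:
                    manifest["inputs"][str(p)] = mio.sha256_of(p)
    except ModqtlError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("load", exc) from exc

    stage = "analyze"
    try:
        result = analyze(
            geno, snp_map, expr, probe_map, cov, pheno,
            config.qc, config.network, config.scan, config.integration,
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    try:
        assignment = result.module_set.assignment.rename("module").reset_index()
        assignment.columns = ["probe", "module"]
        hubs = result.hub_ranking.copy()
        record("qc", [
            mio.write_matrix(result.genotypes, out / "genotypes_qc.tsv"),
            mio.write_table(result.qc_report, out / "qc_report.tsv", "qc_report"),
        ])
        record("network", [
            mio.write_matrix(result.residual_expression,
                             out / "residual_expression.tsv"),
            mio.write_table(assignment, out / "module_assignment.tsv",
                            "assignment"),
            mio.write_matrix(result.module_set.eigengenes,
                             out / "eigengenes.tsv"),
            mio.write_table(hubs, out / "connectivity.tsv", "connectivity"),
            mio.write_table(result.module_trait, out / "module_trait.tsv",
                            "module_trait"),
        ])
        record("eqtl", [
            mio.write_table(result.eqtl_records, out / "eqtl.tsv", "eqtl"),
            mio.write_table(result.eqtl_counts, out / "eqtl_summary.tsv",
                            "eqtl_summary"),
            mio.write_table(result.eqtl_drops, out / "eqtl_drops.tsv",
                            "eqtl_drops"),
        ])
        record("integrate", [
            mio.write_table(result.eigengene_qtl, out / "eigengene_qtl.tsv",
                            "eigengene_qtl"),
            mio.write_table(result.hotspots, out / "hotspots.tsv", "hotspots"),
            mio.write_table(result.candidates, out / "candidates.tsv",
                            "candidates"),
        ])
    except Exception as exc:
        raise PipelineStageError("write", exc) from exc

    mio.write_json(manifest, out / "manifest.json")
    return manifest
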