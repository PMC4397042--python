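"""Synthetic genotype/expression/phenotype generator with a planted
genotype -> regulator -> module causal chain.

The generator emulates the statistical structure of a pig muscle eQTL
study: ~200 samples, biallelic SNPs with MAF >= 0.05 in Hardy-Weinberg
proportions (no LD by default), log2-scale expression with sex, sire,
RYR1-like, carcass-weight and slaughter-batch effects, one or more
co-expression modules driven by a cis-regulated regulator transcript,
and phenotypes correlated with the module mean.

RNG discipline: every operation derives its own stream from
``SeedSequence([config.seed, stage])`` (stage 0 = genotypes, 1 =
expression, 2 = phenotypes) and performs its draws in a fixed,
documented order so that re-draw oracles can reproduce them exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io as mio
from .errors import ConfigError
from .genome import interval_distance

GENE_LENGTH_BP = 2_000  # nominal transcript footprint used for all genes
_REGULATOR_OFFSET_BP = 200_000  # regulator gene start relative to cis SNP


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    The regulator transcript sits within 1 Mb of its cis SNP (the gene is
    placed ``_REGULATOR_OFFSET_BP`` downstream of the resolved SNP, so the
    cis relationship holds by construction).  ``module_size`` counts the
    regulator itself plus its target genes; targets are scattered across
    chromosomes away from any cis SNP so their planted eQTL act in trans.
    """

    name: str = "M1"
    module_size: int = 30
    regulator_chrom: str = "1"
    regulator_bp: int = 50_000_000
    regulator_cis_snp: str | None = None  # None: nearest SNP to regulator_bp
    regulator_cis_maf: float | None = 0.30  # pin the drawn MAF of the cis SNP
    cis_effect_b: float = 1.2  # expression units per minor allele
    loading_range: tuple[float, float] = (0.6, 1.0)
    trait_correlation_target: float = 0.32

    def validate(self) -> None:
        if self.module_size < 2:
            raise ConfigError("module_size must be >= 2")
        if not abs(self.trait_correlation_target) < 1:
            raise ConfigError("|trait_correlation_target| must be < 1")
        lo, hi = self.loading_range
        if not lo <= hi:
            raise ConfigError("loading_range must be ordered")
        if self.regulator_cis_maf is not None and not (
            0 < self.regulator_cis_maf <= 0.5
        ):
            raise ConfigError("regulator_cis_maf must lie in (0, 0.5]")


@dataclass
class CovariateSpec:
    """Covariate/batch layout plus effect-size SDs.

    The source study corrects for these effects without reporting their
    magnitudes; the SDs below are calibration choices producing a total
    covariate variance share of roughly 10-15% of a transcript's variance.
    """

    n_sires: int = 10
    sex_fraction: float = 0.5
    batch_count: int = 5
    weight_mean: float = 95.0
    weight_sd: float = 10.0
    ryr1_freqs: tuple[float, float, float] = (0.49, 0.42, 0.09)
    sex_effect_sd: float = 0.2
    sire_effect_sd: float = 0.2
    ryr1_effect_sd: float = 0.2
    batch_effect_sd: float = 0.3
    weight_slope_sd: float = 0.01


@dataclass
class SimConfig:
    n_samples: int = 200
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    n_snps: int = 2_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    unmapped_snp_fraction: float = 0.02
    n_background_genes: int = 300
    unmapped_gene_fraction: float = 0.05
    module_specs: list[ModuleSpec] = field(default_factory=lambda: [ModuleSpec()])
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    baseline_mean: float = 8.0  # log2-scale intercept of every transcript
    baseline_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        for name in (
            "n_samples", "n_chromosomes", "chrom_length_bp", "n_snps",
            "n_background_genes",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        for spec in self.module_specs:
            spec.validate()
        names = [s.name for s in self.module_specs]
        if len(set(names)) != len(names):
            raise ConfigError("module names must be unique")


@dataclass
class TruthTable:
    """Ground truth emitted alongside each simulated dataset."""

    genes: pd.DataFrame    # probe, gene, chrom, start_bp, end_bp, module, loading
    eqtl: pd.DataFrame     # snp, probe, gene, effect, cis_trans
    modules: pd.DataFrame  # module, regulator_probe/gene, cis_snp, chrom, pos
    traits: pd.DataFrame   # trait, module, coef, noise_sd, target_r

    def module_probes(self, module: str) -> list[str]:
        sel = self.genes["module"] == module
        return self.genes.loc[sel, "probe"].tolist()


class GenotypeSim(NamedTuple):
    dosage: pd.DataFrame  # samples x SNPs, float with NaN for missing
    snp_map: pd.DataFrame


class ExpressionSim(NamedTuple):
    expression: pd.DataFrame  # samples x probes
    probe_map: pd.DataFrame
    covariates: pd.DataFrame
    truth: TruthTable


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def _draw_positions(rng: np.random.Generator, length: int, m: int) -> np.ndarray:
    """m distinct, sorted 1-based positions on a chromosome of given length."""
    pos = np.unique(rng.integers(1, length + 1, size=m))
    while pos.size < m:
        pos = np.unique(
            np.concatenate([pos, rng.integers(1, length + 1, size=m)])
        )
    if pos.size > m:
        pos = np.sort(rng.choice(pos, size=m, replace=False))
    return pos


def resolve_cis_snp(spec: ModuleSpec, snp_map: pd.DataFrame) -> str:
    """SNP id of the module's cis SNP.

    An explicit id must exist and lie within 1 Mb of the regulator target
    position; otherwise the mapped SNP nearest to ``regulator_bp`` on the
    regulator chromosome is chosen.
    """
    mapped = snp_map[snp_map["mapped"] & (snp_map["chrom"] == spec.regulator_chrom)]
    if spec.regulator_cis_snp is not None:
        row = snp_map[snp_map["snp"] == spec.regulator_cis_snp]
        if row.empty:
            raise ConfigError(
                f"module {spec.name}: cis SNP {spec.regulator_cis_snp} not found"
            )
        row = row.iloc[0]
        if (not row["mapped"]) or row["chrom"] != spec.regulator_chrom or abs(
            row["pos_bp"] - spec.regulator_bp
        ) >= 1_000_000:
            raise ConfigError(
                f"module {spec.name}: cis SNP must map within 1 Mb of the regulator"
            )
        return spec.regulator_cis_snp
    if mapped.empty:
        raise ConfigError(
            f"module {spec.name}: no mapped SNP on chromosome {spec.regulator_chrom}"
        )
    dist = (mapped["pos_bp"] - spec.regulator_bp).abs()
    return mapped.loc[dist.idxmin(), "snp"]


def simulate_genotypes(config: SimConfig) -> GenotypeSim:
    """Draw the genotype matrix and its SNP map.

    Draw order on stream 0 (one ``default_rng`` per run):
      1. per chromosome, in order: SNP positions (:func:`_draw_positions`);
      2. one uniform MAF per SNP over ``maf_range`` (then deterministic
         overrides for pinned cis-SNP MAFs);
      3. the full dosage matrix in one ``binomial(2, maf)`` call of shape
         (n_samples, n_snps);
      4. one uniform (n_samples, n_snps) block for the missing mask
         (drawn whenever ``missing_rate > 0``);
      5. one uniform n_snps block for the unmapped-SNP mask (drawn
         whenever ``unmapped_snp_fraction > 0``; cis SNPs stay mapped).
    """
    config.validate()
    rng = _rng(config.seed, 0)
    n, s = config.n_samples, config.n_snps
    base, rem = divmod(s, config.n_chromosomes)
    counts = [base + (1 if c < rem else 0) for c in range(config.n_chromosomes)]
    chroms, positions = [], []
    for c, m in enumerate(counts, start=1):
        pos = _draw_positions(rng, config.chrom_length_bp, m)
        chroms.extend([str(c)] * m)
        positions.extend(pos.tolist())
    snp_ids = [f"snp{i:05d}" for i in range(s)]
    snp_map = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": chroms,
            "pos_bp": np.asarray(positions, dtype=float),
            "mapped": True,
        }
    )

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=s)
    cis_ids = []
    for spec in config.module_specs:
        cis = resolve_cis_snp(spec, snp_map)
        cis_ids.append(cis)
        if spec.regulator_cis_maf is not None:
            mafs[snp_ids.index(cis)] = spec.regulator_cis_maf

    dosage = rng.binomial(2, mafs, size=(n, s)).astype(float)
    if config.missing_rate > 0:
        miss = rng.random((n, s)) < config.missing_rate
        dosage[miss] = np.nan
    if config.unmapped_snp_fraction > 0:
        unmapped = rng.random(s) < config.unmapped_snp_fraction
        unmapped[[snp_ids.index(c) for c in cis_ids]] = False
        snp_map.loc[unmapped, ["chrom", "pos_bp"]] = [np.nan, np.nan]
        snp_map.loc[unmapped, "mapped"] = False

    sample_ids = [f"S{i:04d}" for i in range(n)]
    geno = pd.DataFrame(dosage, index=sample_ids, columns=snp_ids)
    geno.index.name = "sample"
    return GenotypeSim(geno, snp_map)


def _covariate_table(rng: np.random.Generator, config: SimConfig,
                     sample_ids: list[str]) -> pd.DataFrame:
    cs = config.covariates
    n = config.n_samples
    sex = np.where(rng.random(n) < cs.sex_fraction, "F", "M")
    sire = np.array([f"sire{k:02d}" for k in rng.integers(0, cs.n_sires, n)])
    ryr1 = np.array(["NN", "Nn", "nn"])[
        rng.choice(3, size=n, p=np.asarray(cs.ryr1_freqs) / sum(cs.ryr1_freqs))
    ]
    weight = rng.normal(cs.weight_mean, cs.weight_sd, n)
    batch = np.array([f"day{k:02d}" for k in rng.integers(0, cs.batch_count, n)])
    return pd.DataFrame(
        {"sex": sex, "sire": sire, "ryr1": ryr1, "weight": weight, "batch": batch},
        index=pd.Index(sample_ids, name="sample"),
    )


def _covariate_contributions(rng: np.random.Generator, cov: pd.DataFrame,
                             config: SimConfig, n_genes: int) -> np.ndarray:
    """(n_samples, n_genes) matrix of summed covariate/batch effects.

    Per gene, each categorical covariate gets zero-centred normal level
    effects and carcass weight a normal slope.  Draw order: sex, sire,
    RYR1, batch, weight.
    """
    cs = config.covariates
    n = len(cov)
    contrib = np.zeros((n, n_genes))
    for col, sd in (("sex", cs.sex_effect_sd), ("sire", cs.sire_effect_sd),
                    ("ryr1", cs.ryr1_effect_sd), ("batch", cs.batch_effect_sd)):
        levels, idx = np.unique(cov[col].to_numpy(), return_inverse=True)
        eff = rng.normal(0.0, sd, size=(n_genes, len(levels)))
        contrib += eff[:, idx].T
    slope = rng.normal(0.0, cs.weight_slope_sd, size=n_genes)
    contrib += np.outer(cov["weight"].to_numpy() - cs.weight_mean, slope)
    return contrib


def _place_gene(rng: np.random.Generator, config: SimConfig,
                excluded: list[tuple[str, float]]) -> tuple[str, int]:
    """Uniform gene placement avoiding +/-2 Mb around planted cis SNPs."""
    while True:
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        start = int(rng.integers(1, config.chrom_length_bp - GENE_LENGTH_BP))
        if all(
            c != chrom or interval_distance(p, start, start + GENE_LENGTH_BP) > 2_000_000
            for c, p in excluded
        ):
            return chrom, start


def simulate_expression(geno: GenotypeSim, config: SimConfig) -> ExpressionSim:
    """Generate expression, probe map, covariates and ground truth.

    Per module the regulator transcript is
    ``x_r = mu_r + b * G_cis + covariate effects + N(0, noise_sd^2)`` and
    each target ``x_j = mu_j + w_j * x_r + covariate effects +
    N(0, noise_sd^2)`` with loadings ``w_j ~ U(loading_range)``.
    Background genes are baseline + covariates + noise.  Missing cis-SNP
    dosages are mean-imputed for generation only.

    Draw order on stream 1: covariate table; per-gene baselines; covariate
    effect matrices; then per module (spec order): loadings, target gene
    placements, regulator noise, target noise; then background placements,
    background noise, and the unmapped-gene mask.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    dosage, snp_map = geno.dosage, geno.snp_map
    n = config.n_samples
    if len(dosage) != n:
        raise ConfigError("genotype matrix does not match config.n_samples")
    sample_ids = list(dosage.index)

    cov = _covariate_table(rng, config, sample_ids)

    module_sizes = [spec.module_size for spec in config.module_specs]
    n_genes = sum(module_sizes) + config.n_background_genes
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)
    contrib = _covariate_contributions(rng, cov, config, n_genes)

    cis_ids = [resolve_cis_snp(spec, snp_map) for spec in config.module_specs]
    excluded = [
        (snp_map.set_index("snp").loc[c, "chrom"],
         float(snp_map.set_index("snp").loc[c, "pos_bp"]))
        for c in cis_ids
    ]

    values = np.empty((n, n_genes))
    probe, gene, gchrom, gstart, gend, module_lbl, loading = [], [], [], [], [], [], []
    truth_eqtl_rows = []
    truth_module_rows = []
    col = 0

    def add_gene(sym, chrom, start, mod, w):
        probe.append(f"probe_{len(probe):04d}")
        gene.append(sym)
        gchrom.append(chrom)
        gstart.append(float(start) if start is not None else np.nan)
        gend.append(float(start + GENE_LENGTH_BP) if start is not None else np.nan)
        module_lbl.append(mod)
        loading.append(w)

    for spec, cis in zip(config.module_specs, cis_ids):
        smap = snp_map.set_index("snp")
        cis_chrom = smap.loc[cis, "chrom"]
        cis_pos = float(smap.loc[cis, "pos_bp"])
        g = dosage[cis].to_numpy(dtype=float)
        if np.all(np.isnan(g)):
            raise ConfigError(f"module {spec.name}: cis SNP {cis} has no calls")
        g = np.where(np.isnan(g), np.nanmean(g), g)

        w = rng.uniform(spec.loading_range[0], spec.loading_range[1],
                        size=spec.module_size - 1)
        placements = [
            _place_gene(rng, config, excluded)
            for _ in range(spec.module_size - 1)
        ]
        reg_start = min(
            int(cis_pos) + _REGULATOR_OFFSET_BP,
            config.chrom_length_bp - GENE_LENGTH_BP,
        )
        x_reg = (
            baselines[col] + spec.cis_effect_b * g + contrib[:, col]
            + rng.normal(0.0, config.noise_sd, n)
        )
        add_gene(f"{spec.name}_REG", cis_chrom, reg_start, spec.name, 1.0)
        reg_probe = probe[-1]
        values[:, col] = x_reg
        truth_eqtl_rows.append((cis, reg_probe, gene[-1], spec.cis_effect_b))
        col += 1
        for j in range(spec.module_size - 1):
            chrom, start = placements[j]
            x = (
                baselines[col] + w[j] * x_reg + contrib[:, col]
                + rng.normal(0.0, config.noise_sd, n)
            )
            add_gene(f"{spec.name}_T{j:02d}", chrom, start, spec.name, float(w[j]))
            values[:, col] = x
            truth_eqtl_rows.append(
                (cis, probe[-1], gene[-1], float(w[j] * spec.cis_effect_b))
            )
            col += 1
        truth_module_rows.append(
            (spec.name, reg_probe, f"{spec.name}_REG", cis, cis_chrom, cis_pos)
        )

    bg_placements = [
        _place_gene(rng, config, []) for _ in range(config.n_background_genes)
    ]
    for j in range(config.n_background_genes):
        chrom, start = bg_placements[j]
        values[:, col] = (
            baselines[col] + contrib[:, col] + rng.normal(0.0, config.noise_sd, n)
        )
        add_gene(f"BG{j:04d}", chrom, start, "background", 0.0)
        col += 1

    probe_map = pd.DataFrame(
        {
            "probe": probe, "gene": gene, "chrom": gchrom,
            "start_bp": gstart, "end_bp": gend, "mapped": True,
        }
    )
    if config.unmapped_gene_fraction > 0:
        unmap = rng.random(n_genes) < config.unmapped_gene_fraction
        unmap[np.asarray(module_lbl) != "background"] = False
        probe_map.loc[unmap, ["chrom", "start_bp", "end_bp"]] = [np.nan, np.nan, np.nan]
        probe_map.loc[unmap, "mapped"] = False

    expr = pd.DataFrame(values, index=sample_ids, columns=probe)
    expr.index.name = "sample"

    truth_genes = pd.DataFrame(
        {
            "probe": probe, "gene": gene,
            "chrom": probe_map["chrom"].to_numpy(),
            "start_bp": probe_map["start_bp"].to_numpy(),
            "end_bp": probe_map["end_bp"].to_numpy(),
            "module": module_lbl, "loading": loading,
        }
    )
    eqtl = pd.DataFrame(
        truth_eqtl_rows, columns=["snp", "probe", "gene", "effect"]
    )
    smap = snp_map.set_index("snp")
    gmap = truth_genes.set_index("probe")
    classes = []
    for _, row in eqtl.iterrows():
        spos = float(smap.loc[row["snp"], "pos_bp"])
        schrom = smap.loc[row["snp"], "chrom"]
        grow = gmap.loc[row["probe"]]
        if pd.isna(grow["chrom"]) or pd.isna(schrom):
            classes.append("unmapped")
        elif grow["chrom"] == schrom and interval_distance(
            spos, grow["start_bp"], grow["end_bp"]
        ) < 1_000_000:
            classes.append("cis")
        else:
            classes.append("trans")
    eqtl["cis_trans"] = classes
    modules = pd.DataFrame(
        truth_module_rows,
        columns=["module", "regulator_probe", "regulator_gene",
                 "cis_snp", "chrom", "cis_snp_pos"],
    )
    traits = pd.DataFrame(
        {
            "trait": [f"trait_{s.name}" for s in config.module_specs],
            "module": [s.name for s in config.module_specs],
            "coef": np.nan, "noise_sd": np.nan,
            "target_r": [s.trait_correlation_target for s in config.module_specs],
        }
    )
    truth = TruthTable(truth_genes, eqtl, modules, traits)
    return ExpressionSim(expr, probe_map, cov, truth)


def simulate_phenotypes(expr: pd.DataFrame, truth: TruthTable,
                        config: SimConfig) -> pd.DataFrame:
    """One trait per planted module plus a pure-noise trait.

    Each module trait is ``sign(r) * module-mean expression + N(0, sigma^2)``
    with sigma chosen from the realized module-mean SD so the expected
    trait-eigengene correlation equals ``trait_correlation_target``.
    Draw order on stream 2: per module (spec order) the trait noise, then
    the noise trait.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    out = {}
    coefs, sigmas = [], []
    for spec in config.module_specs:
        probes = truth.module_probes(spec.name)
        if not probes:
            raise ConfigError(f"unknown module id {spec.name!r} in truth table")
        m = expr[probes].mean(axis=1).to_numpy()
        target = spec.trait_correlation_target
        sd_m = float(np.std(m, ddof=1))
        if target == 0:
            c, sigma = 0.0, 1.0
        else:
            c = float(np.sign(target))
            sigma = sd_m * float(np.sqrt(1.0 / target**2 - 1.0))
        out[f"trait_{spec.name}"] = c * m + rng.normal(0.0, sigma, len(m))
        coefs.append(c)
        sigmas.append(sigma)
    out["trait_noise"] = rng.normal(0.0, 1.0, len(expr))
    truth.traits["coef"] = coefs
    truth.traits["noise_sd"] = sigmas
    pheno = pd.DataFrame(out, index=expr.index)
    pheno.index.name = "sample"
    return pheno


_TRUTH_FILES = {
    "genes": "truth_genes",
    "eqtl": "truth_eqtl",
    "modules": "truth_modules",
    "traits": "truth_traits",
}


def write_truth(truth: TruthTable, path) -> dict:
    """Write the truth bundle as TSVs plus a JSON manifest of file hashes."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"files": {}}
    for attr, schema in _TRUTH_FILES.items():
        fp = mio.write_table(getattr(truth, attr), path / f"{attr}.tsv", schema)
        manifest["files"][f"{attr}.tsv"] = mio.sha256_of(fp)
    mio.write_json(manifest, path / "manifest.json")
    return manifest


def read_truth(path) -> TruthTable:
    path = Path(path)
    parts = {
        attr: mio.read_table(path / f"{attr}.tsv", schema)
        for attr, schema in _TRUTH_FILES.items()
    }
    return TruthTable(parts["genes"], parts["eqtl"], parts["modules"],
                      parts["traits"])


def simulate_dataset(config: SimConfig):
    """Convenience wrapper running all three simulation stages."""
    geno = simulate_genotypes(config)
    esim = simulate_expression(geno, config)
    pheno = simulate_phenotypes(esim.expression, esim.truth, config)
    return geno, esim, pheno


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "module_specs" in d:
        d["module_specs"] = [
            ModuleSpec(**m) if isinstance(m, dict) else m
            for m in d["module_specs"]
        ]
    if isinstance(d.get("covariates"), dict):
        d["covariates"] = CovariateSpec(**d["covariates"])
    for key in ("maf_range", "loading_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    for spec in d.get("module_specs", []):
        if isinstance(spec.loading_range, list):
            spec.loading_range = tuple(spec.loading_range)
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg
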