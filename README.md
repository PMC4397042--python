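# modqtl

Finding **common regulators of trait-associated co-expression modules** by
integrating genome-wide genotypes with transcriptome profiles.

In systems-genetics studies of muscle (and other tissues), groups of
co-expressed genes — *modules* — correlate with organismal phenotypes such as
meat-quality traits. If the coordinated expression of a module is under
genetic control, the genomic location of that control can be found by mapping
expression QTL (eQTL) for the module's member genes and for its *eigengene*
(the first principal component of the module's standardized expression).
Genomic windows where many member-gene *trans*-eQTL pile up **and** the
eigengene itself shows a QTL are *hotspots*: they likely harbor a common
regulator. Transcripts encoded inside a hotspot that correlate with the
eigengene are the regulator candidates.

`modqtl` implements this full chain as a tested, reusable pipeline:

1. **Genotype QC** — sample call rate < 95% and SNP MAF < 5% filters
   (both strict; no Hardy–Weinberg filter, which is inappropriate for
   crossbred populations).
2. **Co-expression network** on covariate-residualized expression —
   unsigned adjacency `a_iu = |cor(x_i, x_u)|^β` (default β = 6),
   topological-overlap similarity (TOM), average-linkage clustering of
   `1 − TOM`, eigengene-based module merging, module membership
   `MM = cor(x_i, ME)`, intramodular soft connectivity `K_i = Σ_{u≠i} a_iu`,
   hub ranking with transcript-to-gene collapsing, and module–trait
   correlations.
3. **eQTL scan** — per (transcript, SNP) F-test of a categorical genotype
   term over a fixed-effect model with sex, sire, an RYR1-like genotype
   factor, carcass weight and slaughter-day batch; incremental R² as
   variance explained; strict < 1 Mb cis definition; threshold summaries
   and per-module Benjamini–Hochberg FDR.
4. **Integration** — eigengene QTL scans, 1-Mb window binning of member
   trans-eQTL, hotspot declaration where both signals co-localize, and
   the strict candidate filter |r| > 0.20 and p < 0.001 against the
   eigengene, ranked by |r|.
5. **Knockdown statistics** — geometric-mean reference-gene Ct
   normalization, 2^−ΔΔCt relative expression, two-tailed Student t-tests.
6. **Synthetic data** — a generator that plants a
   genotype → regulator → module causal chain (cis-regulated regulator
   transcript, loading-weighted target genes, covariate/batch effects,
   module-correlated phenotypes) and emits the ground truth, so the whole
   pipeline is validated end-to-end without any external data.

## Worked example

```python
import modqtl as m
from modqtl.pipeline import analyze

cfg = m.SimConfig(seed=1)                     # n=200 samples, 2,000 SNPs,
geno, expr_sim, pheno = m.simulate_dataset(cfg)  # one planted 30-gene module
res = analyze(geno.dosage, geno.snp_map, expr_sim.expression,
              expr_sim.probe_map, expr_sim.covariates, pheno)

print(res.module_set.assignment.value_counts().to_dict())
print(res.eqtl_counts[["threshold", "total", "cis", "trans"]].to_string(index=False))
print(res.hotspots[["module", "chrom", "region_start", "region_end",
                    "n_genes", "eigengene_min_p"]].to_string(index=False))
top = res.candidates[res.candidates["passes"]].iloc[0]
print(f"top candidate: {top['gene']}  r={top['r']:.3f}  p={top['p']:.2e}")
```

prints

```
{'unassigned': 300, 'M1': 30}
 threshold  total  cis  trans
  0.000010     33    1     32
  0.000001     22    1     21
module chrom  region_start  region_end  n_genes  eigengene_min_p
    M1     1      50000000    51000000       26     2.768657e-14
top candidate: M1_REG  r=0.988  p=3.60e-162
```

The 30 planted module genes are recovered exactly (300 background genes stay
unassigned). The scan finds one cis-eQTL (the regulator's own SNP) and 32
trans-eQTL records at p < 1e-5, 26 distinct module genes co-localize in the
1-Mb window on chromosome 1 that also carries the eigengene QTL
(p ≈ 3e-14), and the candidate search inside the padded hotspot ranks the
planted regulator transcript first with r = 0.99 against the eigengene.

The same stages are available from the shell:

```bash
modqtl simulate --seed 1 --out sim/
modqtl qc --geno sim/genotypes.tsv --out qc/
modqtl run --config pipeline.yaml --seed 1 --out run/   # full pipeline
modqtl knockdown --ct ct.tsv --target Zfp36l2 --refs Hprt1,Ppia --out kd/
```

All interchange formats are plain TSV with documented headers (missing
values encoded as `NA`); `run` additionally writes a JSON manifest with
content hashes for reproducibility.

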