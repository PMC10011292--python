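# phsmalt

Quantitative genetics of **preharvest sprouting (PHS) resistance and malting
quality** in spring barley breeding populations.

PHS — germination of mature grain on the spike after field wetting — destroys
malting value, but the seed dormancy that prevents it can also slow
germination during malting. The two trait complexes are linked through the
dormancy gene *HvMKK3* (alleles D dormant, N non-dormant, N* highly
non-dormant/PHS-susceptible) and through polygenic background correlations.
`phsmalt` implements the statistical workflow a breeding program needs to
quantify that link and its consequences for selection:

* **Germination statistics.** Per 30-kernel plate, germination percentage GE
  and the rate index
  `GI = 10 (n24 + n48 + n72) GE / (1·n24 + 2·n48 + 3·n72) ∈ [0, 10]`,
  with GI at 6 days post physiological maturity (TP1) as the PHS-resistance
  measure.
* **REML variance partitioning.** Technical repeatability
  σ²_pl/(σ²_pl+σ²_e); the within-year model `Y = TP + g + g:TP + e`; the
  check-based decomposition `σ²_g:TP ≈ σ²_Δg:TP + σ²_pltE`, where a check
  cultivar replicated every 15 samples estimates the plot-level sampling
  error σ²_pltE; and across-year heritability
  `H² = σ²_g / (σ²_g + σ²_g:TP + σ²_e / y)`.
* **Line BLUEs** from fixed-effect reparameterizations (per timepoint,
  timepoints as replicates, across years with heterogeneous error by year) —
  the hand-off point to genome-wide association tools.
* **Bivariate genetic correlations** `r_g = cov_g / √(σ²_A σ²_B)` from a
  two-trait mixed model with an unstructured 2×2 line covariance and
  trait-by-year residuals, tested with a 1-df likelihood-ratio test, scanned
  over after-ripening timepoints across and within *HvMKK3* allele groups;
  phenotypic-correlation biplots via eigen-decomposition.
* **Correlated response to selection.** Cycle means (Wald t vs the C0 base)
  and per-cycle genetic variances with a variance-homogeneity LRT.
* **End-use quality scoring** (adjunct vs all-malt) from a declarative,
  config-driven band/target table.
* **A synthetic breeding-population generator** — half-sib families from a
  common parent, index selection over cycles C0 → C1P/C1G → C2G, a
  pleiotropic tri-allelic dormancy locus with allele-specific after-ripening
  curves, and recorded ground truth for every recovery test.

A small general REML engine (`phsmalt.mixedlm`) powers all model stages:
IID/per-stratum/unstructured-2×2 random structures, heterogeneous residuals,
analytic-gradient quasi-Newton optimisation on the profiled restricted
likelihood, LRT and Wald inference.

## Worked example

```bash
phsmalt run --seed 1 --out results/study
```

simulates the default synthetic study (422 lines: 105 C0 + 108 C1P + 87 C1G +
114 C2G + 8 parents; 3 years; duplicate germination plates at 7 timepoints;
malting at TP4/TP6 with technical replicates; checks every 15 samples) and
runs every stage. With seed 1 the run reports, among others:

| quantity | value | meaning |
|---|---|---|
| `h2_fan_across_years` | 0.86 | across-year heritability of free amino nitrogen (FAN) |
| `rg_fan_gi_tp1_all_alleles` | 0.74 | genetic correlation of FAN with GI at TP1 across all *HvMKK3* alleles |
| `fan_response_c2g_vs_c0` | −37.2 ppm | correlated FAN response in the second genomic selection cycle |
| `nstar_freq_reduction_c0_to_c2g` | 0.59 | drop in N* allele frequency caused by PHS-targeted index selection |

The signs tell the biological story: PHS-targeted selection removes the N*
allele, and because FAN is positively genetically correlated with germination
rate, FAN falls as a correlated response — the adjunct-style malt profile is
genetically tied to PHS susceptibility.

Python API equivalent:

```python
from phsmalt.config import RunConfig
from phsmalt.pipeline import run_pipeline
run_pipeline(RunConfig(seed=1), out_dir="results/study")
```

Outputs are plain CSVs (`germination_summary.csv`, `varcomp.csv`,
`heritability.csv`, `blues.csv`, `genetic_correlations.csv`,
`selection_response.csv`, `scores.csv`, truth tables, and a `manifest.txt`
with content hashes for reproducibility).

## Layout

| module | contents |
|---|---|
| `phsmalt.io` | table schemas, CSV readers/writers, marker QC (het ≤ 0.10, MAF ≥ 0.05) |
| `phsmalt.germination` | GE/GI statistics and plot-level summaries |
| `phsmalt.mixedlm` | the REML engine, LRT, Wald tests |
| `phsmalt.variance` | repeatability, variance partitions, check decomposition, heritability |
| `phsmalt.blues` | fixed-effect line means per labelling scheme |
| `phsmalt.correlations` | *HvMKK3* classification, bivariate r_g scans, biplots |
| `phsmalt.selection` | correlated response to selection |
| `phsmalt.scoring` | adjunct/all-malt scores and target-range classes |
| `phsmalt.simulate` | the synthetic breeding-population generator |
| `phsmalt.pipeline`, `phsmalt.cli` | orchestration and the `phsmalt` command |

See `docs/methods.md` for the statistical models, generator assumptions and
numerical choices.
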