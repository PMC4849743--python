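# homburden

Case-control **runs-of-homozygosity (ROH)** and **genomic inbreeding**
analysis for SNP genotype data, with a synthetic-cohort generator that
plants known inbreeding and autozygous tracts so that every stage of the
pipeline is testable end to end.

## What it does

- **Cohort I/O** (`homburden.cohort`): PLINK 1 text (PED/MAP) and binary
  (BED/BIM/FAM, SNP-major, bit-exact) readers/writers; autosomes 1–22 only;
  allele-b dosage coding; per-marker frequencies, per-sample missing rates,
  configurable MAF filter (default 0.05 in the pipeline).
- **Synthetic cohorts** (`homburden.sim`): genotypes drawn from the
  inbreeding-inflated Hardy–Weinberg trinomial law, planted autozygous
  tracts of configurable kb length / SNP count, missingness, and
  label-driven / logistic-on-F / recessive-locus disease models, with a
  ground-truth TSV. Fixed seed ⇒ byte-identical output.
- **SNP-wise homozygosity tests** (`homburden.snp_tests`): per-SNP 2×2
  Pearson chi² (hom vs het × case vs control, no continuity correction)
  with Benjamini–Hochberg FDR control.
- **ROH calling** (`homburden.roh`): sliding-window caller (50-SNP windows,
  0 hets / ≤5 missing per window, ≥75 SNPs, ≥1000 kb, 1000 kb gap split,
  50 kb/SNP density), the minimum-SNP length criterion
  `(1−het)^L · n_snps · n_individuals < target`, and greedy LD tag grouping
  (r² > 0.8 within 250 kb) with the LD-adjusted minimum-SNP count.
- **Recurrent ROHs** (`homburden.recurrent`): single-linkage overlap pooling
  with consensus = interval intersection, kept at ≥6 distinct carriers,
  ≥500 kb and ≥75 genotyped SNPs; carrier chi² (+ label permutation) and a
  one-tailed Welch t-test on per-SNP homozygote proportions.
- **Burden analysis** (`homburden.burden`): per-individual ROH count /
  total kb / mean kb, case-control t-tests with label-permutation
  confirmation, median splits, and control-quantile-binned odds ratios with
  Woolf 95% CIs.
- **Inbreeding** (`homburden.inbreeding`): SNP-wise estimators F1
  (additive-variance), F2 (excess homozygosity), F3 (uniting-gamete
  correlation), segment-based `F_ROH = Σ L_ROH / L_AUTO`
  (L_AUTO = 2,676,172,944 bp by default), per-chromosome profiles, and
  cross-measure correlations.
- **Association GLM** (`homburden.glm`): genotype PCA covariates
  (standardized dosages, deterministic signs), logistic regression of case
  status on an inbreeding measure with sex / PCs / missing-rate covariates,
  and a permutation-of-regressor-residuals test.
- **Pipeline + CLI** (`homburden.pipeline`, `homburden.cli`): orchestrated
  simulate → roh → recurrent → burden → inbreed → assoc run with TSV
  outputs, a manifest (input hashes, version, seed) and a text report.

## CLI

```sh
homburden simulate --fixture clean_roh --out-dir sim/
homburden roh      --ped sim/cohort.ped --map sim/cohort.map --out segs.tsv
homburden recurrent --ped sim/cohort.ped --map sim/cohort.map \
                    --segments segs.tsv --out pools.tsv
homburden burden   --ped sim/cohort.ped --map sim/cohort.map \
                    --segments segs.tsv --stat n_rohs --out-prefix burden
homburden inbreed  --ped sim/cohort.ped --map sim/cohort.map \
                    --segments segs.tsv --out inbreeding.tsv
homburden assoc    --ped sim/cohort.ped --map sim/cohort.map --measure f1 \
                    --covariates sex,pcs,missing --n-perm 1000 --seed 17
homburden run      --fixture clean_roh --seed 1 --out-dir out/
```

`homburden run --config cfg.txt` accepts a flat `key = value` config file;
`PipelineConfig` in `homburden/pipeline.py` documents every key and its
default.

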