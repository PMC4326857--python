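# regionscan

Region-centric discovery of **differentially methylated regions (DMRs)**
and **variably methylated regions (VMRs)** in sparse CpG methylation array
data (Infinium 450K-style beta-value matrices).

Single-CpG epigenome-wide association scans test ~450,000 probes against a
phenotype, paying a heavy multiple-testing price and remaining vulnerable
to single aberrant probes.  Because methylation of neighbouring CpGs is
correlated over short distances, `regionscan` groups probes into
distance-based regions (every adjacent gap ≤ L, default 1 kb, ≥ 2 probes)
and tests regions instead:

* **DMRs** — per-probe OLS of methylation on age,
  `Y_ij = γ_j + β_j·X_i + ε_ij`; a candidate is a run of in-cluster probes
  all with β above the 95th percentile of positive β (hyper) or below the
  5th percentile of negative β (hypo), scored by the trapezoidal area of
  |β| over genomic position.  Significance by phenotype permutation: ages
  are shuffled K times, the entire identification rerun, and the observed
  area compared against the pooled null areas
  (`p = #{A⁰ ≥ A_r} / #A⁰`), followed by Benjamini–Hochberg q-values.
* **VMRs** — per-probe median absolute deviation (MAD) within one sample
  group; candidates are runs of probes with MAD above the 95th percentile.
  Significance by parametric bootstrap: log-MAD along regions is modelled
  as a stationary AR(1) process (`k_i = ρ·k_{i−1} + e_i`) fitted by Burg's
  method on all regions with ≥ 50 probes, and synthetic MAD landscapes on
  the real probe layout supply the null areas.

Supporting machinery: the correlation-vs-distance profile that motivates
L, cross-hybridizing-probe region filtering, probe-weighted hypergeometric
gene-set enrichment, CpG-island-category and open-chromatin (DNase hot
spot) enrichment, multi-list overlap simulation, a SNP-proximity filter,
a Wilcoxon–Mann–Whitney power comparison of single-probe vs region
testing, and a synthetic-data generator that reproduces the spacing and
correlation structure the method assumes.  See `docs/methods.md` for the
full model description.

## Worked example

Simulate a 5,000-probe study with planted age effects, then run the DMR
scan:

```sh
regionscan simulate --n-probes 5000 --n-samples 60 --n-planted 20 \
    --seed 17 --out-prefix sim/
regionscan dmr --matrix sim/matrix.tsv --pheno sim/pheno.tsv \
    --manifest sim/manifest.tsv --K 100 --seed 17 --out sim/dmrs.tsv
```

which prints

```
17 significant DMRs of 26 candidates (q < 0.05); fraction hypomethylated with age: 0.471
```

17 of the 20 planted regions (each a cluster of probes whose methylation
drifts 0.002 per year of age) reach q < 0.05 against a 100-permutation
null; the planted effects alternate sign, hence
roughly half the calls are hypomethylated with age.  `sim/dmrs.tsv` lists
each region's span, member probes, area, direction, empirical p and q;
`sim/dmrs.tsv.bed` is a BED6 browser track; `sim/dmrs.tsv.run.json`
records the seed, configuration and input checksums for reproduction.

The same pattern with `regionscan vmr --group old` scans one group for
variability regions, and `regionscan cluster / corr / enrich / snpfilter`
expose the supporting analyses.  All commands are thin wrappers over the
library API (`regionscan.run_dmr_pipeline`, `regionscan.run_vmr_pipeline`,
…), which is the recommended surface for scripted analyses.

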