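# hotprop

Hotspot propensity of somatic mutational processes: detection of recurrent
same-base mutations, fixed-activity subsampling, and closed-form models of
expected hotspot counts.

## The problem

Somatic mutations are sparse: even pooling thousands of whole genomes leaves
most of the ~3 Gbp unobserved, which makes mutation-rate variability at
single-base resolution hard to measure directly. A useful indirect readout is
the **mutational hotspot** — a single genomic position mutated to the same
alternate allele in two or more independent samples. A mutational process that
concentrates its activity on few genomic positions forms hotspots far more
often than one that spreads the same number of mutations evenly, so the rate
of hotspot formation *at fixed activity* measures the process's single-base
rate variability.

`hotprop` implements that programme end to end for anyone studying somatic or
germline mutagenesis:

* **Hotspot calling** (`hotprop.hotspot_finder`) — QC filter cascade
  (reference mismatches, ambiguous context, complex indels, mappability,
  blacklist, population variants, driver regions), duplicate-sample and
  hypermutator detection, and alternate-specific or position-level hotspot
  identification.
* **Signature machinery** (`hotprop.signatures`) — 96-channel catalogs,
  genome-normalized profiles and their entropy
  `H = -Σ_k p_k log p_k`, non-negative least-squares exposure fitting
  `Ê = argmin_{E≥0} |SE − M|²_F`, exhaustive AIC search over signature
  subsets, and probabilistic attribution
  `P(s | c) = E_s f_s(c) / Σ_t E_t f_t(c)`.
* **Observed propensity** (`hotprop.propensity`) — repeated subsampling at
  fixed activity (default 100 samples × 300 mutations, 1000 iterations),
  conversion rates (mutations per hotspot, from the inverse slope of hotspot
  membership on burden), and inside/outside-hotspot enrichment statistics
  with a paired signed-rank test and Benjamini–Hochberg correction.
* **Expected models** (`hotprop.expected_model`) — closed-form expected
  hotspot counts under per-position independence. With per-position,
  per-alternate mutation probability `q`, a sample of `n` mutations hits the
  event with probability `π = 1 − (1−q)^n`, and a cohort of `S` samples forms
  no hotspot there with probability `(1−π)^S + Sπ(1−π)^{S−1}`. Weight maps
  come in three resolutions: trinucleotide profile only
  (`q = f(c→a)/N_c`), binned regional rates (`q = r_k f_k(c→a)/N_{c,k}`),
  and CpG-methylation-aware
  (`q_meth = fρ/(ρN_m + N_u)`, `q_unmeth = f/(ρN_m + N_u)`), where ρ is the
  methylated/unmethylated mutability fold inferred as a per-site odds ratio.
  A class-based Monte-Carlo simulator acts as the independent oracle for the
  closed form. Negative-binomial overdispersion (`v = μ + αμ²`) quantifies
  binned rate heterogeneity.
* **Local features** (`hotprop.local_features`) — core-vs-flank pileup
  enrichment in 2000-bp feature windows (600-bp core) against a
  sequence-composition-aware randomization null, methylated-CpG odds ratios,
  and covariate-decile summaries.
* **Synthetic data** (`hotprop.synthetic_data`) — genomes with controllable
  CpG depletion, masks, bimodal methylomes, feature tracks and
  signature-driven cohorts, so every claim above is testable against a known
  ground truth with no external downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(an 8-Mbp CpG-depleted genome, three single-signature cohorts of 100 samples ×
450 mutations):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_find_hotspots.py
python analysis/03_fit_signatures.py
python analysis/04_propensity.py
python analysis/05_expected_models.py
python analysis/06_local_features.py
```

Outputs land in `results/`. A run prints, among other things:

```
SIG_CPG: kept 43985/45000 mutations, 6151 alternate-specific hotspots
SIG_CPG: median 3082.0 hotspots per 30,000 subsampled mutations (IQR 3059-3104)
SIG_FLAT: median 48.0 hotspots per 30,000 subsampled mutations (IQR 44-51)
SIG_CPG: inferred methylation fold rho = 2.03
  SIG_CPG        genomewide 2806.17  ... explained 91.1%
  SIG_CPG methylation_aware 2966.93  ... explained 96.3%
mutations: OR = 2.03 [1.97, 2.09]
hotspots:  OR = 3.42 [3.16, 3.70]
```

Reading this: the profile concentrated on the four (depleted) NpCpG>T
channels forms ~64× more hotspots than the near-uniform profile under
identical activity; its trinucleotide-composition model already explains ~91%
of the observed median, and adding the (true fold 2, inferred 2.03) CpG
methylation structure closes most of the rest. Hotspots are more strongly
enriched at methylated CpGs (OR 3.42) than individual mutations are (OR
2.03), as recurrence amplifies rate differences.

## Command line

A thin CLI covers the standalone operations:

```bash
hotprop hotspots   --mutations muts.tsv --genome genome.fa --out hotspots.tsv
hotprop expected   --genome genome.fa --profiles cosmic.tsv --signature SBS1 \
                   --samples 100 --mutations-per-sample 300 --out expected.tsv
hotprop propensity --mutations muts.tsv --out propensity.tsv
hotprop simulate   --config config.yaml --profiles profiles.tsv \
                   --exposures SBS1=0.6,SBS5=0.4 --outdir cohort/
```

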