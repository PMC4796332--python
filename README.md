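# hapalt

Analysis toolkit for SNP-panel surveys of an archaic-introgressed haplotype
across populations living at different altitudes — the study design used to
show that a Denisovan-derived *EPAS1* haplotype is widespread in Himalayan
populations and strongly correlated with residence altitude.

Given a samples × SNP genotype table (derived-allele dosages for a ~19-SNP
intronic panel) and a population table (3-letter codes, residence altitude in
metres), the package provides the full computational chain:

- **QC** — sex-concordance filtering, per-sample (>20%) and per-SNP (>30%)
  missingness filters, duplicate-pair and reference concordance;
- **phasing** — an Excoffier–Slatkin EM estimator of haplotype frequencies
  with per-sample best-pair assignment (a deterministic, testable stand-in
  for coalescent phasing software, adequate at ~19 tightly linked SNPs);
- **core-haplotype statistics** — calling the five-SNP core motif (derived
  at rs115321619, rs73926263, rs73926264, rs73926265, rs55981512 — "AGGAA"),
  per-population frequencies, Spearman rank correlation with altitude,
  derived-allele frequency profiles, and the shared-derived-allele filter
  for nominating candidate functional variants (derived + carried by the
  archaic genome + fixed in carriers + absent from non-carriers);
- **median-joining networks** — minimum spanning networks augmented with
  consensus median vectors that reduce total mutational cost, with
  core/non-core cluster partitioning;
- **selection inference** — a hierarchical Bayesian sampler for locus- and
  deme-specific scaled selection coefficients σ = 2·Nₑ·s under Wright's
  island model, with stationary density
  π(p) ∝ p^(Mπ̃−1)(1−p)^(M(1−π̃)−1)·e^(σp),
  plus genotype–altitude association under additive / dominant / recessive
  codings;
- **forward simulation** — two-population Wright–Fisher scenarios (split at
  2800 / 10,000 / 30,000 years, 30 y/generation; starting frequencies 0.01 /
  0.05 / 0.1; selection only in the highland population with
  s = σ/(2·Nₑ)), 100 replicates per cell;
- **synthetic data** — a generator that emulates the survey's statistical
  structure (two haplotype clusters, altitude-driven core frequency, missing
  calls, duplicates, sex discordance, genotyping error) with ground-truth
  phase, so every stage is testable without any external data.

## Worked example

Fit selection coefficients on a synthetic nine-deme survey (six lowland
demes pin the migration rate; three highland demes carry the core haplotype
at high frequency):

```bash
python examples/04_selection_inference.py
```

```
posterior mean sigma at core loci, by deme (rows = demes):
     rs115321619  rs73926263  rs73926264  rs73926265  rs55981512
P00          8.5         9.6         9.0         8.6         9.3
...
P06         54.4        57.2        51.6        59.4        59.9
P07         62.9        70.9        68.7        72.0        73.4
P08         72.8        86.0        76.6        83.3        81.6

estimated M = 17.3
```

The three high-altitude demes (P06–P08) receive scaled selection
coefficients an order of magnitude above the lowland demes at every
core-motif locus — the signature the method is built to detect.  The
companion examples cover QC (`01`), phasing + altitude correlation (`02`,
prints Spearman ρ = 0.970, p = 1.75e-07 on a 12-population survey),
networks (`03`), forward simulation (`05`, the grid showing fixation under
an old split versus intermediate frequencies under a 2800-year split), and
the one-command pipeline (`06`).

The same stages are exposed as a CLI (`hapalt qc|phase|core-freq|correlate|
assoc|selestim-lite|network|simulate|run|demo`); `hapalt demo --out-dir out`
runs the whole chain on bundled synthetic data.

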