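# opnsplice

Quantifying co-overexpression of osteopontin (OPN/*SPP1*) splice isoforms in
tumor cohorts from exon-level expression data, with matching qRT-PCR
quantification rules and a seeded synthetic-cohort generator.

## The problem

*SPP1* produces five splice isoforms over eight exons: OPNa (the reference
form), OPNb (skips exon 6), OPNc (skips exon 5), OPN4 (skips exons 4–6) and
OPN5 (the only isoform containing exon 4). In esophageal adenocarcinoma
(EAC) these isoforms are of interest because they act through distinct
invasion/adhesion mechanisms, so knowing whether tumors express one isoform
exclusively or all of them together matters for targeting.

Exon arrays measure per-exon probe-set signals, not per-isoform abundances.
Writing θ for the vector of isoform abundances and M for the binary
isoform × exon incidence matrix, the signal on exon *e* is

    S_e = Σ_i M[i, e] · θ_i ,

so only linear functionals c′θ in the row space of the observed design are
estimable. On the array used for the EAC cohort no probe set targets exon 6;
`opnsplice` shows that the estimable functionals are then exactly the three
group sums **OPNa+OPNb**, **OPNc+OPN4** and **OPN5**, and estimates them by
the subtraction scheme

    OPN5      = S₄            (exon 4 is private to OPN5)
    OPNa+OPNb = S₅ − S₄       (exon 5 carries OPNa, OPNb, OPN5)
    OPNc+OPN4 = S_total − S₅

where S_total is the mean of the k = 3 common-exon probe sets with the least
cross-sample deviation (common exons 1, 2, 3, 7, 8 appear in every isoform).
A non-negative least-squares estimator generalizes the scheme to arbitrary
designs; Pearson correlation of each group against S_total quantifies
co-overexpression. Arithmetic is on linear-scale abundances (2^log2 signal);
correlations default to the log2 scale.

The qPCR side implements 2^−ΔΔCt with a three-gene reference index
(*GAPDH*, *ACTB*, *RPLP0*), the tumor overexpression caller with threshold
T = 2·m + s (m, s: mean and SD of the Normal + Barrett's reference folds),
per-stage Welch comparisons, and the single-tube copy-number ratio
2^−[(ΔCt tumor) − (ΔCt normal)] against an internal control.

Because the original cohorts are not redistributable, a seeded generator
produces cohorts with the structure the analysis assumes: a shared
per-sample log-normal factor (co-overexpression), class-dependent tumor
upregulation (+3 log2 in EAC), Dirichlet isoform proportions with OPNc
scarcer than OPNa/OPNb, exon-level probe noise, and Ct tables.

## Worked example

```python
from opnsplice import (SimulationConfig, simulate_cohort, simulate_exon_signals,
                       select_total_proxy, subtraction_estimates, correlate_groups)
from opnsplice.spp1 import spp1_incidence

M = spp1_incidence()
cfg = SimulationConfig(n_per_class=29, seed=1)      # ~200 samples, 7 classes
rng = cfg.rng()
labels, truth = simulate_cohort(cfg, rng)
X = simulate_exon_signals(truth, M, cfg, rng)
proxy = select_total_proxy(X, M, k=3)
estimates = subtraction_estimates(proxy, X, M, sorted(set(X.probe_to_exon.values())))
for corr in correlate_groups(estimates, proxy):
    print(f"{corr.group_label:10s} r = {corr.pearson_r:.3f} (n = {corr.n})")
```

prints

```
OPNa+OPNb  r = 0.995 (n = 203)
OPNc+OPN4  r = 0.891 (n = 200)
OPN5       r = 0.883 (n = 203)
```

— every identifiable isoform group rises and falls with total OPN
expression across the cohort, the co-overexpression signature. The same
workflow on noise-free signals returns the true group sums exactly, and on
noisy cohorts recovery of the simulated truth is r ≈ 0.99 for OPNa+OPNb and
OPN5 and r ≈ 0.91 for the subtraction remainder OPNc+OPN4 (see
`docs/methods.md` for why the remainder is noisier).

More narrated examples live in `examples/` (identifiability and null space,
the 253/211/172 bp amplicon ladder, cohort deconvolution, qPCR
quantification, the end-to-end pipeline). The `opnsplice` console script
exposes the stages as `simulate`, `incidence`, `deconvolve`, `qpcr` and
`report` subcommands; `opnsplice report -c config.yaml` runs everything
from a YAML config and writes TSV outputs plus a JSON/Markdown run report.

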