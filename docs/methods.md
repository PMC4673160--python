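# Methods

## Model

Let θ ∈ R⁵₊ be the per-sample linear-scale abundances of the *SPP1* isoforms
(OPNa, OPNb, OPNc, OPN4, OPN5) and M the 5 × 8 binary isoform × exon
incidence matrix. An exon-level probe set targeting exon *e* measures, up to
log-scale noise, the summed abundance of the isoforms containing *e*:

    S_e = Σ_i M[i, e] · θ_i.

Exons with identical membership columns carry identical information and are
collapsed into one design equation (their signals averaged on the linear
scale, as are multiple probe sets on one exon). The estimable linear
functionals of θ are the row space of this collapsed design; the null space
is the unidentifiable ambiguity. `identifiable_groups` computes both in
exact rational arithmetic (sympy RREF/nullspace), canonicalizes the bases to
coprime integer coefficients with positive leading entry, ordered by first
nonzero isoform, and labels 0/1 functionals as '+'-joined groups. Two facts
follow for *SPP1*:

* without exon 6 (the array situation) the rank is 3 and the estimable
  groups are exactly {OPNa+OPNb}, {OPNc+OPN4}, {OPN5};
* even with all 8 exons the rank is only 4: the contrast
  OPNa − OPNb − OPNc + OPN4 is invisible to exon-level data, because the
  exon-5 and exon-6 columns sum to the same pattern. Exon arrays can never
  fully resolve these five isoforms.

## Estimators

**Total proxy.** Candidates are probe sets on common exons (present in every
isoform). Each candidate's deviation score is the cross-sample SD of its
log2 signal after centering every sample at the median of all candidates;
the centering removes genuine per-sample expression differences so the score
ranks probe-level inconsistency. The k = 3 lowest-scoring candidates (ties
by probe-set id) are averaged on the linear scale.

**Subtraction.** When the non-common observed exon patterns have nested
carrier sets ({OPN5} ⊂ {OPNa, OPNb, OPN5} for *SPP1*), successive
differences of the per-pattern linear signals, anchored at the total proxy,
yield each group: OPN5 = S₄, OPNa+OPNb = S₅ − S₄, OPNc+OPN4 = S_total − S₅.
Negative differences are clipped to 0 and flagged; clipping is diagnostic,
never silent. Non-nested designs raise an error pointing to the NNLS route.

**NNLS.** Per sample, `scipy.optimize.nnls` solves the collapsed design for
a non-negative θ̂ and the estimable group functionals are evaluated on θ̂.
On consistent (noise-free) systems estimable functionals are invariant over
the solution set, so NNLS and subtraction agree to numerical precision —
the package tests this equivalence rather than assuming it.

**Scale choices.** Abundances add on the linear scale, so all subtraction
and least-squares arithmetic is linear (signals are 2^log2 first); a log2
alternative would subtract ratios and is deliberately not offered for
estimation. Pearson correlations default to log2-transformed abundances —
the scale on which array expression is conventionally compared — excluding
clip-censored samples (reported n says how many were used);
`scale="linear"` is available.

## qRT-PCR rules

Replicate Ct values are averaged per (sample, assay); replicate pairs more
than 1.0 cycle apart are flagged, not dropped. The reference index is the
arithmetic mean of the reference-gene Ct values (*GAPDH*, *ACTB*, *RPLP0* by
default), i.e. the geometric mean of their linear quantities; ΔCt = Ct_target
− index, ΔΔCt subtracts the mean calibrator ΔCt, fold = 2^−ΔΔCt with
efficiency fixed at 2 per cycle. Consequences the tests rely on: the
calibrator's geometric-mean fold is exactly 1, adding any constant to all of
a sample's Ct values leaves its fold unchanged, and one target cycle equals
a factor of 2.

The overexpression caller uses T = 2·m + s, with m and s the mean and
sample SD (n−1) of fold changes in the Normal + Barrett's reference group,
and calls strictly above T. The wording "2-fold plus one SD" admits a second
reading (fold > 2 AND fold > m + s); it is implemented behind
`rule="2fold_and_m_plus_s"` with the first reading as default, since a
single threshold line matches how such cutoffs are drawn on cohort plots.
Stage comparisons use Welch t-tests on log2 folds (fold distributions are
log-normal-like); identical zero-variance classes are reported as p = 1
rather than NaN. The copy-number ratio is 2^−[(ΔCt_t) − (ΔCt_n)] from
single-tube co-amplification with an internal control; the gain/loss bounds
1.5/0.67 are configurable conventions — the biology of interest here is the
*unchanged* call.

## Synthetic cohorts

Per sample: total = 2^(baseline + class shift + N(0, σ_sample)); isoform
proportions are one Dirichlet draw; abundances are total × proportions.
Probe signals add N(0, σ_probe) on the log2 scale; Ct values follow
Ct = intercept − log2(quantity) + N(0, σ_ct) with constant-quantity
reference genes. All randomness flows through one `numpy` Generator, so a
fixed seed gives byte-identical outputs.

Defaults and why:

* **class shifts** — EAC stages +3 log2 (8-fold) over Normal, Barrett's 0,
  dysplasia +1: tumor upregulation strong enough that the caller's job is
  sensitivity, not heroics; the stage gradient is deliberately flat since
  stage differences in the motivating cohorts were not significant.
* **shared factor σ_sample = 1.0 (log2)** — one per-sample factor multiplies
  every isoform; this is the entire mechanism generating co-overexpression,
  and the simplest one consistent with strongly correlated groups.
* **Dirichlet concentration (18, 18, 6, 3, 3)** — means 0.375/0.375/0.125/
  0.0625/0.0625 encode OPNc scarcer than OPNa ≈ OPNb and minor OPN4/OPN5,
  with OPNb above or below OPNa in individual samples. The concentration
  *scale* is a calibration: a scale-1 component (Beta(1, 15)) has log-SD
  ≈ 1.8, which would swamp the shared factor and destroy the group-vs-total
  correlation the generator exists to emulate; ×3 keeps proportion noise
  subordinate (OPN5 log-SD ≈ 0.6) so every group correlates with total at
  r > 0.8. These are qualitative reconstructions, not measured quantities.
* **probe noise σ_probe = 0.1 log2; 4 probe sets per common exon, 1
  elsewhere; no exon-6 probe set** — a clean summarized exon array with the
  one structural gap that makes the problem interesting.
* **Ct: intercept 30, σ_ct = 0.1, duplicates; references at 1024/512/256** —
  quantities in the 2^6±spread range land Ct in the low-to-mid 20s, typical
  for an abundant transcript.

What the generator does *not* emulate: probe-sequence effects and
cross-hybridization, batch and array-version effects, within-tumor
heterogeneity or stromal contamination, reference-gene instability, and
amplification efficiencies below 2. Passing tests therefore demonstrate the
estimators' correctness and noise behavior under the stated generative
model, not robustness to those real-data artifacts.

## Numerical choices and degenerate inputs

Identifiability is exact rational arithmetic, so rank decisions carry no
floating-point tolerance. Estimator agreement and conservation are asserted
at 1e-9 relative. Clipping at 0 never increases an estimate and vanishes as
noise → 0. Zero-variance groups are reported as not-computable rather than
r = 0. Proxy ties break by probe-set id; requesting more proxy probe sets
than exist selects all with a warning. All-zero expression propagates to
all-zero groups without clipping flags. Writers are atomic (temp file +
rename), so interrupted runs leave no partial tables.

## Problem sizes

Cohort-level checks use ~200-sample cohorts (the scale of the motivating
EAC series) with 20 seeds for seed-swept recovery, 50 samples for the
noise-free estimator-equivalence check, and 60 pairs for the copy-number
cohort. These sizes give stable statistics (correlation SEs ≈ 0.01–0.02)
while the whole suite runs in well under a minute.

## Known limitations

* The estimator variance of the remainder group (OPNc+OPN4 = S_total − S₅)
  is dominated by the single exon-5 probe set: at σ_probe = 0.1 its error is
  ≈ 0.06 × total in linear units against a true signal of ≈ 0.19 × total,
  capping recovery correlation near 0.92 where the directly measured groups
  reach 0.99. More exon-5 probe sets or lower probe noise are the only
  remedies; the package reports the recovery it actually achieves.
* The amplicon ladder's primer anchors are a reconstruction: exon 5 (81 bp)
  and exon 6 (42 bp) are pinned by the 253/211/172 bp band spacing, but the
  anchor exons and offsets are chosen, not measured.
* GTF input assumes one gene on one strand per file; multi-gene annotations
  should be pre-filtered.
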