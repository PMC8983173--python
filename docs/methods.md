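# Methods

## Problem setting

rs76971248 is a biallelic G>T substitution (label NT-26) in the HLA-E
promoter/regulatory region. The toolkit implements three independent routes
to a diploid genotype call at this site and the statistics of a two-cohort
association study. All three callers emit the same vocabulary: `G/G`, `G/T`,
`T/T`, `UNKNOWN` (with an optional `VARIANT_SUSPECTED` flag on HRM calls).

## Reference database

References are pre-aligned, equal-length A/C/G/T sequences over a ~400-bp
promoter amplicon. Indels and gaps are out of scope: the amplicon is short,
and keeping coordinates fixed lets scoring stay positional and exact. Site
labels such as "NT-26" are symbolic; promoter numbering conventions differ
between sources (relative to ATG, to the transcription start, etc.), so the
coordinate is supplied by configuration (a 0-based column index plus ref and
alt base) and never guessed. The packaged database is a **synthetic** toy
stand-in for the real allele catalogue: four alleles over 400 nt, exactly one
carrying the NT-26 T, two others differing at one or two unrelated columns.

## Sequence-based typing

A diploid Sanger consensus represents heterozygous positions as IUPAC codes
(G/T double peak → K). For alleles a, b the expected consensus is the
position-wise IUPAC superposition of their sequences; self-pairs (a, a) are
included so homozygotes type correctly. The observed consensus is scored
against all n(n+1)/2 expected consensuses.

**Score.** Number of exact per-position IUPAC code matches (Hamming
similarity). This is the simplest rule that produces a ranked-combination
output; a partial-credit variant (observed base set ⊆ expected base set)
would be a backward-compatible extension. An observed N matches only an
expected N — conservative, deterministic.

**Ties.** All pairs attaining the maximum score are reported (`best` is a
set). Typing ambiguity between alleles identical over the amplicon is real
information and is never hidden by arbitrary tie-breaking; the ranking order
itself uses a lexicographic tiebreak purely for stable output.

The site genotype is read directly from the observed code at the configured
column (G → G/G, T → T/T, K → G/T, anything else → UNKNOWN). On noise-free
input this agrees with the genotype implied by the best-scoring pair; the
direct read degrades more gracefully under local base-call noise.

## Endpoint (TaqMan) calling

Two channels: fx (wild-type G probe), fy (mutant T probe). A well with
max(fx, fy) below `min_signal` (default 5.0 units) failed to amplify →
UNKNOWN. Otherwise the call is the genotype of the nearest configured
centroid (Euclidean distance in the (fx, fy) plane). Calls are invariant
under joint rescaling of signals and centroids. Default centroids
(30, 3) / (18, 18) / (3, 30) with per-channel Gaussian noise SD 1.0 give a
cluster separation of ≳ 12 SD — instruments print no numeric fluorescence
values, so these are fixture constants chosen to emulate a cleanly clustered
endpoint plot, documented here and exposed via config.

## HRM calling

Normalization is two-point linear: the mean over a pre-melt temperature
window maps to 1, the mean over a post-melt window to 0 (defaults 68–72 °C
and 89–92 °C on a 65–92 °C grid). This is deliberately simpler than
exponential background subtraction; it is idempotent, affine-invariant, and
sufficient for curves whose windows bracket the transitions. Distance to the
per-genotype reference curves is the mean absolute difference on the
references' grid after linear-interpolation resampling.

`max_distance` (default **0.02**) separates "assign nearest genotype" from
"flag VARIANT_SUSPECTED". Calibrated on the synthetic fixtures: concordant
wells at default noise sit near 0.003 (≈ 6× below threshold), while melt
transitions ≥ ~1 °C outside the catalogued Tm range sit above ≈ 0.025. A
variant whose transition lands within ~0.5 °C of a catalogued duplex Tm is
physically indistinguishable from that genotype by curve shape — a known
limitation of HRM, not of the implementation.

A sample genotype requires at least `min_replicates` = 3 informative wells
that all agree; fewer informative wells or any discordance → UNKNOWN
(repeat the experiment).

## Association statistics

* **Pearson χ²** on 2×2 tables, uncorrected: χ² = N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)],
  p from the 1-df upper tail. No Yates correction — the study's printed
  values (9.515, 3.921, 6.046) are the uncorrected statistic; the corrected
  variant is available behind a flag.
* **Fisher's exact test**, two-sided by point-probability summation
  (hypergeometric probabilities ≤ that of the observed table), used whenever
  any expected cell is below 5.
* **Odds ratio** ad/bc with the Woolf (logit) 95% CI,
  exp(ln OR ± 1.96·√(Σ 1/cell)). A zero cell makes the CI (and for a zero
  off-diagonal product the OR) undefined; this raises an error — no silent
  continuity correction.
* **HWE**: 1-df χ² goodness of fit of observed genotype counts against
  (p̂²n, 2p̂q̂n, q̂²n); a monomorphic cohort fits trivially (χ² = 0, p = 1).
  An exact HWE test is out of scope.
* **Report**: allele-level case vs control table, per-subtype allele tables,
  and per-genotype tables modeled as *genotype vs all others*. Display
  rounding is 3 decimals for statistics and 2 for percentages; full precision
  is kept internally.

Two published-table quirks are flagged, not resolved: the patient allele
counts as printed (437 G / 19 T) differ by one chromosome from the
genotype-derived counts (438 G / 18 T) — the report computes each table from
its own counts and records the disagreement in `notes`; and the published
G/G odds ratio (2.007, CI 1.114–3.614, p 0.019) is not derivable from any
evident 2×2 of the printed counts (genotype-vs-rest gives 2.586,
p ≈ 0.001) — the report carries its own computed value.

## Synthetic data

The generators emulate the study's statistical structure; defaults are the
study conditions: cases n = 228 at T-allele frequency 0.0416, controls
n = 226 at 0.0929, sampled under Hardy–Weinberg (two independent Bernoulli
alleles per individual; `hwe=False` produces a maximally disequilibrated
all-homozygote cohort for negative controls). Consensus sequences are built
from a uniformly drawn allele pair consistent with the genotype, with
optional i.i.d. per-position corruption by a random different IUPAC code.
Melt curves are logistic duplex-melting transitions (width 0.7 °C) at
Tm 84.6 °C (G homoduplex) and 83.4 °C (T homoduplex); the heterozygote is an
equal mixture of the homoduplex and a destabilized heteroduplex transition
at 81.8 °C, which is what gives heterozygous HRM curves their distinct
shape. Additive Gaussian noise SD 0.15 raw units on an amplitude of 40
(≈ 0.004 after normalization). All randomness flows through one explicit
seed/Generator argument; a fixed seed reproduces byte-identical outputs.

What the simulators do **not** emulate: chromatogram traces and base-caller
artifacts (corruption is i.i.d., real Sanger noise is position-correlated),
PCR efficiency and Cq structure, probe cross-talk, plate/batch effects, and
sequence-determined Tm. Passing recovery tests therefore demonstrates the
correctness of the call logic under the stated noise model, not instrument
robustness on real wells.

## Problem sizes and numerical choices

The replicate-coverage check simulates 200 studies at the study's cohort
sizes (counts only — the genotype callers are exercised separately on a
120-sample simulated study run through all three methods, where their calls
are 100% concordant with truth below the default noise levels). The Woolf CI
coverage of the generating odds ratio across replicates is ~95%, consistent
with its nominal level. Tolerances in the test suite: published values at
their printed precision; oracle equivalences at 1e-9; sampling checks within
3–4 standard errors under fixed seeds.

## Known limitations

Positional scoring presumes correctly trimmed, aligned input — there is no
alignment step. HRM references are synthetic; with real instrument data they
must be built from control wells of known genotype. The endpoint caller is
nearest-centroid, not a mixture model; heavily skewed clusters would need
per-class covariances. Fisher's test and the χ² are two-sided only; no
multiple-testing correction is applied (matching the study design).
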