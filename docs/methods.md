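# Methods

This note documents the models, conventions and numerical choices behind
`chimpnet`, and what the synthetic generator does and does not emulate.

## Sampling model

The unit of observation is the *focal follow*: 18 minutes tracking one individual,
with nine instantaneous scans at 2-minute ticks recording the focal's party (the
temporary fission–fusion subgroup), the subset of the party within 10 m, and the
focal's grooming state (given / received / mutual) with at most one partner.
Follows of the same focal are kept at least 20 minutes apart so consecutive
samples can be treated as independent. Communication is recorded continuously
alongside: each event has a signaller, recipient(s), and a functional category
from a fixed ethogram. Pant-hoots are broadcast calls — every individual within
10 m of the signaller is a recipient — while gestures and pant-grunts are
one-to-one.

All rate measures are focal-perspective ordered-dyad quantities. Because only
focals are followed, the matrix cell (non-focal → focal) is structurally missing
unless that individual is also a focal; with 12 focals this yields the full 132
ordered dyads.

## Rate measures and their conventions

`DA = 60·P10/PSP` (minutes within 10 m per hour in the same party, range 0–60),
`GA = 60·GR/P10` per grooming category, and `CA = 30·C/P10` (sequences per hour
within 10 m). Three conventions matter:

- **Operator precedence.** The rate definitions are implemented as
  numerator ÷ (denominator × 2): only that reading places DA on the documented
  0–60 min/h scale, since the numerator carries the ×2 scan-duration and ×60
  per-hour factors.
- **Missing, not zero.** A dyad never observed in the denominator state (PSP = 0
  for DA, P10 = 0 for GA/CA) carries no information about the behavior and is
  missing; missing dyads are excluded pairwise downstream. Encoding them as 0
  would conflate "never co-present" with "co-present but never close".
- **Sequence assembly.** Gestures group into sequences greedily left-to-right per
  signaller; a sequence breaks when the recipient, goal or context changes or the
  gap exceeds 30 s (30 s exactly still joins, matching a "maximum of 30 s"
  criterion). Goal/context equality is exact string match on coder-assigned
  controlled vocabulary. Gesture functions are counted per sequence; pant-hoot
  categories count each co-recipient dyad once per event; pant-grunts count per
  call event.

The repertoire filter admits a morphological gesture type iff at least 60% of its
cases (boundary inclusive) show at least one of the five intentionality criteria.
Cohen's kappa is computed from the marginal-product expected agreement and is
reported as undefined when both coders are constant and identical.

## Networks and bonds

Dichotomization scores any positive rate as a tie; OR-symmetrization scores an
undirected tie when either directed cell has one (one observed 1 dominates a
missing opposite cell; only double-missing stays missing). Bond thresholds are
the mean ± half SD of the *directed* off-diagonal nonmissing proximity values
(132 cells for 12 focals); threshold comparisons are inclusive. The SD is the
population SD (ddof = 0), the convention of the matrix-analysis tools this
workflow descends from. If every value is identical the band collapses and
classification raises a degenerate-threshold error rather than labeling every
dyad both preferred and non-preferred.

A published instance of this workflow prints thresholds (30.3 and 16.23 around a
mean of 21.16) that are mutually inconsistent with any single (μ, σ) pair; this
implementation always derives both thresholds from one (μ, σ) computed from the
data, and the discrepancy is noted here rather than resolved.

Normalized degree divides by the number of *observed* potential partners (≤ n−1),
so partial sampling does not deflate centrality; on binary networks it is the
proportion of potential partners with a tie. Degree is used instead of
eigenvector-style centralities because those are unreliable when only part of a
community is sampled.

## Permutation inference

- **MRQAP (double semi-partialling).** Point estimates are OLS with intercept on
  the vectorized nonmissing off-diagonal dyads (listwise deletion over outcome
  and predictors). For each predictor, its dyad vector is residualized on the
  remaining predictors, the residuals are placed back in matrix form, and each
  permutation relabels nodes (rows and columns jointly) before re-extracting the
  originally observed cells — permuting node identity rather than cells preserves
  the row/column dependence that makes dyadic data non-exchangeable cellwise. A
  permutation that moves a missing cell into the observed set drops that dyad for
  that permutation only.
- **Pivot and p-value.** The permutation pivot is the t-like standardized
  coefficient (robust to scale), compared two-tailed by absolute value; the
  add-one convention p = (b + 1)/(n_perm + 1) keeps p in (0, 1]. The source
  analyses report signed β with two-sided interpretation but do not state the
  pivot; the t-pivot is the standard choice for semi-partialling.
- **r².** Conventional OLS r² with intercept; whether legacy matrix-analysis
  software applies a different adjustment is not verifiable, so the conventional
  definition is documented as the assumption.
- **Node-level regression** permutes the outcome vector across nodes under an
  otherwise identical OLS/pivot/p-value scheme.
- **Geary's C** uses
  `C = (n−1)·Σ w_ij (x_i−x_j)² / (2·Σ w_ij·Σ (x_i−x̄)²)` with missing weights as
  zero; weights are the raw rates by default with a binary option. C is invariant
  to affine rescaling of the attribute and positive rescaling of the weights, and
  averages 1.0 when the attribute is permuted over nodes.
- No multiple-testing correction is applied by default (matching the a-priori
  hypothesis-testing stance of the source analyses); a Bonferroni helper is
  provided but off everywhere.

Default permutation counts are 2000 (MRQAP and Geary) and 10,000 (node-level);
all results are bit-reproducible given (data, n_perm, seed).

## The synthetic generator

The generator is a planted-truth stand-in for the unobserved social process, not
a fitted model of any real community. Structure:

- **Affinity.** A symmetric latent dyadic affinity α ~ Beta(0.8, 1.5) (right-
  skewed: most dyads weak, a few strong), plus clipped Gaussian directional noise
  (scale 0.08) so proximity can be non-reciprocated.
- **Party process.** Parties are resampled once per follow (probability 0.55 per
  other individual), not per scan: fission–fusion changes are slow relative to
  the 2-minute tick, which produces realistic within-follow autocorrelation in
  party membership while follows ≥ 20 min apart stay independent.
- **Proximity.** Within 10 m given same party per scan with probability
  `expit(logit(0.58) + 12·(α_dir − ½))`.
- **Grooming.** Per scan and within-10-m partner with probability
  `(1.88/60)·α^5.5/E[α^5.5]`; at most one partner grooms per scan, with category
  drawn in proportion 0.69 : 0.53 : 0.66 (given : received : mutual) minutes/h.
- **Events.** Within each 2-minute interval, events toward each concurrent
  within-10-m neighbor arrive as a Poisson process at per-dyad rates whose
  dyad-average equals the per-category magnitudes of the observed rate table
  (e.g. greeting 0.27/h, gesture-to-give-groom 0.37/h). Affiliative categories
  scale as normalized α^5.5; the two threat categories scale with normalized rank
  distance; pant-grunts run only from lower- to higher-ranked individuals at
  twice the all-dyad mean rate over the eligible half of dyads (preserving the
  mean); pant-hoots are emitted at the node-level rate whenever at least one
  neighbor is within 10 m, with all within-10-m individuals as recipients — which
  makes every dyad's expected pant-hoot rate exactly the configured rate, at the
  cost that affinity cannot modulate pant-hoots per dyad.
- **Demography.** The shipped community is the 12-focal study group (6 males, 6
  females, ages 15–46, observation effort 500–1118 min per focal, three oestrous
  females, an alpha pair). The dominance order and the single kin pair are
  synthetic placeholders — the community's full rank order and pedigree are not
  published. Oestrus is static per dataset. All randomness flows from one root
  seed through named substreams (community / scans / events).

**Calibration.** The five shape parameters above (Beta shape, proximity base and
slope, the two skew exponents) were chosen once so that, at the shipped defaults,
the dichotomized-symmetrized mean degrees and the mean association land near the
observed community's values — proximity ≈ 97% vs 95.5%, gesture ≈ 57% vs 56%,
grooming ≈ 38% vs 36.4%, mean DA ≈ 20.6 vs 21.16 min/h (averages over 20 seeds) —
while the per-category event rates are the observed per-function means used
directly. What passing tests show is therefore that the *pipeline* recovers
planted structure under realistic magnitudes and sampling effort; they say
nothing about field-data phenomena the generator omits: spatially explicit
ranging, feeding ecology, diurnal rhythm, observer error, rank dynamics, or any
acoustic structure of calls.

## Problem sizes and runtime choices

Test and acceptance workloads run at the study's own scale (12 focals, 132
ordered dyads, ~4,500 scans, ~1,000 events per dataset). Monte-Carlo checks use
500 null replicates at 199 permutations for the MRQAP type-I rate, 200 replicates
for coefficient recovery, 100 random matrices for the bond-classification oracle,
20 seeds for generator calibration, and 2000 permutations for the Geary null
mean — sizes at which the binomial/standard-error bands quoted in the tests are
decisive.

## Known limitations

- The generator's pant-hoot channel is node-level, so per-dyad pant-hoot rate
  variation cannot be planted or recovered.
- Grooming is sampled per focal scan without enforcing consistency between the
  two partners' own follows (two focals may be recorded grooming different
  partners in overlapping real time); dyadic counts are focal-perspective, as in
  the sampling protocol, so measures are unaffected.
- `mean_degree` requires a binary matrix and intentionally rejects weighted
  input rather than silently averaging rates.
- MRQAP assumes the predictor set is full rank after listwise deletion;
  collinear predictor matrices raise an error naming the predictors rather than
  being dropped automatically.
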