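# Methods

## Data model

An EcoPlate reading is 96 optical densities (590 nm). The plate is three
replicate blocks of 32 wells (columns 1–4, 5–8, 9–12); within a block the
substrates run column-major from row A to row H starting with the water
blank, so wells A1/A5/A9 are water. Blank correction subtracts each block's
water OD from the block's substrate wells, clips negative corrected values
at 0 (an OD below blank carries no information about substrate use), and
averages the three blocks into one 31-entry profile per sample. The
clip-then-average order matters only for wells straddling the blank; it is
the common CLPP convention and keeps profiles non-negative by construction.

The analysis timepoint is configurable: `last` (default — incubation runs
to the plateau phase, so the final reading is the plateau by protocol),
`max_awcd`, or `fixed:T` with nearest-timepoint matching. A fixed-time tie
between two equidistant readings breaks toward the later one (closer to
plateau); a gap above 12 h triggers a warning.

## Conventional metrics

With responses `x_s`, total `S = Σ x_s` and proportions `p_s = x_s/S`:
AWCD `= S/31`; Shannon `H = -Σ p_s ln p_s` in nats (0·ln 0 := 0); Simpson
as the Gini–Simpson complement `D = 1 - Σ p_s²`. Both index forms were
chosen because they match the magnitudes conventionally reported for
31-substrate plates (H near ln 31 ≈ 3.43, D near 0.96). `S/AWCD` is 31 by
construction here; published tables sometimes imply other divisors, which
this package does not attempt to reverse-engineer.

## Niche segmentation

The niche range per substrate is the control replicates' min/mean/max —
sample extremes, not mean ± sd, because the model is about the observed
variation interval of the undisturbed community. At least two control
replicates are required (three or more recommended; with few replicates the
range understates the niche and expansion/contraction are overcalled).

The four segments are the piecewise-linear split documented in the README.
Two identities are enforced and property-tested: per substrate
`int + exp - nar - con = x - c` with `(int+exp)·(nar+con) = 0`, and per
sample `I_int + I_exp - I_nar - I_con = 100·(S - S_c)/S`. A control
replicate decomposed against its own range can never expand or contract.

**Index denominator.** Segment indices divide by the sample's *own* total
activity S, not the control total: this is the only denominator that
reproduces the published index rows from the published guild sums and
treatment totals (to ≤ 1 % relative error), and it reads naturally as "the
share of this community's activity that lies in this segment". Indices are
computed per replicate and then averaged (matching mean ± s.e. reporting),
not computed on treatment means.

**Functional alteration** uses the control mean total as baseline:
`FA = 100·(S - S_c)/S_c`, signed. The narrowing index is sometimes called a
restriction index; the API uses one name, `narrowing`.

## Association and dominance ranking

Guild associations rank the five guild means of one treatment × segment;
dominance–codominance ranks the 31 per-substrate treatment means. Ordering
is by descending value at full precision; exact ties fall back to the
guild's (or substrate's) summed mean across all four segments, then to
alphabetical order. Whenever values rounded to the reporting precision
(two decimals by default) cannot distinguish the pair or its order, the
result carries a tie flag — tied pairs are flagged, never silently ordered.
Pairs print with an en dash (`CH–CX`); ASCII hyphens are accepted on input.
An all-zero segment yields an empty flagged pair at substrate level and a
flagged alphabetical pair at guild level.

## Community resemblance

Two deliberately distinct measures:

- **Within**: for each replicate, the mean Czekanowski percentage
  similarity `PS(a,b) = 200·Σ min(a_s,b_s)/(Σa_s + Σb_s)` to the other
  replicates of its treatment; reported as mean ± s.e. per treatment.
- **Between**: directional coverage — for sample r of treatment t and
  another treatment u with mean profile `m_u`,
  `100·Σ min(x_rs, m_us)/Σ x_rs`, averaged over all u ≠ t and then over
  replicates. The asymmetric form is intentional: it asks how much of this
  community is present elsewhere, which is how the quantity is described.
  Whether the control counts among the "other" treatments is configurable
  (`between_include_control`, default true). Both formulas are kept behind
  their own functions so alternative definitions can be swapped in; their
  absolute values cannot be validated without raw data, only their
  qualitative ordering.

The shared-with-control profile `min(x_s, c_s)` feeds a PCA alongside the
raw profiles, the four per-segment matrices and their concatenation.

## Statistics

One-way fixed-effects ANOVA is computed from explicit between/within sums
of squares (the pooled MSE and within df are reused by the LSD test).
Letters are the unprotected Fisher LSD compact display, the agricolae-style
default: pairwise two-sided t tests at α = 0.05 on the pooled MSE, letter
classes as maximal cliques of the non-significance graph ordered by the
highest mean they contain, so two groups share a letter exactly when their
pairwise test is non-significant. A protected variant (omnibus gate) is
available. PCA is a centered SVD (scikit-learn), unscaled by default since
all variables are commensurable ODs; unit-variance scaling is an option.
Constant columns are dropped with a warning, and each axis is signed so its
largest-magnitude loading is positive, making runs deterministic.

## Synthetic experiments

The generator emulates a 5-treatment × 4-replicate fertilization trial read
at plateau. Control responses are `max(0, Normal(μ_s, σ_s))` with per-
substrate baselines `μ_s ~ Uniform(0.3, 2.5)` OD and `σ_s = 0.1·μ_s`;
treatment t multiplies every substrate of guild g by `κ_tg` before noise.
Truncation at zero (rather than a lognormal) matches the OD floor and is
negligible at these settings (μ/σ = 10). The defaults put total activity
near 43 OD per sample — the magnitude of real plateau-phase grassland
profiles — and the default κ matrix contrasts an organic treatment
(CH 1.30, CX 1.15, P 1.35, AA 1.05), a mild organo-mineral one, a mineral
treatment (CH 0.80, P 0.80, AM 0.90, CX 0.95, AA 1.05) and a high
organo-mineral one, chosen so the default functional-alteration pattern
spans roughly +19 % to −10 % across treatments.

Ground truth records each guild's direction per treatment and the guild
expected to dominate expansion/contraction (largest expected activity mass
shifted beyond the control mean, `(κ_g - 1)·Σ_g μ_s`).

What the generator does *not* emulate: kinetic color development (only the
plateau snapshot), correlation between substrates within a sample, plate-
or reader-level batch effects, and within-plate triplicate noise (profiles
are generated at the substrate level). Tests passing on this generator
therefore demonstrate correctness of the computations and recoverability of
guild-structured effects at realistic noise, not robustness to real-world
plate artifacts.

## Problem sizes and verification

The test suite checks the decomposition identity on 10⁴ random
substrate/range draws, the LSD letters against a brute-force maximal-clique
oracle on 100 random 4-group instances, PCA variance against a covariance-
eigenvalue oracle, and parameter recovery on 200 seeded two-treatment runs
with one guild's κ at 1.5 (the boosted guild must head the expansion
association in ≥ 95 % of runs); under κ ≡ 1 the mean functional alteration
over 200 runs must sit within 3 s.e. of zero. The published-table worked
examples (segment indices, functional alteration, all 16 guild pairs) are
reproduced to ≤ 1 % relative error from the printed aggregates; two
association cells tie at the printed two-decimal precision and are accepted
in either order, flagged.

## Limitations

- The niche range from 4 control replicates is a coarse min/max estimate;
  expansion and contraction magnitudes are sensitive to control outliers.
- Printed two-decimal aggregates limit how precisely the published index
  rows can be reconstructed; a few non-targeted cells differ by more than
  rounding alone explains.
- Resemblance definitions are reconstructions validated qualitatively, not
  numerically, against published values (raw data unavailable).
- No kinetic modelling, no reader-specific OD standardization, no
  inferential claims about fertilization ecology.
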