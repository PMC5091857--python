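# Methods

This note documents the models and procedures implemented in `delimkit`,
the defaults and why they were chosen, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## K2P distances (`delimkit.seqdist`)

Kimura's two-parameter model assigns one rate to transitions (A↔G, C↔T)
and another to transversions. With P and Q the observed transition and
transversion proportions over pairwise-complete sites, the distance in
expected substitutions per site is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Handling of incomplete data is *pairwise deletion*: any column with a gap
(`-`) or ambiguity (`N`) in either sequence of a pair is dropped for that
pair only, and the number of sites actually compared is stored per pair.
This is the robust choice for ragged 16S fragment alignments, where
complete deletion would discard most of the signal; `N` is treated as
missing rather than as a wildcard, the conservative reading. When the
observed proportions put either logarithm out of domain the pair is
*saturated*: it carries a flag instead of a number and is ordered after
every finite distance downstream. A pair with zero comparable sites is an
error naming the pair, never a default value.

## Barcode-gap delimitation (`delimkit.abgd`)

The procedure operationalizes barcode-gap discovery: intraspecific
distances are small, interspecific ones large, and a survey's mixture of
both shows a gap in the ranked distance distribution.

Given the ranked within-group distances `d_1 ≤ … ≤ d_m`:

1. Let `i0` be the first rank with `d_{i0} > P`, the prior intraspecific
   limit (default `P = 0.03`; the conventional 3% 16S threshold for
   Neotropical frogs). No such rank → no gap.
2. For ranks `i ≥ max(i0 - 1, 1)`, the gap `g_i = d_{i+1} - d_i` is
   compared with the mean of the `W = max(2, ⌈0.1·m⌉)` preceding gaps (the
   local spacing scale, excluding `g_i` itself).
3. The barcode gap is the first rank whose gap exceeds `X` times that
   scale (`X = 1.0` by default); the split threshold is the midpoint of
   the gap. A tiny relative slack (1e-9) keeps exactly-tied gaps — a
   constant ladder of distances — from qualifying through floating-point
   jitter.

Groups are formed by single linkage at the threshold (ids with distance
below it share a unit), which matches the verbal between/within criterion
exactly, and the procedure recurses within every group of ≥ 3 members
(a 2-member group has a single distance; no gap is definable) up to
`max_rounds = 10`. Ties are broken toward the lowest rank; the whole
procedure is deterministic and every threshold decision is recorded in a
trace. The windowed local-scale gap test is this package's normative
definition of the gap statistic; it is deliberately simple, fully
specified, and testable against brute-force split-point scans.

If the gap lies at the boundary of a saturated tail, the threshold is set
one unit above the largest finite distance, which separates the saturated
pairs without inventing a numeric distance for them.

## Single-threshold GMYC (`delimkit.gmyc`)

On an ultrametric gene tree with node heights `t_1 > … > t_{n-1}` (time
before present, tips at 0), a threshold `T` splits branching into a
between-species diversification process (events older than `T`) and
within-entity neutral coalescence (younger than `T`). The entities are the
branches crossing `T`; each carries the tips beneath it.

For each inter-event interval `i` (duration `x_i = t_i - t_{i+1}`,
`i = 1 … n-2`), every lineage present belongs to one process: branches
extending above `T` to the diversification process (`k_i` of them),
branches entirely below `T` to their entity's coalescent (`n_{i,j}`
lineages in entity `j`). The combined rate is

    b_i = λ_S · k_i^{p_S} + λ_C · Σ_j [n_{i,j}(n_{i,j} - 1)]^{p_C}

and the log-likelihood is `Σ_i (ln b_i - b_i x_i)`. The bookkeeping starts
at the root's first descendant event (the root event is conditioned on,
standard for birth-process likelihoods) and the eventless span below the
youngest node is omitted, giving exactly `n - 2` interval terms.
Zero-duration intervals (simultaneous nodes, e.g. from resolved
polytomies) contribute the event term only, the limit of the exponential
density. A vanishing rate on an interval that ends with an event yields a
flagged minimal value rather than `-inf` in arithmetic.

Choices and rationale:

- `p_S = p_C = 1` fixed by default: the model then reduces exactly to a
  Yule process above `T` and independent neutral coalescents below it, and
  small trees do not support stable exponent estimation. Estimation over
  `[0, 2]` is available (`estimate_p`).
- The likelihood is piecewise in `T` between node heights, so the scan
  over midpoints of consecutive distinct heights — plus one candidate below
  the youngest node (all singletons) and one above the root — is
  exhaustive. The above-root candidate *is* the null model (one process on
  the whole tree), so `logL_alt ≥ logL_null` and `LR ≥ 0` by construction.
- At fixed `T`, rates are maximized over `log λ` by bounded quasi-Newton
  from a moment-style start (events per unit of summed interval time) with
  two perturbed restarts; with exponents free, two starts at `p = 1` and
  `p = 0.5`.
- The likelihood-ratio test uses a χ² reference with df = 3 by default
  (threshold plus one extra rate parameter, conservatively counting the
  boundary); df is configurable, and the simulation experiments report the
  resulting empirical type-I error rather than assuming the reference is
  exact.

`upgma_tree` (average linkage on the K2P matrix, node height = merge
distance / 2) is a deliberately plain fallback for surveys without a
time-calibrated genealogy; it is exact on truly ultrametric distances but
inherits all UPGMA biases otherwise, and the pipeline warns when it is
used.

## Reconciliation and classification (`delimkit.integrate`)

Two delimitations over the same ids are reconciled per *conflict
component* (connected blocks of the join of the partitions). Within a
component the grouping with fewer units wins — "most conservative" —
unless some pair split only by the finer grouping carries a positive flag
in any of three evidence channels: morphological differentiability,
acoustic differentiability, or a prior reference delimitation (the third
channel exists because published integrative decisions sometimes rest on
earlier multi-locus work rather than on new phenotypic data). Components
where neither grouping refines the other are collapsed to a single unit
with an explicit warning in the decision log — conservatism preserved,
human review requested. Every choice is logged with the rule that fired.

Classification applies rules in order per unit, two-pass so that nominal
species exist before anything tries to attach to them:

1. **NS** — the unit contains a lineage with a nominal name.
2. **DCL** — morphology *and* acoustics both explicitly fail ("no") to
   separate the unit from some NS unit; the unit attaches to that species.
3. **CCS** — some morphological or acoustic flag positively separates the
   unit ("yes") from a comparator.
4. **UCS** — no positive flag, and either no morphological/acoustic data
   at all (all flags unknown) or no NS unit exists to anchor a DCL call.
   The second clause keeps the classification total on surveys of wholly
   unnamed faunas, where "not differentiable from a described species" is
   undefined.

Anything else raises an error carrying the unit's evidence snapshot —
silent defaults would hide exactly the cases a taxonomist must inspect.
Evidence between multi-lineage units is aggregated yes > no > unknown.

Acoustic comparison (`acoustic_differentiable`) is a range-overlap rule
over note duration (s), pulse rate (pulses/s) and fundamental frequency
(Hz): disjoint reported ranges on any diagnostic parameter → "yes"; shared
parameters all overlapping → "no"; no shared parameter → "unknown". A
relative-difference rule (midpoints differing by a configurable fraction)
is available.

Richness arithmetic counts `U = |CCS| + |UCS|` undescribed species-level
units (DCL are conspecific lineages, not species — the reading under which
the worked-example percentages reproduce exactly) and reports
`100·U/(U+D)` and `100·U/D` rounded half-up to whole percent using exact
integer arithmetic.

## The bundled case study (`delimkit.fixtures`)

The case-study CSVs encode, at one id per lineage, the published outcome
of an integrative *Scinax* delimitation: 13 distance-based and 12
tree-based focal-region units, three discordant lineage sets (two resolved
conservatively, one overridden by reference evidence), and the evidence
rows that drive the NS/CCS/UCS/DCL calls (each row carries a free-text
note naming the characters involved). Comparator lineages from outside the
study region are included because the reconciliation and several CCS calls
depend on them. Two encodings are judgment calls worth flagging: one
lineage's CCS status rests on call parameters reported only in the
original study's supplementary material, encoded here as a single acoustic
flag; and the two data-free lineages are kept UCS exactly as published
even though a morphological difference between them is mentioned in the
source prose. The fixture reproduces published *categories*; it does not
re-derive them from measurements, and the full-survey inputs (sequences,
calibrated tree) are not bundled — the 13/12 unit counts are properties of
the encoding, checked for consistency, not recomputed from data.

## Synthetic data (`delimkit.synthdata`)

The generator chains the processes the methods assume:

- **Yule species tree** — per-lineage speciation rate (default 0.2/Ma);
  the present is one further exponential waiting time after the n-th
  lineage appears, so terminal branches are positive. When
  `min_species_divergence` is set (default 5 Ma) the tree is rescaled so
  the youngest split sits exactly there.
- **Multispecies coalescent** — within each species branch, each lineage
  pair coalesces at rate `1/θ`, so two samples from one species have
  expected TMRCA `θ` (default 0.3 Ma); survivors pass to the parent
  branch. No migration or hybridization: the delimitation model assumes
  clean lineages, and θ is constant across species to match the
  single-threshold assumption of one transition depth.
- **K2P sequence evolution** — exact transition probabilities per branch
  (no per-site rate heterogeneity), root drawn uniformly, total rate
  7.35e-3 subs/site/Ma (a published 16S clock for hylid frogs), κ = 4.
- **Evidence** — independent Bernoulli differentiability flags per species
  pair (default 0.7 each channel; complement is an explicit "no") and a
  seeded fraction of named species (default 0.25).

Defaults give within-species distances around 0.4% and interspecific
distances of roughly 7% and upward — the shape of a real regional 16S
survey of congeneric frogs, with the barcode gap comfortably clear of the
3% prior. Everything is reproducible bit-for-bit from one seed via spawned
generator streams.

What the simulations do *not* emulate: alignment error, sequencing error,
rate variation among sites and lineages, gene flow, uneven sampling, and
overlapping intra/interspecific distance distributions. Passing the
recovery experiments therefore shows the implementation is correct and
well-calibrated under its own assumptions, not that the methods succeed on
hard empirical data — on real surveys the methods disagree, which is what
the reconciliation layer is for.

## Experiment sizes and determinism

The bundled experiments use 8 species × 4 samples × 550 bp (32 sequences)
for recovery runs, 20 samples for single-species nulls, 20 replicates for
barcode-gap recovery and 50 for each GMYC calibration arm — sizes at which
the replicate counts dominate runtime and results are stable across seeds
(recovery 95–100%, GMYC entity recovery ≈ 90–98%, empirical type-I error
0–6% against the 5% nominal level in spot checks). All pipeline outputs
are deterministic given inputs and seed; reports are JSON with sorted
keys, and the text summary is derived from the JSON so every printed
number is traceable.

## Known limitations

- The gap statistic is a normative simplification of barcode-gap
  discovery; it preserves the published inputs (prior `P`, relative width
  `X`, recursion) but is not a byte-level reimplementation of any web
  service, and no theta-informed intraspecific model is used.
- The GMYC degrees of freedom are a convention; boundary effects make the
  χ² reference conservative, which the type-I experiment quantifies.
- Classification consumes evidence as three-valued flags; it does not
  compute morphological diagnosability from measurements, and the
  range-overlap call rule ignores sample sizes.
- Units of fewer than 3 sequences are never re-split by recursion, so
  late-round oversplitting is impossible but a true split hidden inside a
  pair is invisible by construction.
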