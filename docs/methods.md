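# Methods

This note documents the models, parameter choices, and numerical
decisions behind `exoflux`, and what the synthetic test bed does and
does not demonstrate.

## Model and units

All computation happens on a constraint-based stoichiometric model:
metabolites × reactions matrix S, flux vector v with
S·v = 0 and lb ≤ v ≤ ub, fluxes in mmol per gram dry weight per hour.
The biomass pseudo-reaction's flux is the growth rate (1/h).  Exchange
reactions are single-metabolite boundary reactions in the extracellular
compartment, written `met[e] ⇌ ∅`; negative flux is uptake, positive is
secretion.  Every bound is capped to ±500 mmol/gDW/h on model load.
The cap is applied to *all* bounds, not only the conventional ±1000
"infinite" markers: loop detection (below) relies on ±500 being the
recognizable "unbounded" value, and a finite bound above 500 is
physiologically indistinguishable from unbounded at this scale.

The in-memory container is `cobra.Model`; FBA and FVA are solved with
GLPK through cobrapy.  FVA always runs with the full constraint set
active — including any enforced biomass minimum — so "unable to carry
flux" means unable anywhere in the data-constrained polytope.  Solver
feasibility tolerance is left at the backend default; all post-hoc
feasibility checks use 1e−6 on |S·v| and on bound violations.

GPR rules are boolean expressions over gene ids with case-insensitive
`and` (complex subunits) / `or` (isozymes) and arbitrary nesting; an
empty rule is vacuously satisfied.  Malformed rules raise a parse error
rather than degrading to an always-true rule.

## From spent medium to exchange bounds

Cell dry weight is scaled by volume from a reference cell:
`dry_weight = ref_mass / (ref_volume / cell_volume)`.  With the
defaults (60 pg, 4000 µm³ reference; 243 µm³ lymphoblast) this gives
3.645 pg/cell.

Concentrations convert to fluxes as

    Flux = MetConc / (CellConc × CellWeight × T × volume_factor)

with `CellConc` in cells/mL, `CellWeight` in g, `T` in h, and
`volume_factor = 1000` converting per-mL cell concentration to per-L so
the units cancel to mmol/gDW/h.  The factor is exposed as a
`CultureParams` field because the dimensional analysis is the only
thing fixing it; the shipped default is the dimensionally consistent
form.

**Classification.**  Evidence for uptake/secretion is a change of the
cell-line profile exceeding 5 % of what the cell-free control shows.
The comparison arithmetic is `FC_cell / FC_control − 1` by default,
with a plain difference of percent changes available behind
`change_mode`; the two coincide whenever the control is drift-free.
Signals below the MS detection limit are floored at it (with a logged
warning) before any fold change is formed, so noise can never produce
zero or negative fold changes.  Metabolites without a model exchange,
compounds human cells cannot produce (riboflavin, trehalose, …), and
GlutaMax breakdown products (glutamine, alanine — their extracellular
accumulation reflects spontaneous dipeptide hydrolysis, not cellular
secretion) are excluded; GlutaMax artifacts keep unconstrained
exchanges.

**Qualitative bounds.**  Uptake: lb = −flux(medium concentration),
ub = −flux(detection limit) — the detection limit *enforces* the
observed uptake direction.  Secretion: lb = +flux(detection limit),
ub = +500.  Unmeasured and unchanged exchanges close to (0, 0) except
the whitelist (ions, gases, basic medium compounds, essential amino
acids, cysteine), which keeps lb at −flux(medium) when a medium value
exists and −500 otherwise.  Biomass is boxed to growth_rate × (1 ∓ 0.2)
and the oxygen exchange lower bound is fixed at −2.346 mmol/gDW/h.
The detection-limit upper bound is applied uniformly to every uptaken
metabolite; applying it only to a subset would need information the
data tables do not carry.

**Quantitative bounds.**  For metabolites commonly uptaken or commonly
secreted by both conditions, per-series fold changes give
`Slope = FC_cellline / FC_medium` and the ratio r = slope_A/slope_B.
For secretion the stronger secretor has the larger slope; for uptake
the stronger consumer has the *smaller* slope (its signal drops
further), so the roles are assigned from the slope ordering and the
bound factor is x = max(r, 1/r) ≥ 1.  The stronger exchanger keeps its
qualitative bound; the weaker consumer's supply is shrunk to
|lb|/x, or the stronger secretor's minimum raised to x·lb.  Scaling
one model while anchoring the other (rather than moving both
symmetrically) keeps every adjusted bound inside its qualitative
envelope.  Phosphate, histidine, cysteine, valine, methionine,
alanine, and glutamine are never adjusted (skip list): their signals
are inconclusive or their uptake essential.

## Contextualization

Order is fixed: exo-metabolomic bounds first, then absent-gene
deletion, then pruning.  A reaction is shut when its GPR is
unsatisfiable with the absent genes false and all others true; an
isozyme rescues, a missing mandatory complex subunit disables.  If the
enforced minima become unsatisfiable, the consistency checker reports a
minimal relaxation set (each enforced exchange relaxed singly; greedy
accumulation as fallback) instead of silently re-enabling genes — the
failure is surfaced to the user.  Pruning removes every reaction whose
FVA range lies within ±1e−6 of zero (tolerance configurable), then
orphan metabolites and genes; it is idempotent and cannot remove the
biomass reaction or an enforced-minimum exchange.

## ACHR sampling

Warm-up points are LP vertices: the 2n per-reaction min/max optima
first, then optima of standard-normal random objectives up to
`n_warmup`.  The chain keeps a running center (mean of warm-up plus all
stored points), draws a previously seen point, takes the normalized
direction from the center through it, computes the feasible step
segment from the box bounds (directions live in the null space of S by
construction), and steps uniformly within it.  Every
`steps_per_point`-th iterate is stored; points are re-projected onto
the null space of S every 100 steps to stop round-off drift, and every
stored point is checked against |S·v| < 1e−6 and the bounds before it
is kept.  A fixed seed yields bit-identical output; a zero-dimensional
polytope yields its single point repeated.

Two presets exist: `paper` (10,000 warm-up points, 100 files × 5,000
points, 2,500 steps per point) matches the published cluster-scale
settings and is intended for genome-scale models; `desk` (200 warm-up
points, 4 × 250 points, 100 steps per point) is the package's own
choice for toy networks, where the polytope has a handful of free
dimensions and the heavy thinning of the paper preset buys nothing.
`burn_in_files` (default 0) optionally discards leading chunks.

Per-reaction medians summarize the sample; signs are preserved, so a
negative median means net reverse flux.

## Comparison and concordance

Shared reactions partition into x (more utilized by A), y (more
utilized by B), and z.  "Differently utilized" means the medians differ
by more than 10 % — the denominator of that percentage is the single
most consequential unstated choice in this workflow.  The default is
max(|m_A|, |m_B|) (symmetric and scale-free); `baseline_B` and `mean`
are available behind `denominator`.  Opposite-sign median pairs,
near-zero pairs (both |m| < 1e−9), and loop reactions are forced to z.
Loop reactions are those whose FVA range spans the full ±500 cap in
both directions — internal cycles whose sampled values carry no
information.  The partition is antisymmetric under swapping the models
and invariant under common positive rescaling of both median vectors.

DEG concordance is computed at two levels over shared non-loop
reactions: reaction-level (what fraction of reactions associated with
up/down genes fall in x/y/z, where association is any appearance of the
gene in a reaction's GPR) and gene-level (what fraction of up genes
have a strict majority of their classified reactions in x, and down
genes in y; ties count as misses).  Empty denominators report `None`,
never a division error.

## Gene deletion

A knockout shuts the reactions whose GPR fails without the gene.  By
default the biomass lower bound is relaxed to 0 before testing and a
gene is lethal when the knocked-out maximum growth falls below
1e−6 h⁻¹; this separates "cannot grow at all" from "cannot meet the
enforced minimum".  The stricter mode (`keep_biomass_minimum=True`,
lethality = infeasibility) is available because contextualized models
carry growth minima and either reading of lethality is defensible.
Lethal sets of two models are compared as shared / unique-to-A /
unique-to-B, with genes absent from the other model flagged separately.

## Synthetic test bed

The toy network is a parametric caricature of central carbon
metabolism: glucose-like exchange and transporter (an `or` isozyme
pair), a linear glycolysis-like chain ending in `2 pyruvate + 2 ATP`, a
lactate-like overflow branch, a pyruvate-dehydrogenase-like `and`
complex releasing CO₂ and NADH, a TCA-like cycle producing NADH, an
ETC-like chain consuming NADH and oxygen to make ATP (its first complex
carries a designated mandatory subunit so a single absent gene disables
it), a biomass drain consuming ATP, pyruvate, and phosphate, an ATP
maintenance drain, and configurable dead-end reactions.  Reaction and
metabolite counts are closed-form functions of the segment sizes.

The default two-condition truth makes condition A glycolytic (glucose
uptake −12, lactate secretion +16 mmol/gDW/h) and condition B half as
glycolytic (−6, +4), with culture parameters at the package defaults
(2.17 × 10⁶ cells/mL, 48 h, 3.645 pg dry weight, growth rates
0.035/0.032 h⁻¹).  Signals are emitted in mM with unit scale 1 by
inverting the flux conversion (`t1 = t0 + flux·K`), so the zero-noise
round trip is exact; the noise model is additive Gaussian on the final
signal, an intentionally minimal stand-in for MS measurement error.

What passing tests show: the constraint arithmetic, classification,
slope-ratio logic, pruning, sampler, grouping, and screen are mutually
consistent and recover constructed ground truth exactly when noise is
zero, and the sampler's marginals match uniform rejection sampling on
low-dimensional polytopes.  What they do not show: behavior on
genome-scale reconstructions (thousands of reactions, extensive loops,
degenerate GPRs), real MS signal distributions, or microarray-derived
call quality.  Published genome-scale figures (group sizes of order
10³, ~220 loop reactions, 63 shared lethal genes) require the full
reconstruction plus the original data sets and are outside the desk
scale of this package's test bed.

## Problem sizes and determinism

Tests and the acceptance script run the desk sampler preset on toy
networks of ~25 reactions (oracle sweeps use up to 40), sizes at which
every LP and the ACHR chain complete in seconds while still exercising
isozymes, complexes, dead ends, and enforced minima.  All randomness —
toy generation, simulated tables, warm-up objectives, and the ACHR
chain — flows from explicit integer seeds; LP results are
deterministic given the solver, with cross-call agreement asserted at
1e−9 (GLPK warm starts can shift optima at the 1e−13 level).
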