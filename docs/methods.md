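# Methods

## Model overview

`vlobule` is a discrete-time (1 second per step), discrete-object,
stochastic simulation of APAP disposition and hepatotoxicity in a single
hepatic lobule coupled to a lumped extrahepatic compartment. Every event —
absorption, flow, binding, uptake, metabolism, glutathione depletion,
damage formation, amplification, mitigation, death triggering — is an
independent Bernoulli trial per object per step. On integer counters these
trials are realized as binomial (or multinomial) draws, which is exactly
equivalent distributionally and lets a 14,000-cell lobule advance in a few
vectorized draws per step. The test suite verifies this equivalence by
chi-squared comparison against a literal per-object Bernoulli simulator.

All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning: each Monte Carlo trial receives an
independent child stream, so an experiment is bit-reproducible from
(protocol, mechanism, master seed) and trials are order-independent.

## Lobule geometry and the dPP coordinate

The lobule is a directed graph of 68 sinusoid segments — 45 in Zone 1
(periportal), 20 in Zone 2, 3 in Zone 3 (pericentral) — wired by exactly
99 edges: 55 Z1→Z2, 10 within Z1, 24 Z2→Z3, 10 within Z2, none within
Z3. Within-zone edges follow a random linear order and therefore cannot
form cycles; the cross-zone wiring guarantees every segment lies on at
least one PP→CV path. Segment lengths and circumferences are drawn
uniformly per zone for every Monte Carlo variant; the hepatocyte census is
fixed (9,310/3,948/742; cells apportioned to segments proportional to
length with largest-remainder rounding, so zone totals are exact for every
seed).

A hepatocyte's lobular position is the scalar path length

    dPP = x + sum over upstream zones of (mean segment length of that zone)

where `x` is its 0-based offset along its own segment. `d_max` is the sum
of the three zone means (the mean total PP→CV path length); a cell in an
unusually long Zone-3 segment can sit numerically past `d_max` and is
treated as at the CV (distance 0, gradients evaluated at the CV endpoint).

Default per-zone mean lengths are 23/13/14 grid spaces (`d_max` = 50,
uniform ±~20% ranges). Zone 1 is long enough that "near PP" (> 30 grid
spaces from the CV) is always a Zone-1 location. Zone 3 is relatively
long because its three segments represent the converged pericentral
channels every flow path shares; its mean length also defines the
pericentral distance band used by the trigger-location phenomenon check.
These shares are free configuration (no reference dimensions exist) and
were fixed during the calibration described below.

## Zonation gradients and calibration

A gradient is (shape, value at PP, value at CV), with shape constant,
linear, or reverse sigmoid (inflection and steepness; evaluated with a
numerically safe logistic). Calibration of a free endpoint or steepness to
a prescribed population mean uses Brent root finding over the canonical
census population — the deterministic dPP multiset obtained from the
configured zone means with cells spread evenly over each zone's columns —
to |mean − target| ≤ 1e-6, verified independently by brute-force
averaging in the tests.

Mechanism presets:

* NZ: metabolism linear 0.35→0.95, NAPQI fraction linear 0.33→0.90,
  GSH depletion threshold constant 3.5, mitoD mitigation constant 0.67.
* GNZ: threshold linear with 5 at the entrance, CV endpoint solved so the
  census mean remains 3.5 (≈ 1.13 at the CV).
* MNZ: mitigation reverse sigmoid 0.9→0, inflection mid-Zone-2
  (dPP = 29.5), steepness solved so the census mean remains 0.67.
* MGNZ: both zonations.

The constant values 3.5 and 0.67 used by the location-independent
mechanisms are, by construction, the census means of their zonated
counterparts, so whole-lobule comparisons across mechanisms are matched.

## Cell cascade semantics

Each step, the five cascade phases (metabolism, NAPQI fate, amplification,
mitigation, trigger check) execute in a pseudo-random order drawn once per
lobule per step and applied to all cells. A per-cell order would cost a
~5× slowdown in the vectorized engine; aggregate per-step statistics are
indistinguishable, because phases interact only through shared counters.

Details that the prose description leaves open were resolved as follows:

* The GSH depletion threshold is compared as `cumulative depletion events
  ≥ threshold` (thresholds such as 3.5 are meaningful on the integer
  counter; 4 events crosses 3.5).
* Amplification "uniform (1, 6)" is discrete uniform on {1,…,6}; each
  mitoD is amplified exactly once (at its next pass through the
  amplification phase), so one NAPQI yields at most 7 mitoD.
* A triggered cell stops metabolizing APAP immediately; all other damage
  dynamics continue until the death time, after which the cell is inert.
* Death delay is uniform [1.2, 12] h by default; the alternative normal
  rule (mean 7.2 h, SD 4.1 h) is available and floored at zero.
* nonMD never contributes to the death trigger; it accumulates and is
  mitigated only.

## Transport

Intragastric/intraperitoneal doses enter a depot absorbed first order
(k_abs = 1e-3 s⁻¹: "rapid", > 97% in an hour); intravenous doses start in
the body pool. Each second a fixed fraction (hepatic_fraction = 1e-4 s⁻¹)
of body APAP is metered to the PP entrance columns proportional to
segment circumference — the analog of hepatic blood flow for a lobule
that maps to a small sample of all lobular flow paths.

Percolation is column-resolved along each segment (1-D axial; the
circumference enters via hepatocyte counts and inflow apportioning).
Per step and per free object: endothelial binding (p = 0.1) and release
(p = 0.5); hepatocyte uptake; forward advance with probability 0.9;
uniform routing over outlet edges at segment ends; Zone-3 outflow returns
to the body (recirculation). Two transport features matter scientifically:

* **Flow-convergence scaling.** All flow converges from 45 Zone-1 onto 3
  Zone-3 segments, so pericentral linear velocity is higher and the
  per-column capture opportunity lower. Per-column uptake is scaled by
  (flux multiplier)^−α with α = 0.6 and flux multiplier 1 / 2.25 / 15 in
  Zones 1/2/3. This sets the per-cell exposure gradient: steep enough
  that pericentral cells see several-fold more APAP per cell, shallow
  enough that the periportal majority participates — the regime in which
  NAPQI zonation alone demonstrably cannot localize injury.
* **Necrotic sequestration.** Cells past the death trigger no longer
  release APAP and take it up with a 25× multiplier (membrane integrity is
  lost; the analog of covalent-adduct accumulation in necrotic
  centrilobular tissue). The necrotic region therefore becomes a sink that
  progressively stalls hepatic clearance after pericentral death — which
  both caps the cumulative NAPQI dose fraction at 24 h and shields
  surviving periportal cells from slow late poisoning.

Living cells release unmetabolized APAP back to their column at
0.1 s⁻¹, so with metabolism disabled every dosed object is eventually
recovered at the CV (verified exactly). Mass balance is exact and integer
at every audited step: depot + body + intralobular (free, bound,
intracellular, CV buffer) + cumulative NAPQI + cumulative G&S equals the
dose; the marker total is separately conserved and the marker count inside
any cell is identically zero.

## Calibration of free parameters

Only gradient endpoints, the probabilities 0.5, the thresholds (5 → mean
3.5; trigger 6), the delay rule, the extraction-ratio band, the NAPQI
dose-fraction range, and the dose rules are prescribed by the reference
description. Everything else — uptake probability, flow scaling, dose
scale, metering rate, sequestration multiplier, zone length shares — was
calibrated once, in the spirit of the iterative refinement protocol the
model family uses, against the prescribed performance targets in this
order, and then frozen:

1. p_uptake = 0.024: single-pass extraction ratio 0.60 (target 0.6 ± 0.06;
   measured spread across lobule seeds ≈ ±0.01).
2. Dose scale 1,000 objects/(mg/kg): the toxic reference dose
   (300 mg/kg → 300,000 objects, ~21/hepatocyte) places periportal
   lifetime NAPQI exposure near the threshold scale while pericentral
   cells pass both thresholds — the regime with both dose-responsiveness
   and zonated injury.
3. hepatic_fraction = 1e-4 s⁻¹ and necrotic_uptake_scale = 25: 24-h NAPQI
   dose fraction 0.34 (target 0.15–0.4), ~52% reduction in 24-h deaths at
   half dose (target ~50%), earliest death ≈ 1.6 h (must be ≥ 1.2 h),
   deaths plateau by ~12 h.
4. Zone length shares 23/13/14 and α = 0.6: the four-way mechanism
   discrimination below.

## The Target-Phenomenon check

For each mechanism, death-trigger events from 12 Monte Carlo lobule
variants are pooled; the per-second mean distance-from-CV of triggers is
smoothed with a centered 100-second event-weighted moving average. The
mechanism *achieves* the phenomenon when, after a 1,200 s settling period,
the smoothed series lies within the pericentral band (distance ≤ the
pooled mean Zone-3 path length, ≈ 14 grid spaces) for ≥ 95% of
event-bearing time points.

The evaluation window is the early-injury period, 3,900 s (65 min): real
centrilobular necrosis *begins* pericentrally and then spreads outward, so
trigger locations are expected to leave the pericentral band later — by
24 h deaths occur in all three regions under every mechanism. Judged over
this window with default presets, MGNZ achieves the phenomenon
(occupancy 0.99–1.0 across master seeds) while NZ (≤ 0.07), MNZ (≤ 0.19)
and GNZ (≤ 0.67) do not: the GSH-threshold zonation is needed to start
pericentral damage early and densely, and the mitigation zonation to
suppress mid-zonal and periportal triggers — neither alone suffices. The
NZ series additionally shows its characteristic signature: an early
closest approach to the CV followed by sustained drift toward PP, driven
by the sheer number of periportal cells experiencing occasional early
triggers. At the calibrated absorption and metering rates this drift is
established within the first hour; the brief pre-reversal dip is
compressed into the sparse first minutes of trigger activity.

## What the simulations do and do not show

The generator *is* the study system here — there is no external data
path. Passing tests show internal consistency (conservation, kernel
distributional correctness, calibration), agreement with the prescribed
quantitative targets, and that the mechanism discrimination is a robust
property of the model at its frozen configuration. They do not show that
the frozen configuration is unique (other parameter sets may discriminate
equally well or differently), nor anything about real livers beyond the
analogy the model family is built on. Simulated-time scales (e.g. the
~hour-scale trigger window) depend on the calibrated transport rates and
should be read as model time, not mouse time.

## Problem sizes and numerical choices

Default experiments use 12 Monte Carlo lobule variants; the regional
time-course experiment supports the full 332-variant design, and the
variant sweep reports per-zone deaths with a ±20% indistinguishability
band around the MGNZ reference. The acceptance script uses 6 paired
full/half-dose 24-h trials for the dose-response and 3 of the full-dose
trials for the NAPQI fraction and death timing; a 24-h trial runs in
roughly half a minute. Perfusion stabilization is declared when two
consecutive 300-s windowed means of outflow agree within 2% relative;
extraction is then measured over the remaining steps. Calibration
tolerances are 1e-6 on population means; conservation checks are exact
integer equalities, not tolerances.

## Known limitations

* The sinusoid interior is collapsed to per-segment/per-column counts; no
  2-D grid, no bile network, no endothelial CYP2E1/GSH, no induction or
  regeneration dynamics.
* No extrahepatic elimination; disposition ends in metabolites or the
  necrotic sink, so late plasma decay is governed by the sink rather than
  renal clearance.
* GSH is implicit (a depletion-event counter with a threshold), with no
  resynthesis.
* The per-step shared shuffle (rather than per-cell orders) and the
  uniform assignment of uptaken objects within a column are vectorization
  compromises; both are distributionally faithful at the population level
  but not per-cell-trajectory faithful.
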