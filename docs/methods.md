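# Methods

This note documents the models, conventions and numerical choices behind
each `mitofibre` module, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Coordinates and deletion geometry (`mtgenome`)

All positions are 1-based inclusive on the circular rCRS
(NC_012920.1, 16,569 bp). A deletion is recorded by `bp5`, the last
retained base on the 5′ side, and `bp3`, the first retained base on the
3′ side; the removed bases form the open interval (bp5, bp3) and the
size is `bp3 − bp5 − 1`. This convention is fixed by the bundled
breakpoint table, whose printed sizes satisfy it exactly for all 30
rows. Origin-wrapping deletions (`bp5 > bp3`) are rejected rather than
normalised — none occur in the bundled data, and silently renumbering
them would invite sign errors.

A feature is *fully removed* iff its whole span lies inside the open
interval, *partially removed* iff it overlaps without containment; the
control region is the only feature allowed to wrap the origin of the
numbering (16024–576). The minor arc is taken as the gap between the
control-region 3′ end and the O_L start; its overlap is reported as a
flag only. For the expected triplex class, partial removal of MT-ND1 or
MT-ND4 counts as removed: the assay's probes sit inside the genes,
their exact coordinates are not part of the bundled data, and most
breakpoints truncate genes rather than excise them cleanly.

The default feature map carries the standard rCRS gene annotation
(protein genes, rRNAs, O_L, control region). Maps are interchanged
either as a 1-based 4-column table (documented as non-standard BED) or
as strict 0-based half-open BED, with origin-wrapping features split
into two segments on write and re-merged on read.

## Immunofluorescence densitometry (`ifquant`)

Per-fibre optical densities for porin (mass), NDUFB8 (CI) and COX-I
(CIV) are background-corrected by subtracting the per-channel mean of a
no-primary-control section, clipped at 0. Each respiratory-chain
channel is regressed on porin over control fibres (ordinary least
squares, ≥3 controls, non-degenerate porin variance); a fibre's channel
z-score is its residual from that regression divided by the control
residual SD, and its porin z-score is the plain standardisation against
control porin. Regression is in linear OD by default; a log₁₀-OD switch
exists because densitometry pipelines differ on this point and the
choice is not decidable from the data formats alone.

Classification thresholds (all configurable, defaults on the z scale):

| quantity | boundaries | default meaning |
|---|---|---|
| channel level | −3 / −4.5 / −6 | normal / intermediate(+) / intermediate(−) / deficient |
| CI−/CIV− call | z < −3 | channel counts as deficient in the MRC class |
| mass bands | −3 / −2 / +2 / +3 | very_low / low / normal / high / very_high |
| RRF | z_porin > 2.5 (strict) | ragged-red fibre |

Cohort summaries report contingency counts with percentages rounded to
one decimal; empty categories are reported as 0 so tables have a fixed
shape.

## Triplex qPCR (`triplex`)

A standard curve Cq = b + m·log₁₀(copies) is fitted per target to a
plasmid dilution series (≥2 distinct levels); efficiency is
E = 10^(−1/m) − 1 and quantification inverts the curve. Replicates are
aggregated by median with a QC flag when the range exceeds 0.5 cycles —
the median is robust to a single stochastic late-amplification outlier,
which is the dominant failure mode in triplicate qPCR.

The deletion metrics are (1 − ND4/ND1)·100, (1 − ND1/Dloop)·100 and
(1 − ND4/Dloop)·100. Because the control region can carry a third (7S)
DNA strand, the D-loop target over-counts molecules by up to 1.5×, so a
deletion-free fibre can show up to 33% apparent deletion of a coding
target relative to the D-loop; only values strictly above 33 indicate a
real deletion, and the class (none / ND4_deleted / ND1_deleted / both)
is derived from the two D-loop-relative metrics. Metrics are not
clipped: small negative values are legitimate measurement noise and
feed classification as-is. Copy-number comparisons across
respiratory-chain classes are exposed as median/quartile tables; any
rank test on top of them is a one-line scipy call left to the caller.

## Junction repeats (`breakpoints`)

A junction repeat is the longest k with the last k bases of the
retained 5′ flank equal to the first k bases of the retained 3′ flank;
calls shorter than 3 bp are classed "no repeat". Only perfect repeats
are considered — the bundled data report no imperfect ones, and scoring
degenerate homology would need a model the data cannot constrain. Flank
parsing uppercases and rejects non-ACGT characters with the offending
position named. Note the bundled table's own annotations mark only
repeats of 4 bp and longer; four of its "no repeat" rows carry a 3 bp
junction affix, which the finder reports rather than suppresses, and
`repeat_count_summary` gives tallies at both the ≥2 and ≥3 bp cuts
side by side.

## Limiting-dilution smPCR (`smpcr`)

With molecules per well Poisson(λ), the positive-well fraction p gives
λ = −ln(1 − p); a saturated plate leaves λ unbounded and is rejected
with advice to dilute. Confidence intervals transform a 95% Wilson
interval on p (Wilson rather than Wald because well counts are small
and p is near the 0.25 operating point). The dilution factor to a
target positive fraction is −ln(1 − p_target)/λ, and the co-occupancy
risk P(≥2 | positive) = (1 − (1+λ)e^(−λ))/(1 − e^(−λ)) quantifies how
"single-molecule" a plate really is (≈0.14 at the 1-in-4 point).

Species proportions are raw positive-well fractions, matching the
protocol's stated procedure; an optional corrected estimator inverts
the co-occupancy model in closed form under the size-bias assumption
(a co-occupied well is labelled by its largest deletion) for
sensitivity analysis. The "largest deletion most prevalent" statistic
counts, among cells with ≥2 species, those whose largest deletion has
the strictly highest proportion; ties in top proportion or size count
as "not strictly prevalent" and are reported separately. Input rows
whose proportions do not sum to 1 (beyond ±0.02) or with tied sizes are
flagged, never renormalised.

## Clonal-expansion simulator (`clonalsim`)

Neither competing hypothesis for clonal expansion comes with specified
dynamics, so the simulator commits to the simplest stochastic model
that expresses both: a Moran process. Each cell holds exactly N mtDNA
molecules; per event one molecule chosen uniformly is degraded and one
chosen with probability ∝ count_i·w_i is replicated, both drawn from
the same pre-event state (the standard simultaneous Moran convention).
The replication weight is w_i = (L_wt/L_i)^α with L_wt = 16.6 kb: α = 0
is exact neutrality (random genetic drift), α = 1 makes replication
rate inversely proportional to genome length (the naive
replication-time argument), larger α sharpens the advantage. Fixed N is
justified by the absence of copy-number depletion in deficient fibres;
de novo deletion formation is off by default (cells start with their
species already present, matching endpoint observations) behind an
exploratory per-replication formation probability. Time is measured in
Moran events; no calendar calibration is attempted because none is
available.

The summary statistic mirrors the smPCR readout: among cells where ≥2
species survive, the fraction in which the smallest genome is strictly
most prevalent. Wild type is excluded from that comparison by default
(the smPCR assay sees only deleted molecules); a switch includes it.
`compare_to_observed` evaluates an observed numerator/denominator
against the simulated fraction with an exact two-sided binomial
probability — no asymptotics, since observed denominators are ~10.

Cohorts are simulated with the event loop vectorised across cells
(identical kernel to the single-cell step; the tests check both against
the exactly enumerated one-step transition probabilities at small N).
Trajectories are bitwise-reproducible given the seed.

## Synthetic data (`synthdata`)

Every generator is a pure function of (config, seed) and emits ground
truth alongside the observable tables. What they emulate:

* **IF cohorts** — control ODs on a linear porin regression with
  Gaussian residuals (defaults: porin 1.0 ± 0.15 OD, residual SD 0.05);
  patient fibres drawn from a mixture (35% deletion-free, affected
  levels h ~ Beta(4, 1.5)) with a thresholded linear deficiency link
  z-shift = −18·max(0, h − 0.45), the simplest shape consistent with
  threshold behaviour, with COX-I shifting only 0.15 above the CI
  threshold so both observed deficiency groups (CI− only, CI−CIV−)
  arise; 6% of high-level fibres get a porin z of +3.5 (RRF
  hyperproliferation). Per-fibre measurement noise is 0.5 z units —
  replicate densitometry error well below the control scatter that
  defines the z unit — which is what makes the generator's documented
  margin property hold (fibres planted ≥1 z-unit from a class boundary
  classify correctly ≥95% of the time).
* **Triplex plates** — template copies from the molecule-count model
  (total copies log-normal around 10⁴; ND1/ND4 reduced by the planted
  deletion fractions; D-loop inflated by 1 + 0.5·(7S fraction)), Cq from
  the configured curve plus Gaussian noise (0.2 cycles) in triplicate.
  Standard-series noise is separately configurable because it is shared
  by the whole plate: it shifts all fibres together, so recovery checks
  that assume independent per-fibre errors calibrate noise-free.
* **smPCR plates** — Poisson(λ = 0.25) molecules per well, multinomial
  identities, positive wells labelled by the smallest co-occupying
  genome (PCR favours short templates). At the operating point this
  size bias moves proportions by at most the co-occupancy risk (~14%)
  times the species fraction; the corrected estimator quantifies it.
* **Deletion sets** — a random circular reference with deletions placed
  so flank windows are disjoint; a configured fraction is
  repeat-mediated by writing an aperiodic k-mer at both junctions, so
  the finder must recover exactly k (aperiodicity precludes chance
  extension).

What they do **not** emulate: real patients' heteroplasmy
distributions, spatial fibre structure, inter-patient heterogeneity,
probe-sequence effects, or PCR chemistry failure modes. A pipeline
passing on synthetic data therefore demonstrates correctness of the
estimators under their stated observation models, not performance on
any particular biopsy.

## Numerical and policy choices

* Percentages in summaries are rounded to one decimal place at the
  reporting boundary only; internal arithmetic is double precision.
* The 33% triplex threshold, 2.5 RRF cut, 3 bp repeat rule, 0.25 smPCR
  target and all z boundaries are constants with configuration
  overrides; defaults follow the published protocol values.
* Classification uses strict inequalities exactly where the protocol
  states them (RRF z > 2.5; deletion metrics > 33).
* Validation errors name the offending row/column/position; bundled
  tables are verified by SHA-256 checksum and shape before use.
* Reference tables ship inside the package; anomalies in them
  (proportions summing to 1.36, a per-row prevalence call contradicted
  by its own proportions, "no repeat" rows carrying a 3 bp affix) are
  preserved verbatim and surfaced by flags, never corrected in place.

## Problem sizes

Defaults were chosen so the full test suite, including the stochastic
properties, completes in well under a minute on one CPU: cohorts of
400–1,000 fibres, 50 plates of 96 wells, Moran cohorts of 1,000–2,000
cells at N = 100–200 molecules and 500–4,000 events, and 10⁴ random
flank pairs against the brute-force oracle. These sizes put Monte-Carlo
standard errors an order of magnitude below the tested tolerances.

## Known limitations

* Breakpoints are inputs; the package does not call them from reads.
* No imperfect-repeat or homology scoring at junctions.
* The Poisson correction assumes strict smallest-genome labelling of
  co-occupied wells; real PCR bias is graded, so the raw and corrected
  estimators bracket, rather than pin down, the truth.
* The Moran model has no spatial structure (no perinuclear-niche
  dynamics) and conserves N exactly; α is a phenomenological exponent,
  not a measured replication-rate ratio.
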