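# Methods

## Titration models

Chemical-shift titration curves are the base-10 Henderson–Hasselbalch
fast-exchange forms: the observed shift is the population-weighted average
of the limiting shifts of the protonation states, giving a sigmoid with
midpoint pKa for one ionization and a double sigmoid for two. pH is
treated as an opaque axis — values are taken as direct meter readings and
no solvent-isotope correction is ever applied, so pKa values are on
whatever scale the meter was read on.

All 10^x terms are evaluated in exponent-shifted (softmax/logistic) form,
so curves and microstate populations stay finite for |pH − pKa| up to
hundreds of units; the microstate fractions sum to 1 to ~1e−15 by
construction.

Two-pKa parameter sets are canonicalized to pKa1 ≤ pKa2 at construction
(the functional form is symmetric under swapping the labels), which
removes a fit-degeneracy ambiguity.

## Coupled two-site model

Two interacting ionizable groups are modelled by explicit enumeration of
the four protonation microstates, parameterized by four microscopic pKas
subject to thermodynamic cycle closure (enforced to 1e−9; a constructor
accepts three constants and derives the fourth). Macroscopic constants
follow from the partition function: Ka1 = K_A + K_B,
Ka2 = K_A·K_B|A/(K_A+K_B). The inverse map is exact given one extra
observable — the fraction r = K_B/(K_A+K_B) of the first macroscopic
transition carried by site B, which is the relative height of the first
step in a site-B reporter's double sigmoid. `microscopic_pair_from_fit`
uses the fitted intermediate plateau as r̂ and inverts; this is how
simulated coupled-site data are reported on the microscopic scale (for a
symmetric pair the conversion is just the statistical factor log₁₀2 on
each side).

The identity "microstate-derived site curve ≡ two-pKa closed form with
macroscopic constants and plateau r" holds analytically; the test suite
verifies it numerically to 1e−9 over pH 0–14 for random models, and it
serves as the module's core correctness oracle.

## Fitting

Unweighted least squares (no per-point uncertainties exist for this kind
of data), Levenberg–Marquardt via lmfit. Double sigmoids have local
minima, so every fit is multi-started: pKa starts on the grid {4,…,12}
(all pairs with separation ≥ 0.5 for the two-pKa model), limiting shifts
initialized from the first/last observed points and the intermediate
plateau from their midpoint. The two-pKa model is parameterized as
(pKa1, Δ ≥ 0) so the ordering constraint is structural. Multi-start stops
early once a numerically perfect fit is found (residual sum of squares
below a relative floor), which makes noise-free fits cheap.

Per-fit uncertainties are asymptotic standard errors from the Jacobian at
the optimum, but the headline uncertainty of a residue's pKa is the
cross-resonance sample SD (mean ± SD (n) over ≥ 1 resonances), with lower
transitions averaged with lower and upper with upper.

Degenerate-input handling:

- series with fewer than 6 (one-pKa) / 8 (two-pKa) points are rejected;
- a series whose amplitude is below 6× a robust noise estimate (median
  absolute second difference scaled by 1.4826/√6) raises "no titration
  detected" — the expected range of pure Gaussian noise over ~20 points
  is ~3.7σ, while real titrations in this domain run ≥ 10σ, so the factor
  6 separates the two regimes;
- a fitted pKa more than 1 unit outside the observed pH window is flagged
  `extrapolated`;
- practical non-identifiability of a two-pKa fit is flagged when either
  pKa can be displaced by 0.5 units, re-optimizing everything else, at an
  extra-RSS cost below the 95% F-quantile × residual variance (a
  redundant transition is absorbable in at least one direction, so the
  minimum over the two directions is tested). Data truly generated from
  one transition are flagged; well-separated genuine double sigmoids are
  not.

Model selection between the nested forms uses the extra-sum-of-squares
F-test, default α = 0.05. α = 1 always accepts the richer model when it
improves the fit; α → 0 never does.

## Activity statistics

Replicate summaries use the sample SD (n−1) and the percentage standard
error 100·(σ_{n−1}/√n)/mean. Relative activity is the ratio of means
× 100; its uncertainty multiplies the percentage by the quadrature sum of
the two relative sample SDs (not standard errors), and the cross-dataset
average carries √(Σu_i²)/n. This propagation convention reproduces every
printed uncertainty of the bundled reference table (±11, ±7, ±7, ±9, ±4
per dataset; ±5 on both averages), which is why it was adopted; treating
the average's error as the SEM of the per-dataset percentages does not
(it gives ~±1 where the table prints ±5). Internal values are never
rounded; display rounding (integers for means/SDs/percentages, one
decimal for pKas, ties away from zero) lives entirely in the report
formatter.

Formulas generalize to unequal replicate counts, although the bundled
data are all triplicates.

## Motif analysis

Coordinates are 0-based internally with offsets relative to the
N-terminal motif cysteine (so the β1 acidic slot is −6, the α1 acidic
slot defaults to +7 with +6 available for the CcmG/ResA/StoA spacing);
reports are 1-based. The distal β2 partner cannot be a fixed offset
across families (≈+25 in thioredoxin, +27 in cDsbD), so it is located by
a first-match scan for {Q,N,K,R,H} over offsets +20..+35, overridable by
an explicit alignment column when a curated alignment exists. Slots
falling outside the sequence are marked missing and excluded from
conservation denominators. Burial is accepted only as a user annotation:
computing solvent accessibility requires a structure and is out of scope.

Classification is a total, deterministic rule cascade on the extracted
slots (acidic β1 + amide partner / acidic β1 + basic partner / acidic β1
unpartnered / no acidic β1, with a P/G-in-XX modifier); each decision is
recorded in a trace. It depends only on the examined slots, never on
sequence content elsewhere.

## Synthetic data

The generators encode the study conditions used throughout testing:

- titrations: pH ladder 4–13 (step 0.5, or 0.25 for double sigmoids),
  i.i.d. Gaussian noise of SD 0.05 ppm on shifts — small against the
  0.5–3 ppm amplitudes characteristic of cysteine/aspartate titrations;
  per-resonance amplitudes drawn uniformly in a stated range with
  baselines in 25–35 ppm (a ¹³Cβ-like region; the fits are
  translation-invariant so the baseline choice is cosmetic);
- coupled-site observables: shift linear in each site's deprotonation
  fraction, default a pure site-B reporter;
- densitometry: lognormal readings (positivity guaranteed) at CV 0.07,
  matching the ~4–7% spreads of triplicate gel densitometry, with a
  truncated-normal alternative;
- sequences: background uniform over the standard alphabet *minus
  cysteine* (so the planted -CXXC- is unambiguous), with slot residues
  drawn from per-slot frequency tables; partner-candidate residues
  occurring in the scan window before the planted partner are replaced so
  the window scan recovers the planted layout deterministically.

Every generator is a pure function of its spec including the seed, and
returns the ground truth alongside the data. What the generators do not
emulate: peak overlap and assignment errors, pH-meter drift, gel-loading
artefacts, or real phylogenetic correlation between sequences — recovery
results on synthetic data therefore validate the estimators under the
stated noise model, not robustness to those real-world effects.

## Recovery studies and problem sizes

`trxpka.recovery` fixes three simulation-and-refit designs with published
cDsbD values as ground truth: wild-type Cys-461 (pKa 10.6, 7 resonances,
amplitudes 0.5–2.5 ppm), the Q488A symmetric coupled pair (microscopic
7.6/10.4, 5 reporters of 2.7 ppm total amplitude on the fine grid), and
the D455N/Q488A control (pKa 8.8, 6 resonances, amplitudes 1.8–3.0 ppm).
These sizes mirror the resonance counts behind the published aggregate
values and run in a few seconds in total. `scripts/acceptance.py` runs
the three studies from a single master seed (per-study sub-seeds via
`numpy.random.SeedSequence.spawn`) and writes the aggregated estimates.

Monte-Carlo property tests use 200 repeat simulations for the
one-pKa estimator's bias/spread bounds and 100 random models for the
microstate oracle; these sizes keep the full suite around ten seconds
while leaving the asserted bounds comfortably non-trivial.

## Known limitations

- Per-resonance two-pKa fits assume both transitions are visible in the
  observed window; strongly overlapping transitions (Δ ≲ 1) are reported
  but will often carry the non-identifiability flag.
- The microscopic inversion requires 0 < r̂ < 1; a reporter blind to one
  transition (r̂ → 0 or 1) cannot be inverted and raises instead.
- The F-test assumes i.i.d. Gaussian residuals; with correlated residuals
  its size is only approximate.
- Sequence classification is qualitative by design — it labels
  electrostatic archetypes, it does not predict pKa values.
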