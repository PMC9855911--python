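# Methods

`flavidyn` analyzes time-resolved spectra of photoexcited flavins —
transient visible absorption (visTA) and femtosecond-stimulated Raman
(FSRS) matrices spanning femtoseconds to sub-milliseconds — and extracts
the time scales of the underlying photocycle. This note documents the
models, the numerical choices, and the design decisions that were
genuinely open.

## Lifetime-distribution analysis by maximum entropy

Each spectral channel's time trace is modelled as a quasi-continuous
superposition of exponential decays on a fixed lifetime grid,

    y_i(t_j) = Σ_k a_{i,k} exp(−t_j / τ_k) + c_i ,

a discretized inverse Laplace transform. The grid is logarithmic with 41
points per decade from 10⁻¹³ to 10⁻³ s (411 points), so the amplitudes
a_{i,k} — the only fitting parameters — form a lifetime density map over
channel and lifetime. The per-channel offset c_i absorbs components with
lifetimes at or beyond the 0.8 ms experimental window, which the grid
alone would alias into its last decade.

Inverting a Laplace kernel is severely ill-posed, so the amplitudes are
regularized by maximum entropy. Because difference spectra carry both
positive (excited-state) and negative (ground-state bleach) features, we
use the standard signed-MEM construction: a = p − n with p, n ≥ 0 and
the Shannon–Jaynes entropy relative to a flat prior m applied
symmetrically to both halves,

    S(p, n) = Σ_k [p_k − m − p_k ln(p_k/m)] + [n_k − m − n_k ln(n_k/m)] .

Each channel then solves the convex problem

    min_{p,n≥0,c}  ½‖y − K(p − n) − c‖² − λ S(p, n) .

**Prior scale.** MEM needs a prior scale; nothing in the data fixes it.
We use m = 10⁻⁶ · max|signal| per dataset: small enough that an
"empty" lifetime bin contributes negligibly, large enough to keep the
entropy gradient finite. Fits are insensitive to m over several orders
of magnitude because the entropy penalty for an amplitude a scales only
as a·ln(a/m).

**Regularization weight.** One global λ is selected per dataset, pooled
over channels, not per channel: the dynamical content aggregates
channels, and per-channel weights would make amplitudes incomparable
across the map. The path holds 24 log-spaced values over six decades
centered on the discrepancy-principle heuristic λ₀ = n_delays·σ̂², where
σ̂ is a robust noise estimate (1.4826·median|Δ²y|/√6 from second
differences along the time axis; the median makes the smooth kinetic
signal largely irrelevant). The selected λ* is the corner of the L-curve
— the point of maximum discrete (Menger) curvature of the pooled
(log₁₀ χ², log₁₀(−S)) curve — with ties resolved toward the larger, more
conservative λ, and degenerate (collinear) paths falling back to the
largest λ.

**Solver.** The entropy acts as an interior barrier, so the optimum
satisfies smooth stationarity conditions p = m·exp(g/λ),
n = m·exp(−g/λ) with g = Kᵀr and r the fit residual. Substituting back
leaves a small nonlinear system in r (and c) alone,

    r − y + K·2m·sinh(Kᵀr/λ) + c = 0 ,   Σ r = 0 ,

which is exactly the KKT system of the primal problem. It is solved by
a damped Newton method, vectorized over channels (they share the
kernel), with backtracking line search on the residual norm.
Convergence is declared when the KKT residual norm falls below
10⁻⁸‖y‖ (with an absolute floor of 10⁻⁸·10⁻³·max-channel-norm so
channels carrying no signal terminate); channels whose line search can
no longer improve — which happens only at extreme λ where the system's
conditioning is exhausted — are frozen at their best point and flagged,
never silently accepted. Two continuation devices make the solve
robust: a cold start descends from a heavily over-regularized λ (where
the solution is the offset-only fit) in decade steps, and warm starts
across the λ path rescale the residual by the λ ratio, since
Kᵀr = λ·ln(p/m) makes r proportional to λ near the solution. The
sinh/cosh argument is clipped at ±300 to keep intermediates finite; the
converged solution has |g/λ| ≈ ln(|a|/m) ≈ 30 and is unaffected.

In the λ→0 limit the fit reproduces unregularized least squares (tested
against a brute-force oracle to 10⁻⁴ relative on small grids). The
objective's exact scale symmetry is (y, m, λ) → (sy, sm, sλ); the
dataset-level pipeline is scale-equivariant because the prior tracks
max|signal| and the L-curve reselects λ.

## Dynamical content and events

The lifetime density map is condensed to one curve per spectral region,

    D(τ_k) = Σ_i a_{i,k}² ,

summing over the channels inside the region (offsets are excluded — a
non-decaying component has no lifetime coordinate). The printed formula
is a plain sum over channels; since D is reported normalized to max 1,
a 1/N normalization would be immaterial, and we implement the sum.

Peaks of D are the regions around strict local maxima, delimited by the
flanking local minima (or the grid edges). The peak area is the
trapezoidal integral of D over log₁₀τ — the natural measure on a
logarithmic grid; the area measure is otherwise arbitrary and only
relative areas matter. A peak is a significant dynamical event iff its
relative area (fraction of the total area over the full grid) strictly
exceeds 10%. The event lifetime is the D-weighted geometric mean of τ
within the peak; an arithmetic mean would bias toward long lifetimes on
a log grid. In event tables the two largest-area events are labelled
"1" and "2" by ascending lifetime (intersystem crossing and the slow
transition, in all scenarios studied here) and remaining significant
events get Greek letters by ascending lifetime.

Analysis regions are closed intervals: Raman high frequency
(1000–1750 cm⁻¹), truncated low frequency (303–1000 cm⁻¹), full low
frequency (dataset minimum–1000 cm⁻¹; the instrument-dependent minimum
is left configurable), and visTA (380–1000 nm). Delays below 750 fs
fall inside the instrument-response/coherent-artifact window and are
excluded before any analysis; the boundary value is kept.

## Kinetic isotope effects

For a photocycle step observed in both solvents, KIE = τ(D₂O)/τ(H₂O).
Event tables from the two solvents are matched by rank (ascending
lifetime) when they contain equally many significant events — the
normal case, mirroring the identity of events 1 and 2 across solvents —
and otherwise by greedy nearest-log₁₀-lifetime pairing, discarding
pairs more than one decade apart. Steps classify as
`proton_transfer_limited` when KIE > 2 and `none` otherwise: observed
values cluster near 1 (no labile-proton involvement) or at 7–12
(rate-limiting proton transfer), so the boundary sits in the empty
middle and is exposed as a parameter.

## Global kinetic analysis

As a model-based cross-check of the model-free LDA, the whole matrix is
fitted by an irreversible sequential compartment scheme
A → B → C → ground (three components by default), Y ≈ C(τ)·E. For
fixed lifetimes the evolution-associated difference spectra E have a
closed-form minimum-norm least-squares solution, so only the lifetimes
are optimized (variable projection) with `scipy.optimize.least_squares`
in log space. Lifetimes are kept ascending by construction
(τ₁ = e^θ₁, τ_{i+1} = τ_i(1 + e^θ_{i+1})), removing the permutation
ambiguity of the chain. The third component of a three-component fit is
computed but flagged "not reported" by default: with a dark terminal
species it carries almost no signal, and comparisons against LDA use
the first n−1 lifetimes. No instrument-response convolution is applied;
the analysis starts at 750 fs where the kinetics are purely
exponential. On the synthetic protein scenario the first two GKA
lifetimes agree with the LDA event centers to within a few per mille —
comfortably inside the 25% band we regard as quantitative agreement.

Compartment populations (and those of the synthetic generator's Bateman
chains) are computed as exp(At)·e₁ with the bidiagonal first-order rate
matrix via `scipy.linalg.expm`. This is exact for every rate
configuration, including the degenerate rates where the textbook
partial-fraction Bateman formula divides by zero — no formula switching
is needed. The closed-form Bateman solution and an independent ODE
integration serve as test oracles (agreement to 10⁻⁸; mass conservation
to 10⁻¹²).

## Synthetic data generator

The generator emulates the measured quantity of the real experiments so
that every stage of the pipeline can be validated against a known
ground truth:

* **Kinetics** — a sequential irreversible chain (singlet → triplet →
  adduct/ground), with preset lifetimes equal to the published mean
  lifetimes of each sample/solvent/detection-region combination.
  Transient-absorption presets use the TA column of that table, Raman
  presets the Raman-high-frequency column, keeping every ground truth
  traceable to a specific published value. One published row (the slow
  C78A decay) has ambiguous column alignment, so C78A presets expose
  the slow lifetime as an explicit parameter (defaults: 208/269 µs TA,
  87/109 µs Raman for H₂O/D₂O).
* **Spectra** — species-associated *difference* spectra built from
  Gaussian bands: flavin ground-state bleach near 445 nm, singlet
  excited-state absorption ~510 nm, stimulated emission ~565 nm,
  triplet–triplet absorption ~660 nm (and analogous Raman band sets in
  the fingerprint region). Difference spectra are simulated directly —
  bleaches as negative bands — rather than as absolute spectra minus a
  ground state; the analysis only ever sees difference signals, so the
  two are equivalent and the direct form is simpler.
* **Resonance loss** — photoproducts absorbing near 390–450 nm are
  non-resonant with an 800 nm Raman pump, so the terminal species can
  be declared dark (`final_resonant=False`), collapsing the signal at
  the longest delays. The cysteine-less C78A variant instead shows a
  resonant component that persists beyond the window, emulated by a
  constant `nondecaying_fraction` (default 0.15) of the last resonant
  spectrum.
* **Sampling and noise** — 53 exponentially spaced delays from 100 fs
  to 0.8 ms; 64 spectral channels by default; additive homoscedastic
  Gaussian noise with σ = 1% of the peak absolute signal (the
  experiments publish no noise model; 1% of peak is a realistic
  shot-to-shot level for averaged pump-probe data), reproducible from a
  seed.
* **Minor events** — the low-abundance extra events reported for free
  FMN (solvent response ~1 ps, ribityl-chain motion ~100–150 ps, a late
  ~91 µs component) are available as optional additional chain members,
  disabled by default.

What the generator does **not** emulate: instrument response and
coherent artifacts (delays below 750 fs are excluded downstream
anyway), probe chirp, scattering/solvent backgrounds, heteroscedastic
or correlated noise, anisotropy, and spectral overlap structure beyond
a few Gaussian bands. Passing recovery tests therefore demonstrate that
the inverse machinery is correct and well-calibrated for
multi-exponential kinetics at realistic noise — not that real data with
baseline drifts or correlated noise would behave identically.

## Validation problem sizes

Recovery experiments run the full default analysis (411-point grid,
24-point λ path, 64 channels, 48 retained delays) on three
transient-absorption presets over 20 seeds each; the recovered event
centers are required to fall within two grid steps (≈12%) of ground
truth in at least 90% of seeds, and their medians land well within one
grid step. These sizes make the complete validation suite run in a few
minutes on a single core while exercising the exact configuration used
for real data.

## Known limitations

* The MEM entropy form and λ-selection strategy are one defensible
  choice among several (per-channel λ, quadratic penalties, Bayesian
  treatments); output metadata records the pooled-λ decision.
* Peak splitting: two events closer than roughly the peak width on the
  log-lifetime axis (≲ half a decade at the default regularization)
  merge into one detected peak.
* The sequential GKA scheme cannot represent branching or back
  reactions; it is intended as a cross-check, not a mechanism search.
* Loaders accept local delimited matrices only; instrument binary
  formats and chirp correction are out of scope.
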