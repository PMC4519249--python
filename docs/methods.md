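# Methods

`convtx` models gene regulation at a locus where two convergent promoters,
pX (sense) and pY (antisense), transcribe the same stretch of DNA in opposite
directions.  Three coupled layers are implemented: a discrete stochastic
simulation of RNA-polymerase (RNAP) traffic that quantifies transcriptional
interference (TI); deterministic mass-balance ODEs for the cellular RNA pools,
with and without antisense hybridisation (AR); and a protein feedback network
in which the sense gene's product represses the antisense promoter while the
antisense gene's product indirectly relieves that repression.

## 1. The traffic layer

### Geometry and schedules

The locus is the interval from −70 (upstream edge of pX) to L+70 (downstream
edge of pY) with the transcribed overlap spanning positions 1..L (default
L = 400 bp).  Initiation complexes (ICs) occupy a 70-bp footprint at their
promoter; elongation complexes (ECs) a 35-bp footprint, tracked by the RNAP
centre coordinate.

Transcription initiation follows a two-step scheme: RNAP binds at mean
intervals τ_B and converts to an EC after a mean initiation time τ_I < τ_B.
Both times receive Gaussian noise with a 5% coefficient of variation,
truncated at zero.  The binding schedule is precomputed as the cumulative sum
of interval draws and is *independent of outcomes*: an occluded attempt
consumes its slot and the next attempt arrives one interval later.  Because
τ_I < τ_B only on average, noisy schedules occasionally make a round bind
while the previous IC is still initiating; self-occlusion is not modelled
(consistent with the two-step scheme's assumption that the firing period
equals the binding period), so such ICs coexist and are individually exposed
to sitting-duck interference.

The relative promoter strength is α = f_Y/f_X = τ_BX/τ_BY.  Strength sweeps
hold pX fixed (τ_BX = 20 s, τ_IX = 12 s) and retune pY via τ_BY = τ_BX/α with
τ_IY = 9.5 s; α may range over [0.1, 2.1) before τ_BY would undercut τ_IY.
The stronger promoter performs `n_rounds` rounds (default 30,000) and the
weaker as many as bind within that horizon.

### Elongation

An EC fired at time t starts with its centre at position 1 (sense) or L
(antisense) and advances one nucleotide at a time; the residence time at each
position is 1/v with v drawn independently per position from a positive
Gaussian (50 ± 2.5 bp/s).  A pause site adds its dwell time (and records a
pause window) at its position for ECs on its strand.  Paths extend to
L + 70 + fp/2 (sense; mirror for antisense) so that promoter-transit windows
are fully covered; a round whose EC reaches the end of its path yields a
full-length transcript (length > L + 70).  Between the integer arrival knots
positions are interpolated linearly, which matches the discrete stepping to
within 1 bp and makes encounter times closed-form.

### Interference mechanisms

* **Occlusion.**  A binding attempt at time t fails if any live opposing EC's
  centre is inside the promoter-transit window — (L − fp/2, L + 70 + fp/2)
  for pY, (1 + fp/2, −70 − fp/2) for pX — at t.  The window bounds follow the
  EC front/back edges crossing the promoter region.
* **Sitting-duck interference (SDI).**  When an opposing EC's centre crosses
  the promoter boundary (L − fp/2 at pY, 1 + fp/2 at pX) while an IC is
  present (bound, not yet fired), the sitting duck is dislodged with
  probability 0.9 and its round yields nothing; with probability 0.1 it
  survives as a roadblock and the incoming EC terminates, releasing a
  truncated RNA of length L − fp/2 (floored to 382 nt at the defaults).  A
  surviving duck stays on schedule and later fires normally.
* **Collision.**  Two converging ECs inside the overlap collide at the first
  time their centres close within Δ_critical (default = the 35-bp EC
  footprint).  Both fall with probability 0.2; otherwise one survivor is
  chosen with equal odds (0.4/0.4).  A fallen sense EC releases a truncated
  RNA of length ⌊centre⌋; antisense, ⌊L − centre + 1⌋.  Survivors re-enter
  the pool and may collide again.  If exactly one of the pair is paused at
  the encounter, the sitting-duck-like pause rule applies instead: the paused
  RNAP is removed with its site's `removal_prob_on_hit` (default 0.9,
  truncating at the pause position), otherwise the mover terminates.

The simulator is event-driven: binding attempts, firings, boundary crossings
and pairwise encounter times are processed in global chronological order from
a priority queue (ties broken binding < firing < movement, then pX before pY,
then round index).  Pairwise encounter times are computed once, when the
later EC fires, and validated against termination times when popped — exact,
because truncation is the only way a path ever changes.  On noiseless,
probability-degenerate configurations the event-driven results are tested to
agree round-for-round with an independent fixed-step (1 ms) time-stepping
simulator.

All stochastic draws flow from a single `numpy` generator seeded by
`TIConfig.seed`; identical configurations reproduce byte-identical results.

### Rates

With f = 1/τ_B, the success fraction η (full-length rounds / total rounds,
per promoter) gives the net production rates k_x = f_X·η_x and
k_y = f_Y·η_y; truncated pools are histogrammed by length, and only RNAs
longer than 60 nt — long enough to fold the stem-loops needed for antisense
pairing — count toward the aggregate truncated production rates used by the
RNA layer.  One event/s is mapped to 1 nM/s by default
(`concentration_per_event`); this makes f_X = 0.05 s⁻¹ correspond to the
0.05 nM/s used to seed the network solve.

## 2. The RNA layer

The TI-only model balances production against first-order loss
(degradation λ plus growth dilution μ) for the four free pools, so
x* = k_x/(μ+λ_x) in closed form.  The TI+AR model adds second-order hybrid
formation between complementary pairs (x:y, x_k:y, x:y_h, x_k:y_h),
first-order unbinding — one rate k_uxy for the three hybrids with a
full-length partner, a larger k_uxkyh for the doubly truncated hybrid with
its shorter complementary region — and first-order loss of every species.
Hybrids are translationally silent and degraded; they never release material
back except through unbinding.

Steady states are computed by LSODA
integration from an empty cell (all concentrations zero), followed by a
Newton root polish, accepted when max|dc/dt| / max(1, max|c|) < 10⁻⁹ s⁻¹ and
all concentrations are nonnegative.  Warm starts (used by dose sweeps)
replace the empty initial state.

Kinetic constants are exposed as configuration with placeholder defaults
chosen inside the stated literature ranges: binding 0.0017 nM⁻¹s⁻¹
(≈10⁶ M⁻¹s⁻¹), k_uxy = 10⁻³ s⁻¹, k_uxkyh = 10⁻² s⁻¹, all RNA λ = 3×10⁻³ s⁻¹
(≈4-min half-life, the *E. coli* mRNA scale), μ = 3×10⁻⁴ s⁻¹ (≈40-min
doubling).

## 3. The protein layer

Proteins X and Y are translated from full-length x and y only (first-order,
k_X, k_Y).  X represses pY: with rapid-equilibrium operator binding the free
operator fraction is K_OY/(K_OY + [X]) and the pY firing rate interpolates
linearly between f_Y,min (repressed) and f_Y,max (de-repressed).  The
defaults enforce the strength ratios f_Y,min/f_X = 0.37 and
f_Y,max/f_X = 1.74.  Activator Z — produced externally at the dose rate k_WZ
and activated indirectly by Y at k_YZ·[Y] — binds X (k_XZ, k_uXZ) and
sequesters it, closing the positive feedback loop.

Because the traffic layer is a simulation, each steady state is solved
self-consistently in two steps: (1) the twelve ODEs are solved with guessed
transcription rates (k_x = 0.05, k_xk = k_yh = 0.01 nM/s) and, during this
guess stage only, the y production rate slaved to the instantaneous
repressor level through the operator relation — the guess stage has no
success-fraction information, so η_y = 1 there; (2) the resulting repressor
level fixes f_Y, the traffic simulation is rerun at that rate, and the ODEs
are solved again with the realised rates.  Because the guess stage assumes
*no* interference on x, it deliberately biases the solve toward the
repressed branch at low dose, which is what makes the OFF state reachable
from an empty cell; additional fixed-point updates are available
(`n_updates`) and settle quickly in tests.  Steady states with negative
concentrations are rejected as unphysical.

### Bistability analysis

`bistability_scan` sweeps k_WZ quasi-statically: ascending with each
converged state warm-starting the next grid point, then descending.  A
branch transition is a jump of more than J = 5× in the response species
(protein Y by default) between adjacent converged grid points; the jump
location is refined by bisection (probes continue from the pre-jump state)
to 0.1 nM/s by default.  Up- and down-sweep jumps within twice the
refinement precision are treated as one sharp transition, not hysteresis.
Classification: `bistable_irreversible` when the down sweep never leaves the
ON branch inside the grid; `bistable_reversible` for distinct thresholds
(with threshold_off < threshold_on); otherwise by the Hill exponent of the
up branch — |H| > 2 ultrasensitive, 0.8 ≤ |H| ≤ 1.2 Michaelian, else
ramping.  J and the Hill cutoffs are declared conventions.

### Protein placeholder constants

The protein constants are known only to within broad biological ranges.  The
defaults were chosen once, within those ranges, so that the default network
sits in the characteristic dose-response regime of this circuit architecture:
a reversible bistable switch with an OFF→ON threshold on the
10 nM/s dose scale (the defaults give ≈11.4 / ≈5.1 nM/s up/down), loss of
bistability when the RNA binding constants are zeroed, and a bistable window
that widens monotonically with k_bxy.  Calibration used a deterministic
surrogate of the traffic layer (interpolated η(α) curves); the frozen values
are k_X = 1.4 s⁻¹, k_Y = 0.01 s⁻¹, k_YZ = 2×10⁻³ s⁻¹, k_XZ = 0.01 nM⁻¹s⁻¹,
k_uXZ = 10⁻³ s⁻¹, K_OY = 10 nM, λ_X = λ_Z = 3×10⁻³ s⁻¹,
λ_Y = λ_XZ = 3×10⁻⁴ s⁻¹.  The interpretation of k_X is a lumped
translation-and-maturation gain; its size compensates for the placeholder
RNA degradation rates and should be re-fit if real kinetics are supplied.
The mechanistic requirement behind the regime is that the repressor
production flux k_X·x_OFF sets the OFF→ON titration threshold while the
Y→Z feedback k_YZ·Y_ON sets the width of the hysteresis loop.

## 4. Analysis conventions

* **Sweeps.**  The default α grid is 20 linearly spaced points on [0.1, 2].
  Linear spacing mirrors how the switch curves are plotted and fitted — one
  grid convention was fixed after checking that it yields consistent
  exponents across regimes (80% and 0% collision survival).  Per-α seeds are spawned
  deterministically from the template seed.
* **Hill fits.**  Response curves are fitted to k_max·α^H/(K^H + α^H) by
  bounded least squares with multi-starts at H ∈ {±1, ±3, ±6}, |H| ≤ 15,
  K ∈ [0.05, 20]; H is signed (negative for falling curves).  The adjusted
  R² uses n − 3 residual degrees of freedom; fits below 0.95 are flagged
  low-quality.
* **Expression maps.**  Per α, round fates are histogrammed over
  normalised-length bins of width 0.05: bin "0" holds rounds that failed to
  fire (occlusion + dislodged ducks), interior bins ⌊length/L⌋, and ">1" the
  full-length fraction; each column is a probability distribution.  The
  sitting-duck survival length 382 nt lands in the 0.95 bin.
* **Dynamic range** is the fold change of a species between two sweep
  points, reported with its direction; it is invariant to uniform scaling.
* **Sensitivity** tables are one-factor-at-a-time: each factor scales one
  parameter, reruns the supplied pipeline and records the response; factors
  violating structural constraints (e.g. τ_IY ≥ τ_BY) are recorded as
  rejected rows.

## 5. Problem sizes and runtimes

A single 30,000-round simulation takes ~5–10 s on one core; a 20-point α
sweep ~40 s.  The test suite uses reduced instances (2,500–8,000 rounds,
12-point dose grids) for property checks and full 30,000-round sweeps only
in the acceptance tests.  Dose scans embed one traffic simulation per grid
point and bisection probe, so their cost is (grid × 2 + probes) × one
simulation.

## 6. What the defaults do and do not emulate

The default configuration is an abstract convergent-promoter locus with
promoter kinetics, geometry and survival probabilities taken from the main
study condition; it does not model sequence (positions are abstract
coordinates), supercoiling beyond the critical-distance parameter, RNAP pool
depletion, roadblocks by other DNA-bound proteins, or trans-acting antisense
RNA.  Passing tests therefore demonstrate the mechanisms' collective
behaviour under these idealisations, not quantitative agreement with any
particular biological locus; the RNA and protein kinetic constants in
particular are placeholders, and every quantity that depends on them (TI+AR
Hill exponents, bistability thresholds) should be read as
placeholder-conditioned.

## 7. Known limitations

* Same-strand ECs never interact (no queueing); at equal mean speeds
  catch-up is negligible, but strong pause sites make this approximation
  visible for dense same-strand traffic.
* The linear interpolation of paused ECs lets a paused centre drift ≤1 bp
  across its dwell time.
* Multiple coexisting ICs at one noisy promoter are each exposed to SDI;
  other conventions (refractory promoters) would shift sitting-duck
  statistics at α near the τ_IY/τ_BY validity edge (α → 2.1).
* Hill exponents of very sharp switches depend measurably on the α-grid
  placement; the linear default is a convention and is stated with the fits.
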