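# Model and methods

## The model

A single cell lives on a periodic `width × height` square lattice (default
300×300). Each site carries three values: the cell label σ ∈ {0 = medium,
1 = cell}, an integer Act value in `[0, Max_Act]` recording recent
protrusive activity, and an adhesion bit marking attachment to the
substrate. Adhesions exist only under the cell and medium carries no Act
value; both invariants are enforced by the update rules and re-checked in
the tests.

Dynamics proceed by Metropolis-accepted copy attempts between Moore-adjacent
sites with unlike labels. The acceptance probability is 1 for negative
total energy changes and `exp(−ΔH_total/T)` otherwise, with

```
ΔH_total = ΔH_contact+area+perimeter − f·(λ_Act/Max_Act)·(GM(src) − GM(tgt)) + λ_adh·Adh(tgt)·[retraction]
```

GM is the geometric mean of Act over the same-label Moore neighbourhood
*including the focal site* (the convention of the original protrusive-memory
extension; for medium sites GM = 0). The rupture term applies only when the
cell retracts from an adhered site, and the bond is cleared when the
retraction is accepted — the energy is paid once.

One Monte Carlo step (MCS) consists of, in order:

1. **σ-sweep** — attempts calibrated so that each lattice site receives one
   attempt on average (the classic MCS definition). The implementation is
   rejection-free: only directed unlike-label Moore pairs are drawn, with
   the number of skipped like-label draws sampled from the exact geometric
   distribution given the live boundary-pair count, so the scheme is equal
   in distribution to the naive `|Λ|`-draw sweep (verified by a two-sample
   K-S test in the acceptance suite).
2. **adhesion sweep** — all current cell sites visited in a fresh random
   order on the live state: empty sites form de novo with probability `p_s`
   if their Act geometric mean reaches `0.75·Max_Act`; adhered sites first
   attempt an Eden expansion into one uniformly chosen Moore neighbour
   (success `p_e`, only inside the cell), then spontaneous unbinding with
   probability `p_d·(k/8)²`.
3. **Act decay** — every positive Act value decreases by 1.

The adhesion→protrusion feedback factor `f = b + (1−b)/s · A_adh/A`
(clamped at 1 above the saturation fraction `s`, constant 1 when disabled)
is recomputed once per MCS from the current adhesion area and applied to
all attempts of that MCS: it is a cell-wide quantity and a per-attempt
recomputation would create an ill-defined intra-sweep feedback.

### Parameters

Held constant across all study conditions (arbitrary energy units, lattice
sites, MCS): `T = 30`, `A_target = 1000`, `λ_A = 50`, `P_target = 350`,
`λ_P = 4`, `λ_Act = 240`, `Max_Act = 120`, `J_cell,medium = 35`,
`J_medium,medium = 0`, 25000 MCS per replicate. The perimeter is counted
as directed (cell site, non-cell neighbour) Moore pairs; `P_target = 350`
matches a smooth disc of area 1000 under this convention. The adhesion
parameters (`p_s`, `p_e`, `p_d`, `λ_adh`, feedback `b`, `s`) define the
study conditions and are bundled as named presets
(`adhact.experiments.PRESETS`); the no-feedback motility survey uses
`p_d = 0.0008`, the feedback conditions `p_d = 0.001`, and the
cluster-morphology pair `p_d = 0.0004`, `λ_adh = 60`, `b = 0.5`,
`s = 0.12` with (`p_s = 0.003`, `p_e = 0.0015`) vs (`p_s = 0.001`,
`p_e = 0.004`).

### Initialisation, seeding, bookkeeping

The cell starts as a filled disc of area ≈ `A_target` centred on the
lattice with Act and adhesion layers zero; the first 1000 MCS are excluded
from every statistic. Replicate `i` runs on one RNG stream seeded with
`base_seed + i`; all stochastic decisions draw from that stream in a fixed
documented order, so runs reproduce bit-for-bit. Area, perimeter, adhesion
area, the boundary-pair list and the centroid are maintained incrementally;
the centroid sums *unwrapped* per-site coordinates (each site enters with
the periodic image nearest the current centroid), so the recorded track is
continuous across the torus seam. Every bookkept quantity is compared
against a brute-force recount in the tests, and the incremental energy
kernel is checked exactly against full-lattice Hamiltonian differences.

## Trajectory statistics

Centroid and adhesion fraction are sampled every 5 MCS; instantaneous
speed uses a 25 MCS displacement window (the same half-window the
front–rear axis construction uses), assigned to the window midpoint. The
ensemble MSD averages squared displacements from the single post-burn-in
origin over independent replicates; no time averaging is applied because
several regimes (progressive anchoring) are non-stationary and
time-averaging would bias them. The "diffusivity" is the least-squares MSD
slope over lags 11500–24000 MCS divided by 4 (2D convention; only ratios
of diffusivities are interpreted, so the factor cancels). Adhesion
clusters are Moore-connected components respecting the periodic boundary
(scipy labelling plus union-find stitching across the seam). The
front–rear axis at snapshot time t is the unit vector between the cell
positions at t−25 and t+25; adhesion-site offsets from the centroid
(minimal image) are projected onto it and pooled over snapshots (every
100 MCS) and replicates.

## MSD models and fitting

The model family is Fürth, extended Fürth (`+D_T t`), the anomalous
variant (`+D_T t^β`) and the fractional Klein–Kramers MSD
`4ν²t²E_{α,3}(−γ_α t^α)` with either translational-diffusion or constant
noise. Fits minimise squared residuals of `log MSD` over at most 80
log-uniformly thinned lags above 10 MCS (lattice discreteness dominates
below), with positive parameters optimised in log space, `α` and `β`
bounded in (0.05, 1.95), and multi-start initialisation (`α₀ ∈ {0.8, 1.0,
1.2, 1.4}`, persistence-time seeds from the data's late-lag slope). Model
selection is by residual comparison only. A non-convergent fit is returned
flagged rather than raised.

`E_{α,3}(z)` for z ≤ 0 is evaluated by a hybrid scheme: float64 Taylor
series with a running cancellation estimate; the algebraic asymptotic
series `−Σ z^{−k}/Γ(3−αk)` truncated at its smallest term, with an explicit
estimate of the exponentially small contribution present for α ≥ 1; and an
arbitrary-precision (mpmath) series in the intermediate band, at a working
precision predicted from the largest series term. Default target accuracy
is 1e-11 relative (the α = 1 closed form `(e^z−1−z)/z²` serves as the
cross-validation oracle); model evaluations inside the fitter relax this
to 1e-8, far below ensemble sampling noise, to stay out of the
arbitrary-precision band. In the extreme corner α ≳ 1.7 with |z| ≳ 10³ the
evaluator falls back to the better of the two fast branches (~1e-5
worst-case relative error), which only optimizer excursions ever visit.

## Synthetic-data scales and what the reruns show

The published statistics are ensemble averages over 1000 replicates; this
package reruns them at desk scale — 30 replicates for the fractional-order
conditions and 100 per cluster-morphology condition in the acceptance
script, 20–24 in the test suite — chosen so a full rerun fits on a single
CPU in minutes. At these scales the ensemble MSD retains visible noise at
long lags and the fitted fractional order α carries an uncertainty of
roughly ±0.05 (split-half spread), so α-based classifications are
reproduced with tolerances, not digits. Independent-oracle tests
(Ornstein–Uhlenbeck walkers with known speed and persistence time,
closed-form curves) separate fitting error from simulation noise.

## Known limitations

* **Attempt-rate calibration.** The σ-sweep is calibrated to the classic
  definition of one MCS (each site attempted once on average), and the
  rejection-free sampler is exactly equivalent to that definition. The
  per-MCS balance between adhesion kinetics and cell movement is sensitive
  to this time-unit convention, which differs between published lattice
  frameworks. Under this calibration the adhesion inflow at strong
  adhesion (`λ_adh = 100`) is dominated by Eden expansion and removal is
  retraction-limited, so the pinning (pivoting) transition sits at a lower
  formation rate than reported for the original implementation: the
  strong-adhesion/low-formation condition pins progressively (fitted
  α ≈ 1.3) while the strong-adhesion/high-formation condition anchors
  almost immediately and its long-term wander is dominated by slow anchor
  relocation (α ≈ 1.0–1.2). Raising the per-MCS boundary-attempt rate
  2–8× moves the transition toward the published location but breaks the
  exact correspondence with the classic MCS definition (and overshoots
  elsewhere), so the classic calibration is kept and the sensitivity is
  documented rather than tuned.
* The qualitative structure is robust across this ambiguity: speed
  decreases with rupture energy, adhesion area grows with formation rate,
  diffusivity drops far more than speed, the two cluster-morphology
  conditions produce equal adhesion areas with opposite cluster-size and
  front–rear asymmetries, and the speed-fluctuation texture across the
  four motility conditions matches the published ordering.
* Single cell only; no multi-cell interactions, division, chemotaxis,
  substrate mechanics or force-dependent (catch–slip) bond behaviour.
* The generator emulates idealised flat, homogeneous substrates; real
  lymphocyte data include measurement noise, frame-rate limits, cell-cell
  contacts and substrate heterogeneity that these synthetic ensembles do
  not contain, so passing tests validate the model implementation, not
  biological transferability.
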