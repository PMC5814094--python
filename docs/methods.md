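# Methods

## The modeling problem

CaMKII is a ring holoenzyme of 6–12 subunits. Each subunit binds calmodulin
(CaM), can be phosphorylated at Thr286 by its ring neighbor, and each bound
CaM carries four Ca²⁺ sites whose kinetics depend on whether the CaM is
free, subunit-bound, or bound to a phosphorylated subunit. Writing this
system as an expanded reaction network explodes combinatorially: a 6-ring
with 4 states per subunit already has 700 rotationally distinct species
(necklace count), and with 20 per-subunit states over 10⁷. `holosim` avoids
expansion entirely: molecules carry binary site-state vectors, reactions are
site-level rules stored in a hash table keyed by reactant types and states,
and the network is *discovered* at collision time instead of being
enumerated up front.

## Particle engine

One fixed time step performs, in order: Ca²⁺ influx, diffusion, boundary
handling, bimolecular reactions, unimolecular reactions, and ring
autophosphorylation.

**Diffusion.** Free particles take isotropic Gaussian steps with per-axis
standard deviation √(2·D·dt). Bound clusters move rigidly with the smallest
member diffusion coefficient ("the larger molecule sets the pace");
clusters containing an immobilized member (a CaMKII ring attached to the
cytoskeleton) do not move. Bound partners overlap exactly — a cluster is
represented by a root particle plus fixed offsets, so ring geometry stays
rigid and co-location is exact by construction.

**Boundaries.** Reflective faces mirror positions (multi-bounce safe),
periodic faces wrap, and a partially absorbing face removes listed *free*
species with a per-crossing sticking probability, reflecting everything
else. The sticking probability is exposed directly rather than derived from
a macroscopic adsorption coefficient; its effective first-order escape rate
depends on the time step and box height, so presets that rely on Ca²⁺
escape state the probability they use. Crossing detection uses end-of-step
positions, which undercounts multiple crossings at coarse steps — another
reason the probability is treated as the model parameter.

**Bimolecular reactions.** Pairs closer than the binding radius react.
Candidate rules for a colliding pair come from a single hash lookup on
(type, state, type, state); the table is populated lazily and its answers
are guaranteed (and tested) to equal a brute-force condition scan. When
several rules share a reactant pair (branched binding, e.g. apoCaM binding
Ca²⁺ on N1 or C1), the pair reacts within the radius calibrated for the
*summed* forward rate and one uniform draw picks the branch with
probability kf_i/Σkf — the discrete analogue of mass-action superposition.
Pairs are processed in randomized order; a particle reacts at most once per
step. Reactions never delete particles: binding sets site bits and a bond,
co-locates the partners and merges clusters, so reaction histories and
conservation checks stay exact.

**Unimolecular reactions.** All first-order channels of a molecule
(flag flips, unbindings, each with hazard k and eligibility from self,
bonded-partner and ring-neighbor conditions) fire as competing risks with
total probability 1 − exp(−Σk·dt) and proportional channel choice.
Unbinding clears the bond on both sides, splits the cluster and places the
more mobile fragment at the binding radius along a uniformly random
direction (no geminate-recombination tuning; the shipped kinetics are
activation-limited where this choice is immaterial).

**Autophosphorylation.** A ring subunit is eligible when it is CaM-bound,
unphosphorylated, and its *left* neighbor ((i−1) mod n; the direction is an
arbitrary but fixed convention) is activated. Variants: the default counts
CaM-bound or autonomous (phosphorylated, CaM-free) neighbors as kinases;
the Michalski–Loew variant requires the kinase neighbor to be CaM-bound
*and* unphosphorylated; scheme 1/2 additionally require the substrate's
CaM to be C-lobe-full (NxC2) or N-lobe-full (N2Cx). The per-subunit rate
depends on the bound CaM's loading state. Monomeric-CaMKII models reuse
the same machinery without the neighbor gate.

## Binding-radius calibration

A fixed-step scheme realizes a rate constant that depends on the binding
radius σ_b, the step dt and the mutual diffusion D through steady-state
depletion of the pair correlation. We compute the realized per-step rate
from the steady state of the absorb-then-diffuse map acting on the radial
pair density (a small linear system; destination bins integrated exactly
with the radial Gaussian CDF; sub-bin absorbers handled by volume-fraction
absorption; far field held at the uniform profile with an analytic
finite-reservoir correction for the 1/r depletion tail), then invert it
with a bracketed root find. The construction reproduces both closed-form
limits — swept volume (4/3)πσ³/dt for σ ≪ rms step, Smoluchowski 4πσD for
σ ≫ rms step — and a well-mixed two-species simulation recovers the
requested mass-action rate within the 2% calibration contract (tested).
The mutual D entering calibration is the sum of the reactant *types'*
coefficients; for a reactant that is transiently part of a slower cluster
this slightly overstates D, which is immaterial in the activation-limited
(swept-volume) regime where σ_b depends only on kf·dt.

## Rate constants

No single measured table covers this exact three-tier, nine-state scheme,
so the shipped `RateSet` is a literature-style reconstruction, clearly an
assumption set, with all values in one editable object so a measured table
can be dropped in:

* Free CaM, sequential cooperative lobes — N sites fast and weak
  (N1: 100/1000, N2: 150/750 μM⁻¹s⁻¹ / s⁻¹), C sites slower and tighter
  (C1: 4/40, C2: 10/10).
* Subunit-bound (K) and phospho-subunit-bound (Kp) tiers slow the Ca²⁺
  off-rates by 3× and 10× (higher affinity, unchanged on-rates).
* CaM–CaMKII affinity is anchored at apoCaM (kon 2 μM⁻¹s⁻¹, Kd 30 μM for
  K; Kd 3 μM and 10× slower unbinding for Kp — CaM trapping); the affinity
  of every other loading state is *derived* from the thermodynamic cycle,
  which makes every closed loop detailed-balanced exactly.
  `check_reversibility` audits all independent cycles of the two-layer
  association network (28 with the shipped set) and reports residuals.
* Per-state phosphorylation rates peak at N2C2 (1.5 s⁻¹) and satisfy the
  N/C exchange symmetry k(N2C0)=k(N0C2), k(N2C1)=k(N1C2), so the two
  restricted schemes are rate-matched by construction.

The reduced-chain preset (`reduced_fig13`) uses its own small rate set
(C1 2/15, C2 30/15, N1 100/400, CaMKII binding 30/2, phosphorylation
1 s⁻¹, well-mixed Ca²⁺ efflux 80 s⁻¹). These values were chosen once, at
model-construction time, so that the chain acts as a Ca²⁺-frequency
detector: the C-site retention time (~70 ms) sits between the 10 Hz and
5 Hz inter-pulse intervals, giving high-frequency input an advantage at
sub-saturating influx, while apoCaM depletion at saturating influx hands
the advantage to the lower frequency — the crossover the preset exists to
express.
Absolute phosphorylation counts depend on these choices and are asserted
nowhere; only orderings and crossover structure are.

## Stimuli

The synthetic theta-burst generator replaces a detailed compartmental
neuron model: stereotyped biexponential action potentials (rest −65 mV,
peak +30 mV, ~2 ms width) at 5 spikes/100 Hz per burst, 5 bursts at 5 or
10 Hz. Channel gating is a two-state HH-style gate (V½ = −15 mV, slope
8 mV, τ in ms); open channels convert the single-channel current
(g = 5 pS, RT/zF = 12 mV) to ions per step via |i|·dt/2e with stochastic
rounding, entering 1 nm below the top-face center. Matched-influx pairs
are selected from trial ensembles by minimizing the total-ion difference.
What the generator does *not* emulate: morphology-dependent spike
waveforms, synaptic release stochasticity, channel inactivation, and any
feedback from cytosolic Ca²⁺ onto the membrane potential — passing tests
therefore validate the network's response to stereotyped, decoupled input,
not the upstream electrophysiology.

The channel-number fit reproduces N = 16 for a 1 μm² patch. The fitted
offset potential comes out ≈0 mV with these constants: on the shared
12 mV thermal-voltage scale the GHK current is, up to the negligible
intracellular-Ca²⁺ term, exactly of the single-channel functional form, so
the joint fit is shape-degenerate in the offset. The shipped *simulation*
default V_s = −1.91 mV (a literature value for this channel
parameterization) is kept configurable and independent of the fit, which
reports what the equations give.

## Oracles

* **ODE**: stiff-safe mass-action integration over the expanded species
  network (expansion guarded at 10⁴ species).
* **SSA**: exact direct-method sampling over the same network with timed
  injections for pulse protocols. For the full network with monomeric
  CaMKII, CaM classes carry the pair information (the K/Kp attachment bits
  mirror the partner's phosphorylation state), so class counts are exact
  without dimer species. Ring topology is out of the SSA's reach; ring
  phosphorylation is validated instead against the exact chain below —
  this is why the closed-network cross-check preset uses monomers.
* **Ring chain**: the directed ring process under saturating CaM with the
  no-phospho-kinase rule is solved exactly over the 2ⁿ configurations
  (uniform embedded jump chain, n ≤ 16), giving 1/2 (dimer), 2/3 (trimer)
  and ≈1−e⁻¹ beyond — note the approach is *not* monotone (f(4) = 0.625 <
  f(3)). Large rings are sampled.
* **Regime classifier**: 1/k_on = 1/k_enc + 1/k_a with k_enc = 4πσD
  (default encounter radius 5 nm, configurable — the source network's value
  is unstated); every shipped Ca²⁺–CaM reaction is activation-limited, also
  at half diffusion, which is what justifies well-mixed references for the
  spatial engine.

## Problem sizes used by the test suite

Chosen once, as the package's own desk-scale study conditions: Ca²⁺–CaM
consistency runs at 1/8 volume (375 Ca²⁺, 88 CaM, 50 ms, dt 1 μs,
10 seeds per diffusion condition, 5 ms comparison windows, 3×SE envelope
with a one-molecule resolution floor); ring fractions at 600 subunits per
ring size; the frequency-crossover at 1/10 scale (SSA) and 1/50 scale
(particle engine, dt 0.1 ms, 20 seeds per condition, endpoints of the
5k–50k ions/pulse ladder); the scheme comparison in a closed Ca²⁺ bath at
1/50 scale. The coarse-step reduced-chain runs deliberately operate with
rms steps comparable to the box (transport is effectively well mixed);
binding radii are calibrated for that dt, and the step-size guard warns —
these runs probe the reaction machinery and boundary bookkeeping, not
spatial gradients.

## Numerical choices and degenerate inputs

* Default dt = 1 μs; a guard warns (or aborts under `strict`) when any
  k·dt > 0.1 or any rms step exceeds box/10.
* Sub-molecule expectations cannot be resolved by few trials; statistical
  comparisons carry explicit effective-sample-size or one-count floors.
* Zero-rate rules parse, enter the table, and never fire; empty candidate
  sets combine to rate 0; branch selection on an all-zero candidate set is
  an error by contract.
* Preferred-pathway ties are reported and stop the walk; nothing is broken
  silently.
* Event-log conventions: direction +1 for binding/flag-set, −1 for
  unbinding; the vertex recorded is the forward edge's source state, so
  nets cancel exactly and the species ledger (initial + inflow − outflow =
  current at every bin boundary) holds as an identity, which is tested.
* One seeded generator drives everything in a run (gating, diffusion,
  reaction draws), so a seed fixes the event log bit-for-bit.

## Known limitations

No volume exclusion or crowding; no Thr305/306 capping, subunit exchange,
or conformational dynamics beyond a static ring radius; no surface
diffusion; partial absorption is per-crossing, not flux-calibrated against
a half-space; homodimer (A+A) binding rules are not supported; two-ring
holoenzymes are stacked 6-rings without inter-ring kinase activity. The
chord-equals-radius reading of the ring geometry is exact only at n = 6;
the radius sweep keeps neighbor spacing equal to the radius by convention.
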