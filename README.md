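# holosim

Particle-based stochastic simulation of multi-subunit signaling complexes
without network expansion, built around the Ca²⁺/calmodulin/CaMKII system.

## The problem

CaMKII holoenzymes decode Ca²⁺ signals in neurons, but simulating them with
realistic kinetics is notoriously hard: each of the 6–12 ring subunits binds
calmodulin (CaM), is phosphorylated by its ring neighbor, and the bound
CaM's four Ca²⁺ sites change kinetics with the subunit's state. Expanding
this into a conventional reaction network explodes combinatorially — a
6-subunit ring with k states per subunit has

    N(n, k) = (1/n) Σ_{d|n} φ(d) k^{n/d}

rotationally distinct species (the necklace count): N(6, 4) = 700, and
N(6, 20) = 10,668,140. `holosim` sidesteps expansion: molecules carry binary
site-state vectors, reactions are site-level rules

    cam{C1==0, C2==0, k==0} + ca{b==0} <-> cam~ca{cam.C1=1, ca.b=1} kf=4 kb=40 label=C1~ca

resolved at collision time by hash-table lookup, and multi-subunit rings
are first-class complexes with rigid geometry and directional
neighbor-conditional autophosphorylation. Brownian dynamics with calibrated
binding radii (a colliding pair within σ_b reacts; σ_b is numerically
inverted so a well-mixed run reproduces the requested mass-action k_on),
per-face boundary semantics (reflective / periodic / partially absorbing),
stochastic voltage-gated Ca²⁺ channels with GHK-bounded unitary currents,
and a reaction-history analysis that turns the event log into per-edge net
fluxes and preferred activation pathways complete the toolkit. Independent
oracles — a mass-action ODE integrator, an exact well-mixed Gillespie
sampler, and the exact ring-jamming Markov chain (phosphorylated fractions
1/2, 2/3, → 1−e⁻¹ for dimers, trimers, large rings) — validate the engine.

It is written for computational neuroscientists and systems biologists who
want spatial, stochastic, site-resolved kinetics of ring holoenzymes
without hand-building (or machine-generating) million-species networks.

## Worked example

Count the distinct species a network-expansion approach would need for one
6-subunit ring with 4 states per subunit:

```
$ holosim count 6 4
700
```

Fit the number of membrane channels whose summed unitary current matches
the GHK current of a 1 μm² patch (g = 5 pS, RT/zF = 12 mV,
P = 0.241×10⁻³ cm/s, [Ca]ₒ = 2 mM, [Ca]ᵢ = 50 nM):

```
$ holosim fit-channels
N = 16 channels, V_s = -0.00 mV
```

Sixteen channels reproduce the patch current; the fitted offset potential
is ~0 because, on the shared 12 mV thermal-voltage scale, the GHK curve is
already of the single-channel functional form (see `docs/methods.md`).

Run the Ca²⁺–CaM test network (9 CaM states, 500 nm cube, 3000 Ca²⁺ and
700 apoCaM = 39.867 and 9.302 μM) at desk scale and analyze the event log:

```
$ holosim simulate --preset model1_ca_cam --scale 0.125 --seed 1 \
    --t-end 0.05 --out-dir out/
wrote out/species.csv, out/events.jsonl (6373 events, 14.511 s)
$ holosim analyze out/events.jsonl --out-dir out/
72 edge-bin rows; preferred path: N0C0 -> N1C0 -> N2C0 -> N2C1 -> N2C2 [no outgoing flux from N2C2]
```

`species.csv` holds the per-millisecond counts of all nine CaM loading
states; `edges.csv` the cumulative net occurrences (bindings minus
unbindings) of every network edge in 10 ms bins; the preferred path is the
greedy walk along the largest final net counts. In this Ca²⁺-rich bath
(≈40 μM against ≈9 μM CaM) the fast N sites carry the largest net flux, so
the walk loads the N lobe first and ends at fully loaded CaM — there is no
CaMKII in this test model to enter. On the full two-layer network the walk
instead passes through CaMKII binding to phosphorylation, and the analysis
is what exposes how saturating influx flips the dominant outgoing edge of a
vertex (the pathway deviation behind the frequency-preference reversal).

The same run is reproducible bit-for-bit: a manifest (config hash, seed,
version) is written next to every output, and a fixed seed fixes the event
log exactly.

As a library:

```python
from holosim import build_preset, necklace_count
preset = build_preset("model1_ca_cam", scale=1/8)
sim = preset.simulation(seed=1)
sim.run()
print(sim.records_dataframe().tail(1))   # counts of all 9 CaM states
print(necklace_count(6, 20))             # 10668140
```

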