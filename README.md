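# spinepattern

Reaction–diffusion modelling of dendritic-spine patterning: a simulator,
morphometry toolkit and linear-stability analyser for studying how neuron
activity and exogenous substances shape the spines on a dendrite.

Dendritic spines — the tiny protrusions that carry most excitatory synapses
— come in four classical shapes (mushroom, stubby, thin, branched), and
their shape distribution and density change in several nervous-system
diseases.  This package models spine morphogenesis with an
activator–inhibitor–substrate system plus a bistable cytoskeleton marker:

    ∂A/∂t = cA²S/H − μA + (ρ_A + δ_A)Y + D_A∇²A
    ∂H/∂t = cA²S   − νH + (ρ_H + δ_H)Y + D_H∇²H
    ∂S/∂t = c₀ − γS − εYS              + D_S∇²S
    ∂Y/∂t = dA − eY + Y²/(1 + fY²)

The self-catalysing activator A drives cytoskeleton (Y) polymerisation at
the growth tip; the faster-diffusing inhibitor H suppresses it laterally;
the substrate S, consumed at rate ε wherever Y ≈ 1, steers growth toward
resource-rich territory.  δ_A and δ_H are additive source rates modelling
exogenously supplied activator/inhibitor.  Three questions the package
answers quantitatively:

1. **Shape** — scanning ε, the single-spine protocol produces mushroom
   (ε ≤ 0.02), stubby (≤ 0.04), thin (≤ 0.7) and branched (> 0.7) spines,
   classified by two silhouette metrics, the relative average width
   RAW = (w_head + w_neck)/2h and the relative constriction width
   RCW = (w_head − w_neck)/h, with thresholds 0.4 and 0.25.
2. **Density** — in a two-stage dendrite protocol, raising δ_A packs more
   spines along the trunk and raising δ_H strips them away.
3. **Mechanism** — freezing (S, Y) leaves a two-species system whose Turing
   instability region and dispersion relation λ(k) are computed exactly;
   the fastest-growing mode gives the Turing wavelength Λ = 2π/k_m, which
   sets spine spacing.  δ_A shrinks Λ (denser spines), δ_H grows it.

## Worked example

Grow a single spine at low substrate consumption (high-resource, low
activity — the mushroom regime) and classify it:

```
$ spinepattern simulate-spine --preset fig4 --epsilon 0.01 --out-dir out
shape_class=mushroom (RAW=2.0000000000000004, RCW=0.6666666666666669)
```

The newborn spine is a short knob (h = 0.9 length units, i.e. 3 pixel rows)
whose head (w_head = 2.1) overhangs the narrower stalk it grew from
(w_neck = 1.5): RAW = (2.1+1.5)/(2·0.9) = 2.0 ≥ 0.4 rules out thin, and
RCW = (2.1−1.5)/0.9 ≈ 0.67 ≥ 0.25 rules out stubby — a mushroom.  Raising
`--epsilon` to 0.05 yields a thin spine, 0.9 a branched one.

Probe the linear theory at a frozen point of the substrate–cytoskeleton
plane:

```
$ spinepattern dispersion --s 0.45 --y 0.35
A*=0.177552 H*=0.0015843 max Re lambda=0.0124167
```

A positive maximal growth rate at k > 0 (with the reaction part stable)
means this (S, Y) lies in the Turing instability region: spatial pattern —
a spine — will emerge there spontaneously.

Python API equivalents live in `spinepattern.rd_core` (simulation),
`spinepattern.morphometry` (RAW/RCW classification, density),
`spinepattern.turing` (steady states, dispersion, wavelengths) and
`spinepattern.experiments` (the scripted sweeps); see also
`spinepattern sweep-epsilon`, `sweep-density`, `sweep-wavelength`.

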