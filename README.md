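# prxkit

Analysis toolkit for peroxiredoxin hetero-oligomers: quaternary-structure
combinatorics of the (α₂)₅ decamer, kinetics of the catalytic redox cycle
from stopped-flow and coupled steady-state assays, and roGFP2 ratiometric
redox-state analysis — with a synthetic-data generator so every stage runs
and is testable without instrument data.

## Who this is for

Typical 2-Cys peroxiredoxins such as yeast Tsa1 and Tsa2 assemble into
ring-shaped decamers of five head-to-tail dimers. When two subunit variants
(or redox / modification states) can occupy the ten positions, the number of
physically distinct rings is a symmetry-orbit count, and the catalytic
behaviour of mixed rings is probed by transient and steady-state kinetics.
`prxkit` packages the three quantitative workflows such a study needs:

1. **Decamer combinatorics** (`prxkit.ring`). Orbits of ring labelings under
   the dihedral action (five rotations about the fivefold axis, five flips
   about the in-plane twofold axes). By Burnside's lemma the count is the
   group average of fixed colorings, giving

   N(m) = (m¹⁰ + 5·m⁵ + 4·m²) / 10

   for m monomer types on a five-dimer ring — 120 for m = 2, growing with
   the 10th power of the number of states. Exhaustive enumeration returns
   one canonical representative per orbit and the stoichiometry census.

2. **Redox-cycle kinetics** (`prxkit.scheme`, `prxkit.fit`,
   `prxkit.steady_state`). The oxidation half-cycle R →(k₁ₒₓ·[H₂O₂]) SOH
   →(k₂ₒₓ) LU →(k₃ₒₓ) SS and the reduction half-cycle
   SS ⇌(k₁ᵣₑ𝒹·[Trx1], k₋) MIX →(k₂ᵣₑ𝒹) RED (optional slow dissociation
   step) are linear systems under pseudo-first-order conditions; traces are
   propagated exactly and analyzed the way stopped-flow practitioners do:
   multi-exponential fits → k_obs → secondary plots whose slopes and
   intercepts are the mechanistic constants. Superposition fits (some rates
   preset) handle hetero-oligomer traces; the coupled NADPH assay module
   converts A340 slopes (ε = 6.22 mM⁻¹cm⁻¹) into initial rates and fits
   Michaelis–Menten parameters with the three classical linearizations as
   outlier diagnostics.

3. **roGFP2 degree of oxidation** (`prxkit.rogfp2`). With fully reduced
   (DTT) and fully oxidized (diamide) control wells,

   OxD = (I400ₛ·I480ᵣₑ𝒹 − I400ᵣₑ𝒹·I480ₛ) /
         [(I400ₛ·I480ᵣₑ𝒹 − I400ₛ·I480ₒₓ) + (I400ₒₓ·I480ₛ − I400ᵣₑ𝒹·I480ₛ)]

   which is 0/1 on the controls and invariant under common intensity
   rescaling.

`prxkit.synth` generates all inputs (noisy stopped-flow traces, A340
progress curves, ratiometric plates, binomially sampled decamer
populations), deterministic given a seed; `prxkit.protocols` chains
simulate → fit → regress for parameter-recovery studies.

## Worked example

```python
from prxkit import burnside_count, composition_census, oxidation_recovery

print(burnside_count(m=2, d=5))
for pair, count in composition_census(5).combined_ratios().items():
    print(pair, count)

res = oxidation_recovery(seed=1, rate_key="tsa2_oxidation")
print(f"{res['k1ox']:.3g}")
```

prints

```
120
(0, 10) 2
(1, 9) 2
(2, 8) 14
(3, 7) 24
(4, 6) 52
(5, 5) 26
1.31e+07
```

— the 120 symmetry-distinct two-type decamers with their stoichiometry
breakdown (2 homodecamers, 2 with a 1:9 ratio, … , 26 with 5:5), and the
second-order sulfenylation rate constant (M⁻¹s⁻¹) recovered by the full
simulate → triple-exponential-fit → secondary-plot chain from noisy
synthetic Tsa2 traces generated with 1.3×10⁷ M⁻¹s⁻¹ as ground truth.
The `examples/` directory holds one narrative script per capability.

A thin CLI mirrors the library (`prxkit enumerate --types 2 --dimers 5
--census`, `prxkit generate stopped-flow …`, `prxkit fit-exponentials …`,
`prxkit secondary-plot …`, `prxkit steady-state …`, `prxkit oxd …`); all
outputs are CSV with `#` provenance headers.

## Layout

```
src/prxkit/
  ring.py          decamer symmetry group, Burnside count, orbit enumeration
  scheme.py        kinetic schemes, exact trace simulation, chain oracle
  fit.py           multi-exponential / secondary / superposition fits
  steady_state.py  NADPH assay initial rates, Michaelis–Menten analysis
  rogfp2.py        ratiometric degree of oxidation
  synth.py         seeded synthetic-data generators
  protocols.py     end-to-end parameter-recovery chains
  tables.py        CSV schemas + provenance headers
  cli.py           command-line layer
docs/methods.md    model assumptions, parameter choices, limitations
examples/          one runnable script per capability
```
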