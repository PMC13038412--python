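# Methods

## Decamer symmetry model

The (α₂)₅ toroid is modelled as a ring of positions 0…9 where positions
(2i, 2i+1) form dimer i: the B-type interface lies inside a dimer, the
A-type interface between consecutive dimers. Its symmetry group has order
10: five rotations (cyclic shifts by even offsets — a one-position shift is
not a symmetry of a dimer-of-dimers ring) and five reflections about the
in-plane twofold axes.

Where those twofold axes pass is a genuine modelling choice: through
monomers (reflections with two fixed points) or through interface midpoints
(fixed-point-free reflections, each a product of five transpositions). We
take them through interface midpoints. Only this convention yields 120
distinct two-type decamers; through-monomer axes would give 136 and a
different stoichiometry census, and the physical twofold axes of a
head-to-tail (α₂)₅ assembly do run through the dimer interfaces.
The resulting cycle index gives the closed form
N(m) = (m¹⁰ + 5 m⁵ + 4 m²)/10, which the test suite checks against both the
constructed group and independent brute-force orbit grouping.

Counting is exact integer Burnside averaging (no size limit); explicit
enumeration reduces every labeling to its canonical form (lexicographic
minimum over the ten group images) and refuses above 2×10⁶ labelings —
beyond that, counting is what one actually wants. Monomer "states"
(redox intermediates, modifications) are treated as a larger label alphabet;
no constraint couples neighbouring states (free colorings). Disulfide
pairing across the B interface would constrain neighbour states and reduce
the count; that refinement is out of scope and flagged here as an
assumption.

## Kinetic model

Under pseudo-first-order conditions (co-substrate in ≥10-fold excess,
clamped constant; the code warns below that ratio) both half-cycles are
linear time-invariant systems:

* oxidation: R →(k₁ₒₓ·[H₂O₂]) SOH →(k₂ₒₓ) LU →(k₃ₒₓ) SS, optionally with a
  hyperoxidation sink SOH →(k_hyp·[H₂O₂]) SO₂H (off by default; no
  literature value for k_hyp exists, it is a free parameter for emulating
  inactivation at high peroxide loads);
* reduction: SS ⇌(k₁ᵣₑ𝒹·[Trx1], k₋) MIX →(k₂ᵣₑ𝒹) RED, with an optional
  slow RED → DISS step standing for Trx-induced decamer dissociation. The
  non-zero intercept of k_obs,1 vs [Trx1] is attributed to the reverse rate
  k₋ on the mixed-disulfide step; the alternative reading (a parallel
  conformational step) is noted but not implemented. Whether the slow third
  phase changes fluorescence directly or through a silent state is unknown;
  it is modelled as fluorescence-changing.
* hetero-oligomer oxidation: two parallel chains with subunit-specific
  k₁ₒₓA/k₁ₒₓB sharing k₂ₒₓ and k₃ₒₓ, initial populations split by the
  subunit fractions (default 0.5/0.5).

Traces are propagated by matrix exponentials per grid step — exact to
round-off for a linear system, so mass conservation holds at ~1e-15 and the
integrator is verified against an independent closed-form sequential-decay
(Bateman-type) solution at 1e-8 relative. That closed form handles repeated
rates exactly through confluent t^p·e^(−kt) terms rather than perturbation;
rates closer than 1e-12 relative are merged.

Fluorescence coefficients are not published; only the phase sign pattern of
the oxidation traces (decrease, increase, decrease) is constrained.
Defaults: R 1.0, SOH 0.7, LU 0.95, SS 0.6 (oxidation); SS 0.6, MIX 0.95,
RED 1.05, DISS 1.0 (reduction, first phase carrying most of the amplitude,
as in measured reduction traces). All are configurable; they affect phase
amplitudes, never rates.

## Inference

Multi-exponential fits use variable projection: amplitudes and offset are
solved linearly for any trial rate vector, and only log-rates are optimized
(Levenberg–Marquardt), from 20 starts drawn from a log-spaced grid between
1/(10·t_max) and 10/t_min (seeded; best residual wins, ties by smaller
parameter norm). Least squares is unweighted — instrument noise is taken
homoscedastic. Phase count is caller-specified, as in practice. Rates
within threefold of each other trigger an identifiability warning, not an
error. For an irreversible chain the fitted k_obs are exactly the chain's
eigenvalues {k₁ₒₓ[H₂O₂], k₂ₒₓ, k₃ₒₓ}; for the reversible reduction step the
fast eigenvalue approaches k₁ᵣₑ𝒹·[Trx1] + k₋ from above as [Trx1] grows.

Secondary plots are ordinary linear regressions (slope = second-order
constant, intercept = reverse rate) or hyperbolic fits
(plateau, half-saturation); both models' AIC values are always reported.
Superposition fits hold preset rates fixed (amplitudes linear, exact on
noiseless data) and optimize only the free phases; presets closer than
1e-6 relative are rejected as collinear.

Steady-state: v = (baseline slope − reaction slope)/(ε·l) with
ε = 6.22 mM⁻¹cm⁻¹, l = 1 cm, consumption positive; slopes outside the
0.02–0.2 ΔA₃₄₀/min working band raise a quality warning. The
Michaelis–Menten estimate is always the nonlinear fit; Lineweaver–Burk,
Eadie–Hofstee and Hanes estimates are diagnostics, and outliers
(|residual| > 3 robust MAD scales) are flagged, never removed.

## roGFP2

The ratiometric formula uses the 400-nm and long-wavelength excitation
channels; the latter is measured near 488 nm but labelled I480 throughout
(the two labels refer to the same channel). Degrees of oxidation outside
[0,1] can arise from noise: both the raw and the clamped value are kept,
downstream defaults use the clamped one. Background subtraction is not part
of the formula and is omitted. Per-well OxD is computed first and averaged
afterwards.

## Synthetic data: what it emulates, what it does not

Generators produce stopped-flow trace tables, A340 progress curves
(30 s flat-plus-drift baseline, then consumption with a soft-saturation
roll-off N/(N+K_N), K_N = 5 µM, normalized so the rate at reaction start is
exactly the configured v), ratiometric plates (sample intensities linearly
interpolate the control intensities according to the true OxD, which makes
the OxD formula exactly invertible on noiseless data), and decamer
populations with independent binomial subunit incorporation (independence
is an assumption — cooperativity in assembly would distort the
stoichiometry ladder; p is configurable).

Noise is additive Gaussian, homoscedastic, with σ = 1% of the per-trace
signal range by default — no published noise characterization exists.
Real instruments add dead time, drift, photobleaching, correlated noise and
mixing artefacts that are not modelled, so passing round-trip tests shows
the inference chain is self-consistent at realistic noise, not that it is
robust to every instrument pathology.

Study conditions (defaults, chosen once): oxidation 1 µM enzyme,
[H₂O₂] = 10–100 µM (6 levels), 1000-point log-spaced grid 10⁻⁴–2 s;
reduction 2 µM oxidized enzyme, [Trx1] = 20–120 µM (6 levels), 4000-point
grid 2×10⁻⁴–10 s; hetero-oligomer 1 µM enzyme, 8 H₂O₂ levels 10–100 µM,
2000-point grid 10⁻⁴–2 s; 3 technical replicates everywhere, averaged per
concentration before fitting (standard stopped-flow practice; it also
reduces the small noise-induced bias of nonlinear rate estimates). Grid
densities are ordinary instrument sampling rates; the early window matters
because most of the fast-phase information lives below 10 ms.

Generating rate constants ship in `src/prxkit/data/default_rates.yaml`
(yeast Tsa1/Tsa2 literature values, pH 7.4, 25 °C). Two entries deserve
note: the homo-oligomer k₂ₒₓ/k₃ₒₓ are reported only as "similar" to the
hetero-oligomer's printed 45 and 3.6 s⁻¹, so those values are reused; and
Tsa1's k₁ᵣₑ𝒹 is only reported as slightly below Tsa2's 3.9×10⁶, so
3.0×10⁶ M⁻¹s⁻¹ is used.

The reduction entries carry the observable `kobs_intercept` rather than a
microscopic k₋: in the reversible scheme the fast eigenvalue equals
a + k₋ + k₂ᵣₑ𝒹 only asymptotically in the pumping rate a, so the generator
root-finds the k₋ for which the noiseless eigenvalue regression over the
actual concentration design has exactly the configured intercept
(`reverse_rate_for_intercept`). The calibrated k₋ sits ~1 s⁻¹ below the
intercept for the default designs.

## Numerical choices and degenerate inputs

* Matrix-exponential propagation; no step-size control needed (linear
  system), per-step propagators cached by dt.
* Exponential-fit rate search in log space, clipped to e^±60 to avoid
  overflow during line searches.
* Canonical decamer form: lexicographic minimum; ties impossible within an
  orbit because the minimum is unique.
* Zero rates, repeated rates and stalled chains are exact special cases of
  the term algebra, not perturbations.
* Tables: comma-separated, '.' decimal, UTF-8, '#' comment provenance
  headers (package version, seed, config hash); schema validation names the
  offending column and line.

## Known limitations

* No decamer–dimer equilibrium coupled to catalysis; the concentration
  dependence of oligomeric state is only reflected in which parameter set
  one chooses.
* No global multi-trace fitting or Bayesian uncertainty; standard errors
  come from the secondary regression only.
* Free-coloring combinatorics ignore chemical constraints between
  neighbouring subunit states.
* The coupled-assay generator models the detection chain as non-limiting;
  Trx/TrxR kinetics are not explicit.
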