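# Methods

## The composite-seed model

A hemp seed is treated as a perfect sphere of outer radius `R` whose outer
shell of thickness `t_H` is the husk and whose interior of radius
`r_c_max = R − t_H` is the nut kernel. All removal processes act from the
outside in, leaving a concentric core of radius `r_c`; the removed volume
fraction `x = 1 − (r_c/R)³` is the model's canonical process coordinate.
Real seeds are mildly ellipsoidal and their hulls are not perfectly
concentric; neither effect is modelled (a mass-basis converter is provided
for reporting against field practice quoted by weight, but volume is
canonical throughout).

Because removal is radial, the remainder is always "whole kernel + a shell
of husk", so any intensive property `p` with husk/kernel values `p_H`, `p_c`
mixes volume-wise:

    p_remain(x) = p_H − (p_H − p_c) · (1 − f_H) / (1 − x),   0 ≤ x ≤ f_H,

where `f_H` is the husk volume fraction. Density and THC concentration are
deliberately the *same* formula — the model extends the physical notion of
density to a density-like concentration — and both public functions call one
shared kernel, so the structural identity is true by construction, not by
test. Beyond `x = f_H` the formula would extrapolate to non-physical
negative values; the implementation instead returns the kernel value (only
kernel remains). Concentration units are mg of analyte per kg of matrix;
regulatory ceilings are mass-per-mass, so solution measurements in mg/L pass
through an explicit density-aware converter at the boundary.

The compliance threshold inverts the mixing formula in closed form,

    x* = 1 − (C_H − C_C)(1 − f_H) / (C_H − L),

with `x* = 0` when the intact seed already complies and an explicit
infeasibility error when even the pure kernel exceeds the ceiling `L`
(`L ≤ C_C`). A Brent-bisection solver over `[0, f_H]` serves as an
independent numerical cross-check, never as the implementation. Compliance
uses an inclusive boundary (a product measuring exactly the ceiling passes).
The bundled ceilings are Korea's 5 mg/kg (seed) and 10 mg/kg (oil); any
other jurisdiction is user-supplied configuration.

Reference parameters bundled as `REFERENCE_SEED`: husk volume fraction 0.10,
husk/kernel density ratio 1.5, husk 300 mg/kg and kernel 2 mg/kg Δ9-THC.
With these, the intact seed sits at 31.8 mg/kg (volume-weighted) and 1.05
kernel densities, and the Korean seed ceiling requires removing 9.1 % of the
whole-seed volume. Note a unit subtlety: `x` is a fraction of the *whole
seed's* volume, so 9.1 % of the seed corresponds to about 91 % of the husk.

One documented discrepancy: converting husk volume fractions of 10–75 % to
relative shell thickness with the exact spherical formula
`t/R = 1 − (1 − f_H)^(1/3)` gives 3.45–37.0 %, not the 2–33 % sometimes
quoted for the same sweep; the exact formula is used and is pinned by
round-trip and quadrature tests.

## Parameter recovery from peeling series

`fit_peeling_series` estimates `(C_H, C_C, f_H)` from observed `(x, C)`
pairs. For fixed `f_H` the model is linear in the two concentrations, so the
fit profiles the residual sum of squares over `f_H` — evaluating each
interval between consecutive observed `x` values and refining the best one
with a bounded scalar minimizer (`xatol` 1e−12) — with an ordinary
least-squares solve inside. This is exact, derivative-free and immune to the
kink in the model at `x = f_H`.

Identifiability is the important caveat: on the partial-husk branch alone,
`C_C` and `f_H` enter only through the product `(C_H − C_C)(1 − f_H)`, so a
series confined to `x < f_H` determines two parameters, not three. The fit
therefore requires the series to cross into the kernel plateau (`x > f_H`)
and raises an estimation error otherwise, rather than returning an arbitrary
point on the ridge. Standard errors come from the Jacobian at the optimum
(delta method, residual variance on `n − 3` degrees of freedom); residual
resampling gives optional percentile bootstrap intervals. At least four
distinct `x` values are required.

## Extraction simulator

The simulator is a four-pool mass balance (mg of THC): **matrix** (bound in
the seed), **surface** (extracted, sitting in the absorbed-oil film),
**oil** (recovered free oil) and **water** (wash-offs). Its premises:

* Only husk THC is oil-accessible during roasting — the kernel is shielded
  by the intact husk, which is the point of selective extraction. The
  accessible fraction is a parameter (default 1.0).
* Extraction follows first-order approach to equilibrium,
  `extracted = extractable · f_eq · (1 − e^{−k t})`, with the equilibrium
  split `f_eq = K·m_oil / (K·m_oil + m_seed)` and `K = 10^logP` scaled by an
  oil/octanol similarity factor (default 1.0). With cannabinoid logP values
  of 6–7, `f_eq ≈ 1`: the kinetic term dominates.
* Seeds absorb oil up to a fixed capacity (default 0.10 g oil per g seed).
  At 10 % oil the charge is fully absorbed and the run is flagged
  `no_free_oil`; at the standard 40 % run, 25 % of the oil stays behind,
  inside the 5–25 % retention observed for gravity separation. A single
  fixed capacity cannot also keep retention ≤ 25 % at every oil ratio; the
  flag behaviour was kept.
* Extracted THC routes predominantly to the absorbed-oil film (separated
  free oil shows no cannabinoid peaks in practice); the free-oil share is a
  parameter, default 0.10.
* Each wash transfers at most `wash_transfer_efficiency` (default 0.8) of
  the surface pool into the bath, capped so the dissolved bath concentration
  never exceeds the 2.8 mg/L aqueous solubility of THC. Reusing the bath
  accumulates solute and shrinks the headroom, so reuse always removes no
  more than fresh water — and under the strict solubility cap a single
  reused 20 mL bath cannot carry enough THC to decontaminate the default
  charge, which is why the shipped protocol uses fresh water per cycle
  (`reuse_water=False`). Physically, reused wash water likely carries
  emulsified oil as well as dissolved THC; that pathway is not modelled.
* Temperature is recorded metadata only (the protocol fixes 50 °C; no
  thermal degradation or THCA decarboxylation kinetics are modelled).

Residue concentration is reported on the dry-residue mass
(seed solids + absorbed oil). Mass is conserved to floating-point accuracy
across arbitrary stage sequences, and the residue is monotone non-increasing
in `k`, `K` and the number of washes — these are the simulator's testable
claims.

The stage constants `(k, capacity, free-oil share, wash efficiency)` are not
identifiable from endpoint residue data; they were fixed once by
`scripts/tune_extraction.py` so that the default protocol (5 g seed, 40 %
oil, 30 min, four 20 mL washes) lands mid-band in the compliant residue
range 1.5–3.3 mg/kg total THC (shipped default `k = 0.13 /min` gives
3.11 mg/kg). They should be treated as effective, protocol-level constants,
not physical measurables.

## Chromatogram quantification

Detection uses `scipy.signal.find_peaks` with height and prominence
thresholds (defaults 3.0 signal units each); maxima closer than 0.1 min are
merged, tallest wins. Each peak is integrated by the trapezoidal rule over a
±0.35 min region (truncated at the midpoint to a neighbouring peak) after
subtracting a linear baseline drawn between the region endpoints; each
endpoint anchor is the median of up to nine raw samples, so a single noisy
sample cannot tilt the baseline. The ±0.35 min half-width spans > 4 SD of
the generator's 0.08 min peaks; substantially broader peaks would need a
wider setting.

Assignment is by retention window. The anchored windows are: impurity/solvent
front < 2 min (excluded from potency), CBD 2.7–3.3 min, Δ8-THC 4.0–5.0 min,
Δ9-THC 5.0–6.0 min under PK16 (Δ9 near 7 min under the slower AOA
condition), with every analyte eluting by 10 min. The remaining 13 analytes
of the 16-cannabinoid panel get synthetic, non-overlapping windows inside
2–10 min; the full table is a repository convention, not a vendor table, and
user-supplied tables are validated for overlap.

Calibration is per-analyte ordinary least squares, intercept fitted (not
forced through origin), from an 8-level twofold serial dilution of a
50 mg/L stock standard mixture ("ppm" for solution standards is read as
mg/L; the ladder values are a repository convention). Quantification refuses
to extrapolate beyond 1.5× the top level. The residue workup dilution chain
4:1, 1:1, 1:1 (sample:diluent) composes to a factor of 5, applied at
back-calculation. Total THC is the sum of the Δ8 and Δ9 neutral forms; acid
forms (THCA-A etc.) are quantified and echoed but never totalled, since no
decarboxylation weighting is defined for this protocol.

## Synthetic data

Generators draw from a private `numpy.random.Generator` with an explicit
integer seed (no global state) and are bit-reproducible. Chromatograms are
sums of Gaussian peaks at the window centres (SD 0.08 min, area =
12.5 × concentration in mg/L), plus a broad impurity front at 1 min, a slow
sinusoidal baseline drift and additive Gaussian noise (default SD 0.2, i.e.
signal-to-noise well above 50 for the smallest calibrated peak). Seed lots
are truncated normals around the reference values; the spreads (f_H
SD 0.01, density-ratio SD 0.05, 300 ± 20 and 2 ± 0.2 mg/kg) are documented
conventions for plausible lot-to-lot variation. Peeling series add Gaussian
noise to the exact model curve and carry their generating parameters in
`DataFrame.attrs["truth"]`.

What passing closed-loop tests shows — and does not. The generators share
the forward model's functional form, so round-trip accuracy demonstrates
that the estimation and quantification machinery is correct and unbiased
under the stated noise model; it does not validate the spherical-mixing
model itself against real seeds, nor the integrator against real detector
artefacts (tailing, carryover, spectral shift are all out of scope).

## Problem sizes and numerical conventions

Default verification sizes: 10⁴ random parameter draws for the closed-form
vs bisection agreement (tolerance 1e−10), 1 000 random protocols for mass
conservation (1e−9 relative), 100 chromatograms for the 2 % quantification
round-trip, 200 seeded replicates (n = 50, noise SD 1 mg/kg) for the 3-SE
parameter-recovery coverage. Degenerate inputs are contracts, not crashes:
huskless seeds (`f_H = 0`) are legal everywhere, `x = 1` is legal for
geometry and density (nothing remains) but a domain error for concentration,
and zero-variance generator specs yield exact, degenerate samples.
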