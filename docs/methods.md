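# Methods

This note records the models, defaults and numerical choices behind the
package, and what the synthetic-data tests do and do not establish about
real instrument data.

## Units and conventions

Wavelengths are nm, molar extinction M⁻¹cm⁻¹, concentrations M, energies
J mol⁻¹, time hours.  Temperatures cross the interfaces in °C where the
experimentalist thinks in °C (anisotropy series, CLI flags) and are
converted to K internally; thermodynamic functions take K directly.
R = 8.3145 J mol⁻¹ K⁻¹.

## Spectra

A `Spectrum` is a strictly ascending wavelength grid with per-wavelength
values.  Band areas use the trapezoid rule on the native grid with
linearly interpolated endpoints, which makes the integral exactly additive
over contiguous subintervals; no smoothing is applied before integration.
Resampling is linear and refuses to extrapolate — nothing is invented
outside the measured range.  The second derivative is a local
quadratic-polynomial (Savitzky–Golay-type) differentiator with a default
7-point window, centred in the interior and one-sided at the edges; it is
exact for polynomials of degree ≤ 2 on arbitrary (also non-uniform) grids.
The window is a parameter because real absorbance noise levels vary.

The inner-filter correction uses the half-power form
`I_obs·10^((A_ex+A_em)/2)`, appropriate for a centred cuvette; the
absorbances are the *differences* caused by ligand addition at the
excitation and emission wavelengths, and the correction is applied
element-wise when A_em varies across the emission band.

## Quenching and binding fits

The Stern–Volmer constant is the OLS slope of I₀/I against [Q], I₀ taken
from the zero-quencher point.  Note that additive intensity noise becomes
multiplicative — and heteroscedastic — on the ratio scale, so the OLS
standard error is an approximation; the Monte-Carlo suite quantifies the
actual spread.  A negative fitted slope is reported but flagged
non-quenching rather than raised as an error.

The 1:1 isotherm `ΔI = (I₀−I_c)[L]/(1/K_a+[L])` is fitted by bounded
trust-region least squares (I_c ∈ [0, I₀], K_a > 0) with initial guesses
from the double-reciprocal linearization and up to 5 jittered restarts;
the best-cost solution wins and standard errors come from the covariance
at the optimum.  Total added ligand stands in for free ligand — valid only
in ligand excess, which is why the fit insists on a ≥ 5-fold concentration
span and why no depletion correction is offered.  With two temperatures
the van't Hoff parameters use the exact two-point closed form; with three
or more, a linear regression of ln K on 1/T.  ΔS is defined through
ΔG(T_ref) = ΔH − T_ref·ΔS so the triple is always self-consistent.

## FRET

The donor spectrum is normalized to unit area over its full recorded
range before the overlap integral; J is therefore invariant under donor
rescaling.  Donor and acceptor are resampled linearly onto the
intersection of their ranges at the finer of the two native steps, and
the λ⁴-weighted product is integrated by trapezoid.  Against a 100×-finer
brute-force grid the error is well below 0.1% for band widths ≥ 5 nm.
κ² = 2/3 (fast isotropic reorientation) and n = 1.425 (aqueous protein
solution) are defaults, not constants.  The package deliberately stops at
the `1.5·R₀` significance bound rather than inverting a transfer
efficiency into a distance: when quenching is predominantly static, the
efficiency is contaminated and the inversion would be spurious precision.

## Membrane partitioning

`ΔA ≥ 0` is defined as free-state minus observed absorbance (extinction
drops on membrane binding).  The saturation law is fitted either with
ΔA_max fixed from an independent bound-state extinction estimate (one
free parameter) or with both free.  The free mode is weakly identified
whenever the lipid range ends far below saturation — at K_p·γ·[lipid] ≈
0.4 the two parameters are nearly collinear — so the fit sets an
`upper_bound_flag` when the relative standard error of K_p exceeds 50%,
and downstream reporting should then quote only an upper bound.  The
second-derivative route (ΔA from second-derivative amplitudes) reuses the
same fit unchanged.

## Anisotropy

The logistic form `r(T) = r_high + (r_low−r_high)/(1+exp((T−T_m)/w))` is
a package choice — the transition is conventionally judged by eye — and
is recorded in the output metadata.  A fit whose amplitude is below 3
residual standard deviations raises a no-transition error instead of
returning a meaningless T_m.  G defaults to 1 when horizontal-excitation
components are absent, since many instruments pre-correct.

## Kinetics

Hydrolysis is modelled as a single first-order envelope with an optional
plateau; the two-step ring-opening cascade (prodrug → open-chain triazene
→ final amide) is intentionally not resolved, because the observable —
the 329 nm band — tracks only the first step's reactant.  A series whose
terminal value exceeds its initial value by more than 3× the
point-to-point noise is rejected as not-a-decay.

## Plasma distribution

Per-protein fractions assume one independent site per protein and protein
excess; they sum to 1 by construction.  The mass-balance mode solves
`free + Σ_i P_i·K_i·free/(1+K_i·free) = D_total` for the free drug by
Brent's method on [0, D_total], which brackets the unique root because the
left side is strictly increasing.

## Synthetic data

Generators emulate: a tryptophan emission band at 334 nm; drug absorbance
with 329/258 nm bands converting to a 265 nm product band; quenching
titrations from the Stern–Volmer (K_SV = 4837 M⁻¹ default) and isotherm
(K_a = 5103 M⁻¹) forward models; partition titrations on a 0–3 mM lipid
grid (K_p = 159, γ = 0.9, 8 points); polarized intensities encoding
plateaus 0.339/0.092 around T_m = 23 °C; and first-order decays.  Bands
are Gaussian because Gaussians have closed-form areas usable as
integration oracles; real bands are asymmetric, which matters for
absolute J values from real spectra but not for the fit code under test.
Noise is additive Gaussian with σ relative to the dynamic range —
photometric noise at these signal levels — with mandatory explicit seeds.
Monte-Carlo suites use 200 replicates at σ = 1–2%, sizes at which the
recovery medians are stable to well under the tolerances being checked.

What passing tests show: the estimators are unbiased and correctly
implemented for data generated by their own forward models, at realistic
noise.  What they do not show: robustness to baseline drift, scattering,
instrument response, or band asymmetry, none of which the generators
emulate.

## Degenerate inputs and tie-breaks

Quencher grids must start at 0 (defining I₀) unless I₀ is supplied;
partition grids must include 0 and ≥ 4 distinct concentrations; decay
series must start at t = 0.  The static/dynamic classification is a
strict inequality at the 2×10¹⁰ M⁻¹s⁻¹ ceiling (a value exactly at the
ceiling is still diffusion-compatible).  All nonlinear fits run with
trust-region tolerances of 1e-15 so that noiseless round trips recover
generator truth to ≲1e-9 relative.

## Known limitations

- Association constants from quenching conflate all partially quenched
  sites into one effective 1:1 site.
- The AGP Förster radius computed from the published overlap integral and
  quantum yield (20.4 Å) sits ~1.7% below the published ≈20.7 Å; the
  difference is consistent with rounding in published intermediates, and
  the package always reports the computed value.
- No circular-dichroism, docking or molecular-dynamics functionality:
  those are qualitative or handled by dedicated packages.
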