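# Methods

This note documents the models implemented in `spinatmos`, the conventions
and default parameters, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Coordinate and unit conventions

Internal units are nm, ns, Tesla and rad/s throughout; converters live only
at the I/O boundary (GRO is native nm; PDB Å are divided by 10 on read).
The slab normal is z. Cells are periodic in x/y only; the z direction
carries no periodic images, matching simulation setups that keep a vacuum
buffer between slab images. Each surface has a "zero plane" from which all
distances are measured, placed `carbon_offset = 0.2 nm` above the topmost
plane of bulk atoms of that slab — for an oxygenated diamond face this is
the mean height of the oxygen adlayer, and it makes distances comparable
across differently terminated surfaces. Frame spacing must be uniform;
non-uniform input is rejected rather than resampled, because the
autocorrelation estimator assumes a constant dt.

## Dipolar noise at a buried NV site

Averaging a paramagnetic ion's spin over its states, the variance of the
k-th Cartesian component of its dipolar field at distance r (nm) is
`C_S (1 + 3 k̂²)/r⁶` with `C_S = S(S+1)/3 · (μ₀/4π · γₑ ħ)²` expressed in
nm⁶T²; constants are CODATA values from `scipy.constants`, giving
`C_S = 1.00575×10⁻⁵ nm⁶T²` for S = 5/2. Contributions of independent ions
add. For NV ensembles under a {100} surface with no applied field, all four
NV orientations are equivalent on average and the variance transverse to
the NV axis is `⟨B⊥²⟩ = ⅔ (⟨Bx²⟩+⟨By²⟩+⟨Bz²⟩)`.

Useful exact identities (used as test oracles): for a single ion the
component sum is `6 C_S/r⁶` and `⟨B⊥²⟩ = 4 C_S/r⁶` independent of
direction; for a uniform ion density ρ filling the half-space at depth d,
`⟨B⊥²⟩ = (2π/3) C_S ρ / d³`.

Ion–NV displacements use the minimum image in x/y only. No lateral periodic
images are *added* inside the per-frame sum: the per-replica noise of a
single simulated molecule is the quantity of interest there, and long-range
coverage effects are handled separately by `coverage_extrapolation`, which
represents the adsorbed molecule's excess-ion cloud as a point cluster at a
configurable height (default 0.5 nm) above the surface and sums the exact
single-cluster `r⁻⁶` transverse variance over a square lattice of pitch
√(footprint area) out to a cutoff (default 20 pitches; the sum converges as
r⁻⁶). The point-cluster representation slightly overweights distant images
compared with replicating the full cloud; at the 3–4 nm pitches of a dense
monolayer the difference is far below the order-of-magnitude level at which
the extrapolation is quoted.

A guard distance of 0.3 nm between any paramagnetic ion and the NV site
turns corrupt frames into errors instead of r⁻⁶ blow-ups; no physical
configuration places a solution ion that close to a buried defect.

## Relaxation model and contrast proxy

GHz noise with Lorentzian spectrum shortens the NV longitudinal relaxation:

    Γ₁ = 1/T1ⁱⁿᵗ + 3 γₑ² ⟨B⊥²⟩ · τc/(1 + ω₀² τc²),   ω₀ = 2πD,  D = 2.87 GHz.

The spectral factor peaks at τc = 1/ω₀ ≈ 55 ps. τc is the autocorrelation
time of the fluctuating field, set by the paramagnetic-spin dynamics; its
microscopic prediction for surface-bound Mn²⁺ is out of scope here, so τc
is always an input parameter (typically swept over 10 ps–1 ns). Γ₁ is a
rate in s⁻¹; "kHz" values divide by 10³ with no 2π.

The fluorescence decay is modelled as `F(τ) = 1 + A exp(−Γ₁τ)` — a single
exponential with constant baseline. Shallow NV ensembles often show
stretched-exponential relaxation; the single exponential is chosen for
invertibility and because the downstream observable is the two-point
contrast `C = F(τ₁)/F(τ₂)` at τ₁ = 10 µs, τ₂ = 400 µs, which is monotone in
Γ₁ up to Γ* = ln(τ₂/τ₁)/(τ₂−τ₁) ≈ 9.5×10³ s⁻¹ and only weakly sensitive to
the decay shape. Contrast readings are referred to 25 °C by
`C* = C − (T−25)·0.0012 /°C`. Assay arithmetic: amount = concentration ×
channel volume (10 pM × 12 mm³ = 120 amol); the number of molecules needed
to supply a threshold count of adsorbed ions uses a ceiling (⌈180/8⌉ = 23),
since a fractional molecule cannot adsorb.

## Ion-atmosphere analysis

Density profiles are time-averaged histograms along z normalized by
`Lx·Ly·bin_width` (default bin 0.1 nm), measured from the adsorption-side
surface (bottom by convention for non-adsorbed replicas). Region
integration splits partial bins pro-rata and reports means and standard
deviations across frames; the default regions (0–4), (4–9.5), (9.5–15),
(15–19) nm fix only the two outer ones physically (adsorption side vs bare
side); the interior split is symmetric and arbitrary. The excess
accumulation is the difference of two equal-width region counts, with a
standard error computed under an independent-frames assumption — correlated
frames (as in a real MD trajectory) would need a statistical-inefficiency
correction the caller must supply.

Adsorption is operationally defined as: the molecule's minimum atom–surface
distance stays below `contact_cutoff` (default 0.35 nm, a first-solvation
contact) continuously for at least `persistence` (default 1 ns); the onset
is the first instant of that window and the side is the surface achieving
it. Shorter excursions above the cutoff before a later persistent window
simply postpone the onset. This cutoff + persistence rule is a declared
convention of this package, not a community standard.

## Electrolyte theory

The Debye length is `κ⁻¹ = √(εε₀kBT / e²Σᵢnᵢzᵢ²)` (0.78 nm at 150 mM 1:1,
1.92 nm for 5 mM MnCl₂ + 10 mM NaCl at 298 K, ε_r = 78.4; temperature
dependence of ε is not modelled). Surface potentials come from the Grahame
relation `σ² = 2εε₀kBT Σᵢ nᵢ(e^{−zᵢeψ₀/kBT} − 1)` solved by a bracketing
root-finder with sign(ψ₀) = sign(σ) — exact within mean-field PB for any
ion mixture, and verified against the Gouy–Chapman closed form (1:1) and
the Debye–Hückel linear limit. Ion profiles integrate the first integral of
the 1-D PB equation outward with `solve_ivp` (rtol 1e-10); excess ion
numbers are area-weighted trapezoid integrals of c(z) − c_bulk and satisfy
the screening sum rule Σzᵢ·excessᵢ = −σA to better than 1%.

A synthetic RNA oligo of L nucleotides with no terminal phosphate carries
−(L−1) e (the 22-mer assayed here: −21 e).

Integer ion budgets for a box: bulk counts are round-half-to-even of cᵢV
over the water volume; each charged plane contributes its rounded PB excess
counts; an anionic molecule is neutralized divalent-first (⌊21/2⌋ = 10 Mn²⁺
+ 1 Na⁺ for −21 e); any ±1 e rounding residual is absorbed into the most
abundant monovalent species. Every adjustment is logged in the budget's
provenance notes and the final system (ions + surfaces + molecule) is
exactly neutral.

## Synthetic generators

The generators provide every input the analysis needs, with known ground
truth, under a fixed default scenario: a 10 × 10 × 20 nm³ cell whose two
surfaces sit 0.5 nm from the box edges (19 nm of solution), 5 mM MnCl₂ +
10 mM NaCl, a 22-bead polyanion carrying −21 e, and surfaces that are
either neutral or charged (−32 e or −65 e per face), with functional-group
area fractions 64.5% hydroxyl/epoxy, 20.2% carbonyl, 13.7% ether, 1.6%
carboxyl placed deterministically on a lattice (only carboxyls can carry
charge, −1 e each when deprotonated).

- **OU field**: exact discretization
  `x_{n+1} = x_n e^{−dt/τc} + σ√(1−e^{−2dt/τc}) ξ_n`, stationary from the
  first sample. Its autocovariance is exactly `⟨B²⟩e^{−|τ|/τc}` and its
  one-sided PSD is `4⟨B²⟩τc/(1+(2πf τc)²)`, which cross-validates the
  Lorentzian spectral factor of the relaxation model.
- **Static samplers**: Poisson-count uniform placements, independent per
  frame. The half-space variant defaults to a laterally large box
  (oracles compare against the infinite-half-space integral, so lateral
  minimum-imaging must not truncate it; with a 140 nm box at 7 nm depth the
  truncation bias is ~0.2%, far below the Monte-Carlo error).
- **Planted accumulation**: uniform background ions (the full electroneutral
  budget) plus n excess Mn²⁺ placed laterally Gaussian (σ = 1.5 nm) around
  the molecule footprint within a z region, resampled per frame; the static
  bead blob defines molecule selections. Recovery of the planted n by the
  profile/region analysis is unbiased (regression slope 1.00 across
  n ∈ {2,4,8,16} × 20 seeds).
- **Brownian-dynamics surrogate**: overdamped Langevin update
  `Δx = (D/kBT)F dt + √(2D dt) ξ` with screened-Coulomb (Yukawa) pair
  forces `U/kBT = l_B z₁z₂ e^{−κr}/r` between all charges (ions, beads,
  discrete deprotonated-carboxyl surface sites), linearly capped inside the
  soft-core radius so opposite charges cannot collapse onto point sites;
  soft-core excluded volume (0.35 nm, 5 kBT); harmonic bonds (0.6 nm,
  100 kBT/nm²); a Gaussian adsorption well at each surface acting on beads
  (default depth 4 kBT per bead, width 0.35 nm — free calibration knobs
  with no first-principles values; chosen so that adsorption, once
  established, does not reverse); reflective z walls at the zero planes,
  periodic x/y. Default diffusion constants: Mn²⁺ 0.7, Na⁺ 1.3, Cl⁻ 2.0
  nm²/ns (literature-order aqueous values), beads 0.4 nm²/ns (monomer-like;
  the chain's centre of mass then diffuses with D/N as in Rouse dynamics —
  slower than a real oligonucleotide with hydrodynamic coupling, which only
  lengthens adsorption times, not equilibria). Timestep 1 ps; a
  deterministic displacement above 0.25 nm in one step aborts the run with
  diagnostics. The integrator satisfies the Einstein relation (MSD slope
  2D per axis within 5%) and reproduces Boltzmann stationary profiles in
  external 1-D potentials.

**What the surrogate is not.** It deliberately replaces all-atom
replica-exchange MD: there is no explicit water (hence no interfacial water
adlayer and no surface depletion of Mn²⁺), no atomistic force field, no
replica exchange, and Ewald electrostatics are replaced by mean-field
Yukawa screening. It exists to exercise the analysis stages on data with
planted, recoverable truth. Passing tests therefore demonstrate that the
*analysis* is correct and unbiased, not that the surrogate reproduces
all-atom observables (per-molecule excess of 8–9 Mn, 40–80% adsorption
rates, ~10⁻⁹ T² noise increments); those remain properties of full MD and
experiment. In the surrogate's bare-repulsion variant (ions excluded from
the integration), a −21 e chain adsorbs more readily on neutral than on
−65 e surfaces, as electrostatics dictates; with ions included, accumulated
Mn²⁺ can mediate attraction to charged surfaces, and the ordering is not
guaranteed.

## Numerical and design choices

- Autocorrelation fits use the biased (1/N) autocovariance via FFT, an
  initial 1/e-crossing estimate of τc, a fit window of 5× that estimate,
  and one refit with the updated window — stable for short series at the
  cost of a small downward bias at long lags. Constant series and series
  that decorrelate within one sample are flagged, never silent NaNs.
- Sub-stream seeds are derived from the root seed by hashing the stage
  name (SHA-256, reduced below 2³¹), so stages are independently
  reproducible and adding a stage does not shift the others' streams.
- The pipeline's outputs all carry the config hash and seed; re-running the
  same config and seed is byte-identical.
- Sizes used by the default checks: the Monte-Carlo half-space comparison
  uses ~10⁷ ion samples over 2400 independent frames (standard error
  ≈ 0.7%, well inside its 2% band); OU validation uses 10⁶ steps; planted
  recovery uses 150 frames × 20 seeds × 4 levels. The bundled demo pipeline
  is smaller and completes in seconds.

## Known limitations

- τc for bound vs free Mn²⁺ is an input, not predicted; all Γ₁ forecasts
  are parametric in it.
- The PB treatment is mean-field: no ion correlations, finite-ion-size or
  Manning-condensation effects, and fixed protonation states.
- The two-point contrast proxy saturates and becomes non-monotone above
  Γ* ≈ 9.5×10³ s⁻¹ for the default delays; quantitative work beyond that
  range needs full decay fits.
- The coverage extrapolation assumes an ordered square lattice of identical
  adsorbates; real monolayers are disordered, which changes the prefactor
  but not the order of magnitude.
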