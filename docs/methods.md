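# Methods

## Scope and model

`dropsf` treats a phase-separated protein solution as a binary mixture of
one effective homopolymer (the protein, N segments) and a one-site solvent.
That single approximation underlies every stage: the density-conservation
regression assumes two phases of fixed composition; the Flory–Huggins (FH)
free energy per lattice site,

    f(φ) = (φ/N) ln φ + (1−φ) ln(1−φ) + χ φ(1−φ)   (units of kT),

absorbs all protein–protein and protein–solvent interactions into one χ;
and the Scheutjens–Fleer (SF) lattice theory extends the same f to
composition gradients across the condensate surface. Electrostatics,
sequence specificity, and multi-component effects enter only implicitly,
through the measured χ.

## Sessile-drop analysis

The meridian of an axisymmetric drop that is denser than its surroundings
obeys dψ/ds = 2/R₀ + h/ℓc² − sin ψ/r with dr/ds = cos ψ, dh/ds = sin ψ,
origin at the apex and depth h measured downward. The positive gravity term
is the sessile convention for a denser drop; the spherical cap is recovered
as ℓc → ∞. Numerics: fixed-step classical Runge–Kutta (default step
s_max/4000, numba-compiled); the apex 0/0 in sin ψ/r is replaced by its
limit 1/R₀ and the first step leaves the apex on the circular series
ψ = s/R₀. Integration truncates where ψ reaches π: beyond that the
mathematical solution re-enters the physical domain and would corrupt any
interpolation over depth. Volumes are ∫ π r² sin ψ ds to the first s
reproducing the measured drop height, with a 2% tolerance for
pixel-quantized heights that slightly exceed the closure depth.

Edge extraction normalizes intensities (making the result invariant to
affine intensity changes), requires exactly one dark silhouette
(Otsu + connected components; several silhouettes mean the sample needs
re-coalescence), then runs Canny detection with a single sensitivity scalar
mapped to the hysteresis thresholds. The symmetry axis minimizes the mean
left/right radius mismatch; a residual asymmetry above 2% (configurable)
rejects the drop as tilted. Radii get a running-mean filter of radius 5
samples per branch before the branches are folded into one (r, h) profile.

Fitting minimizes the summed nearest-neighbour distance between edge points
and a densely sampled meridian (4000 points) integrated to 1.8× the edge
path length, by Nelder–Mead in (ln R₀, ln ℓc) from three starts (an
osculating-circle R₀ estimate; ℓc at 0.5/1/2× the drop height). A
squared-distance objective is available as an option; on our synthetic
benchmarks the two agree to well within the noise-induced scatter. Two
identifiability guards flag (not fail) weakly deformed drops: drop height
below 0.3 ℓc, and fitted ℓc beyond 20 drop heights (spherical cap — γ is
unidentifiable without gravitational deformation).

## Densitometry

ν_β/ν₀ = (ρ₀ − ρ_α)/Δρ is fitted by ordinary least squares of the volume
ratio on sample density; Δρ = 1/slope, ρ_α is the x-intercept, and both
standard deviations come from the regression covariance (the intercept
ratio via the full 2×2 covariance). Errors-in-variables refinements are out
of scope. γ = Δρ g ℓc² with g = 9.81 m s⁻² and relative uncertainty
√((σ_Δρ/Δρ)² + (2σ_ℓ/ℓc)²). Ideal-mixing density
ρ = (1−φ)ρ_s + φ m_p/v̄_p and φ = c·v̄_p interconvert densities, volume
fractions and molar concentrations; the dense-phase concentration inverts
the same relation, c_β = c_α + Δρ/((m_p/v̄_p − ρ_s)·v̄_p).

## Flory–Huggins binodal and curvature correction

Coexistence equates the solvent chemical potential
ln(1−φ) + (1−1/N)φ + χφ² and the per-chain polymer chemical potential
ln φ − (N−1)(1−φ) + χN(1−φ)² between branches. The solver exploits that
both potentials are monotone in φ outside the spinodal: for each candidate
φ_α the dense partner is a bracketed 1-D root of the solvent equality, and
the polymer-potential mismatch is then monotone in ln φ_α. Searching in
ln φ_α handles dilute branches of order 10⁻⁴ and below without scaling
trouble; residuals at the solution are at machine precision. The critical
point is the closed form φ_c = 1/(1+√N), χ_c = ½(1+1/√N)².

A droplet of dense phase with radius R carries a Laplace pressure
ΔP = 2γ/R that adds v_p·ΔP (v_p = molecular volume per chain) to the
polymer chemical potential inside; re-solving coexistence with that offset
(in kT) shifts the dilute branch up by a relative amount ≈ v_p ΔP/kT — of
order 10⁻⁵ for condensate-scale drops, which is why the flat-interface
binodal is used everywhere else.

`extract_chi` inverts the binodal against a measured observable. Because a
measured (φ_α, φ_β) pair generally does not sit exactly on any FH binodal,
four modes are provided (match the dilute branch, the dense branch, the
gap, or a joint least squares); `match_dilute` is the default since the
dilute branch is the more precisely measured quantity. The modes differ by
roughly ±0.01 in χ for our data, which translates to ~15% in the
theoretical γ — worth keeping in mind when comparing theory to experiment.

## Scheutjens–Fleer lattice solver

One-dimensional gradient lattice, L = 200 layers, mirrored boundaries,
fraction λ = 1/6 of neighbour sites in each adjacent layer (cubic lattice).
Chains are first-order Markov walks: propagators obey
G(z,s|1) = G(z)·⟨G(z,s−1|1)⟩ with G = e^(−u); the composition law
φ(z) ∝ Σ_s G(z,s|1)G(z,N−s+1|1)/G(z) is normalized canonically to the
fixed amount θ = mean_phi·L (default 0.06·200 = 12, the equivalent of 12
chains per column for N ≈ 235 — just below the critical volume fraction
0.061). Incompressibility is enforced exactly by eliminating the solvent,
φ_s = 1 − φ_p, which folds the Lagrange field into the exchange potential
u = χ(1 − 2⟨φ_p⟩) − ln(1−φ_p) up to constants absorbed by the canonical
normalization.

Iteration: Anderson mixing (history 6, mixing 0.2) over the substitution
map, with a damped-substitution polish as fallback. Plain damped
substitution — the obvious first choice — develops limit cycles at deep
quenches (χ ≳ 0.65 for N ≈ 235) at any damping large enough to be useful,
which is why an accelerated scheme is used. Convergence is the fixed-point
residual max|φ_new − φ| < 10⁻⁹; non-converged results are flagged, never
silently returned. Cold starts confine the polymer to the first 30 layers
(widened automatically if that would overfill them); production runs use
the continuation protocol: converge at χ = 0.741658, then step χ down by
0.005 (exact target values merged into the grid), warm-starting each solve
from the previous profile, stopping below χ_c. This keeps exactly one
interface in the box, which is verified by counting mid-composition
crossings — a criterion chosen because sharp lattice interfaces develop
genuine damped layering oscillations that a naive monotonicity test
misreads as extra interfaces.

Free energy and surface tension: the canonical free energy of the box is
F = n_p ln n_p − n_p − n_p ln Q_p − Σ u φ + Σ[φ_s ln φ_s − φ_s]
+ χ Σ φ⟨φ_s⟩ (gauge-invariant in u; constants linear in the conserved
amounts are dropped consistently). The surface tension is the excess over a
lever-rule split of the same material into the two coexisting bulks,
γb²/kT = F_box − L_α f(φ_α) − L_β f(φ_β), which equals F − Σμᵢnᵢ minus the
bulk grand potential because the lever rule conserves both species. SI
conversion multiplies by kT/b² with b = 5.12 Å and T = 295.15 K. The
lattice size is the cube root of the molar volume per residue; full
precision is 5.13 Å for both constructs, and the conventional 3 s.f. value
5.12 Å is the default input. Converged plateaus reproduce the independent
binodal solver to better than 10⁻⁵ — the strongest internal consistency
check between the two halves of the package.

For arbitrary (non-self-consistent) profiles the same free energy is
evaluated by inverting the density→field map per profile (a batched fixed
point u ← u + ½ln(φ[u]/φ_target)); chain conformational entropy is not a
local functional of φ for N ≥ 2, so this inversion is the honest way to
give every admissible profile a free energy. On tiny lattices the converged
solution (best of several cold starts — interface position is a soft mode
in a short box) undercuts 10⁵ random admissible profiles, a direct
variational check of the solver.

Interfacial width: least squares of φ(z) = a − b·tanh(2(z−z₀)/w) with z in
nm. Among the factor-of-two tanh conventions in the interface literature,
this is the one whose w matches the values quoted for these systems
(3.5/4.4 nm for the two constructs); the plain tanh((z−z₀)/w) convention
gives exactly half. End-segment profiles use the per-rank composition
φ(z,s); ranks 1 and N, rescaled to [0,1] alongside the all-segment profile,
show the characteristic enrichment of chain ends on the dilute side —
ends pay less conformational free energy than inner segments to stray into
the polymer-poor phase.

## Synthetic data

The generator is the package's study condition, not a tuning knob. Drops
are rendered at R₀ ≈ 150 µm (±10% across replicates), ℓc = 293 µm,
1.3 µm/px — the scale of centrifugally coalesced condensates — with
sub-pixel edge coverage, Gaussian blur (1 px) and 1% i.i.d. intensity
noise; 13 replicate drops and 13-sample density series
(Δρ = 97 kg m⁻³, ρ_α = 1000.2 kg m⁻³, absolute ratio noise 5×10⁻⁴,
ρ₀ spanning ~10–40% of Δρ above ρ_α) mirror the replication level of a
realistic experiment. What the renders do not emulate: uneven illumination,
textured backgrounds, diffraction fringes, substrate reflections and
evaporation drift. Passing tests therefore validate the geometry and
statistics of the workflow, not its robustness to every optical artefact.

## Numerical choices and degenerate inputs

Binodal brackets are machine-tight (brentq at 4·eps relative); χ extraction
brackets (χ_c, 2χ_c]. Flat or subcritical SCF states short-circuit to the
uniform reference (γ = 0). Blank images, multiple silhouettes, tilted
drops, collinear edges, non-positive regression slopes, unphysical volume
fractions (φ > 1) and confinement overfills all raise typed errors early.
Fits report convergence flags rather than raising on optimizer stalls.
Problem sizes in tests (tiny lattices L ≤ 12 for the variational oracle,
three-drop pipelines for orchestration checks, 13-drop runs for recovery
statistics) are chosen so each check isolates one claim at the smallest
size where it is meaningful.

## Known limitations

- The homopolymer–solvent picture caps the achievable accuracy: the
  mean-field theory overestimates condensate surface tension by a factor
  of 1.4–1.7 at the measured χ, and that factor is the scientifically
  interesting residual, not a bug.
- χ extraction from an overdetermined (φ_α, φ_β) pair is
  convention-dependent at the ±0.01 level (see modes above).
- The shape fit assumes a single axisymmetric drop with near-180° contact
  angle and does not model contact lines.
- Lattice results at deep quench (interface ≲ 2 layers) show layering
  artefacts inherent to the lattice; widths there are convention-dominated.
- The bundled Ddx4N FASTA records are designed synthetic stand-ins with the
  constructs' composition statistics and charge step, not the real
  sequences; tabulated constants (masses, molar volumes, extinction
  coefficient) are the real ones.
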