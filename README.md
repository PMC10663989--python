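# dropsf

Surface tension of model biomolecular condensates, measured and calculated.

Liquid–liquid phase separation of intrinsically disordered proteins (IDPs)
such as the N-terminal region of Ddx4 produces protein-rich liquid droplets
("condensates") whose surface tension γ — typically 10–100 µN m⁻¹ — governs
their wetting, coalescence and internal organisation. `dropsf` implements a
complete workflow for determining γ from bright-field images of sessile
condensates, and for computing it from mean-field polymer theory:

1. **Sessile-drop shape analysis.** Gravity deforms a condensate that is
   denser than the surrounding dilute phase. The axisymmetric Young–Laplace
   (Bashforth–Adams) meridian

   dψ/ds = 2/R₀ + h/ℓc² − sin ψ / r,  dr/ds = cos ψ,  dh/ds = sin ψ

   is fitted to the drop contour extracted from an image, yielding the apex
   radius R₀, the capillary length ℓc = √(γ/(Δρ g)) and the condensate
   volume ν_β.

2. **Densitometry.** Mass/volume conservation makes the condensate volume
   fraction linear in sample density: ν_β/ν₀ = (ρ₀ − ρ_α)/Δρ. A linear
   regression over a concentration series gives the density difference Δρ
   and dilute-phase density ρ_α, hence γ = Δρ g ℓc².

3. **Flory–Huggins thermodynamics.** The coexisting volume fractions
   (φ_α, φ_β), obtained from the measured densities, define a mean-field
   interaction parameter χ through the binodal of
   f(φ) = (φ/N) ln φ + (1−φ) ln(1−φ) + χ φ(1−φ), including the (tiny)
   Laplace-pressure curvature correction of the equilibrium.

4. **Scheutjens–Fleer lattice theory.** A self-consistent-field solver for
   a polymer–solvent interface on a 1-D gradient lattice (mirrored
   boundaries, cubic lattice λ = 1/6) computes the equilibrium profile
   φ(z), the surface tension from the excess grand potential γb²/kT, the
   interfacial width from a tanh fit φ(z) = a − b·tanh(2(z−z₀)/w), and
   end-segment distributions.

A synthetic-data module renders gravity-deformed drop silhouettes from
known (R₀, ℓc) and draws conservation-law density batches, so the entire
pipeline is testable without laboratory data.

## Worked example

Surface tension from measured capillary length and density difference
(values for the two Ddx4N constructs, 150 mM NaCl, 20 mM Tris pH 8, 22 °C):

```
$ dropsf tension --delta-rho 97 --lc 293 --delta-rho-sd 10 --lc-sd 6
gamma = 81.7 +/- 9.1 uN/m
$ dropsf tension --delta-rho 69 --lc 237 --delta-rho-sd 5 --lc-sd 5
gamma = 38.0 +/- 3.2 uN/m
```

Δρ = 97 kg m⁻³ with ℓc = 293 µm gives γ ≈ 82 µN m⁻¹; the lower-contrast
construct (Δρ = 69, ℓc = 237) gives 38 µN m⁻¹. The uncertainty combines the
regression error on Δρ with twice the relative error on ℓc.

Flory–Huggins coexistence for a 234-segment chain at χ = 0.641:

```
$ dropsf binodal --n 234 --chi 0.641
{
  "phi_alpha": 0.00036209528817967397,
  "phi_beta": 0.2942404835839649,
  "phi_c": 0.06136076626943499,
  "chi_c": 0.5675087971828134
}
```

The lattice-theory interface at the same state point, via the warm-started
χ continuation (start at χ = 0.741658 with polymer confined to 30 layers,
step down by 0.005 through the target):

```python
from dropsf.scf import SCFConfig, continuation_sweep

base = SCFConfig(chain_length=234, chi=0.641)   # 200 layers, b = 5.12 A
sweep = continuation_sweep(base, chi_extra=[0.641], chi_stop=0.641 - 1e-12)
res = min(sweep, key=lambda r: abs(r.chi - 0.641))
print(f"gamma = {res.gamma_si:.1f} uN/m, width = {res.width_fit.width:.2f} nm")
```

```
gamma = 119.1 uN/m, width = 3.48 nm
```

The theory overestimates the measured 82 µN m⁻¹ by a factor ≈ 1.45 — the
semi-quantitative accuracy expected of a mean-field homopolymer model — and
puts the interfacial width at ≈ 3.5 nm, a few protein hydrodynamic radii.
A fully synthetic end-to-end run (13 rendered drops plus a noisy density
series) is one command:

```
$ dropsf run --config examples/synthetic.yaml
```

and recovers the ground-truth γ to within a few percent.

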