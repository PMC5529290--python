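# ttvsa

Sub-diffraction sizing of cardiac transverse-axial tubules (t-tubules, TTs)
from dual-dye 3D confocal stacks, via the volume-to-surface-area (V:SA)
ratio.

T-tubules carry the action potential into the interior of cardiac myocytes.
Their diameters (roughly 40–700 nm) sit below the diffraction limit of
confocal microscopy, so they cannot be measured by drawing a line profile.
They can, however, be *sized*: with one fluorescent dye filling the tubule
lumen (an extracellular volume marker such as calcein) and a second dye on
the tubule membrane (e.g. FM4-64), the ratio of the two signals on the
tubule skeleton reports the luminal volume per membrane area — and for any
fixed cross-sectional shape that ratio is linear in diameter.

## The model

After (1) background subtraction, (2) blurring the stack laterally so the
effective point-spread function is spherical with FWHM equal to the raw
axial FWHM ("PSF symmetrization" — without it the reading depends on tubule
orientation), and (3) normalizing the volume channel to the bath and the
membrane channel to the surface sarcolemma (SS), the ratio at a TT skeleton
voxel obeys, for a sub-resolution circular cylinder of diameter D,

    V:SA = (D / (2·FWHM)) · √(ln 2 / π)

so the V:SA → diameter conversion is linear with slope
√(ln2/π)/(2·FWHM) ≈ 0.39 per μm at FWHM ≈ 0.6 μm, and V:SA at the SS
itself is 0.5 by construction (half of a blurred step).  The package also
carries the exact blurred-cylinder law

    V:SA(D) = σ·(e^x − 1)/(a·√(2π)),   a = D/2,  x = a²/(2σ²),  σ = FWHM/2√(2 ln 2)

whose small-D limit is the linear form; inverting it (the default
`diameter_model="cylinder"`) keeps the estimate accurate as D approaches
the FWHM.  An elliptical cross-section of given ellipticity E can be
matched to the same area-to-perimeter ratio in closed form via the complete
elliptic integral.

Everything is validated end to end on synthetic phantoms: scenes of known
tubule diameter, ellipticity and orientation are rendered through the same
optics (sub-voxel rasterization, anisotropic Gaussian PSF, optional noise)
and pushed through the full measurement chain.

## Worked example

```python
from ttvsa import RunConfig, run_pipeline

config = RunConfig(
    phantom=dict(
        shape=(48, 128, 128),
        voxel_um=(0.18, 0.06, 0.06),          # (z, y, x), μm
        cell=dict(axis="x", surface_um=1.53, long_axis="y"),
        tubules=[dict(points_um=[[4.33, 1.0, 4.53], [4.33, 6.7, 4.53]],
                      diameter_um=0.17)],      # a 170 nm tubule
        noise="none",
    ),
    psf_fwhm_um=(0.25, 0.25, 0.6),             # raw confocal PSF (x, y, z)
)
report = run_pipeline(config)
s = report.vsa_summary
print(f"V:SA  = {s['vsa_mean']:.4f} (n={s['n_voxels']} voxels)")
print(f"D_TT  = {s['diameter_mean_um']*1000:.0f} nm  (truth: 170 nm)")
```

prints

```
V:SA  = 0.0685 (n=97 voxels)
D_TT  = 170 nm  (truth: 170 nm)
```

i.e. a 170 nm tubule — almost a factor of four below the symmetrized
resolution of 600 nm — is recovered exactly by the intensity-ratio method,
because the blur conserves both the luminal volume integral and the
membrane area integral.  The report also carries network geometry (skeleton
length density, transverse/axial/oblique fractions, membrane-area and
volume fractions) and passive cable properties (λ_dc = √(D·R_m/4R_L) and
its frequency-dependent reduction), here λ_dc ≈ 240 μm and ≈ 124 μm at
150 Hz for the same tubule diameter.

A command-line interface mirrors the library:

```bash
ttvsa phantom render --config scene.yaml --psf psf.yaml --seed 1 --out out/
ttvsa psf measure beads.tif --bead-um 0.17
ttvsa vsa run --config run.yaml --out out/
ttvsa vsa compare groupA.json groupB.json
ttvsa cable --species-config rabbit.yaml
```

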