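# optpal

Optical palpation elastography for OCT compression series: from raw image
volumes to calibrated maps of tissue surface stress.

## The problem

Early gastric cancers — notably the signet ring cell carcinoma foci of
hereditary diffuse gastric cancer — are stiffer than surrounding tissue but
nearly invisible to white-light inspection. Optical palpation is a
simplified compression variant of optical coherence elastography (OCE): a
thin, transparent silicone **reference layer** of known stress–strain
behavior is placed on the tissue and the stack is compressed axially
against a glass slide while OCT volumes are collected. The layer acts as an
optical stress sensor: it compresses more over soft tissue and less over
stiff tissue, so its local strain, read out from the OCT image, maps the
stress applied at the tissue surface.

`optpal` implements that analysis as a tested, reusable Python pipeline,
together with a synthetic compression-phantom generator that provides exact
mechanical ground truth for validation, since raw clinical OCT volumes are
not generally available.

## The model

Assuming uniaxial, depth-uniform stress shared by the layer (subscript 1)
and tissue (subscript 2):

    σ = σ₁ = σ₂ = E₁·ε₁ = E₂·ε₂

The layer strain at each lateral position is

    ε₁ = ΔL / L

where `L` is the reference-layer thickness at the **preload** state (onset
of a distinct, linear thickness decrease with stage travel) and `ΔL` is its
change three 100 µm stage increments (300 µm) later, at the **compressed**
state. Thickness is measured per A-scan as the distance between the two
highest prominence-gated intensity maxima — the Fresnel reflections at the
glass/layer and layer/tissue interfaces. Strain converts to stress through
the reference material's calibration curve, whose low-strain slope is the
layer modulus `E₁` (≈ 49 kPa for the silicone formulation modeled here).
Stress maps are smoothed with a masked 3-pixel Gaussian blur and an
adaptive Fourier band-stop that removes the depth-pixel quantization
stripe artifact.

## Worked example

```python
import numpy as np
from optpal import (PhantomSpec, RunConfig, analyze_volumes, build_curve,
                    fit_modulus, generate_calibration_data, generate_series)

# a phantom: 600 um silicone layer (E1 = 49 kPa) on uniform 60 kPa tissue,
# one dead-zone increment before firm contact, six 100 um stage steps
spec = PhantomSpec(nx=48, ny=48, nz=256, E1=49.0,
                   tissue_modulus_map=60.0, tissue_thickness_map=800.0,
                   dead_zone_increments=1, n_increments=6, rng_seed=42)
vols, truth = generate_series(spec)

# three replicate force-sensor calibration runs at 1% force noise
rng = np.random.default_rng(42)
reps = [generate_calibration_data(spec, force_noise_frac=0.01, rng=rng)
        for _ in range(3)]
curve = build_curve(reps)
e1, r2 = fit_modulus(curve)
print(f"fitted modulus E1 = {e1:.2f} kPa (R^2 = {r2:.4f})")

res = analyze_volumes(vols, curve, RunConfig(edge_margin_um=0.0))
print(f"preload index     = {res.preload_index}")
print(f"mean stress       = {res.mean_stress_kpa:.2f} kPa "
      f"(ground truth {truth.sigma[res.compressed_index].mean():.2f} kPa)")
```

prints

```
fitted modulus E1 = 49.37 kPa (R^2 = 1.0000)
preload index     = 1
mean stress       = 11.77 kPa (ground truth 11.73 kPa)
```

The fitted modulus recovers the generator's 49 kPa ground truth from noisy
force measurements; the preload lands at the true dead-zone end; and the
mean surface stress of the smoothed map agrees with the exact two-spring
mechanics to well under the depth-quantization bound.

## Command line

```bash
optpal simulate  --spec phantom.yaml --seed 5 --out run/          # phantom + calibration CSVs
optpal calibrate --out run/cal run/calibration_rep*.csv           # E1 fit + curve plot
optpal analyze   --series run/series --curve run/cal/calibration_curve.json --out run/ana
optpal summarize --out run/summary run/ana/mean_stress.csv        # per-class mean ± SD
```

Every command writes a manifest (inputs, config hash, seed, versions) so
deterministic outputs are bit-reproducible.

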