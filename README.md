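# nmjquant

Quantification of synaptic-vesicle distribution in *Drosophila* larval
neuromuscular-junction (NMJ) boutons from calibrated fluorescence
Z-stacks — for neurobiology labs measuring how vesicle pools
redistribute with synaptic activity.

At the *Drosophila* NMJ, anti-HRP staining outlines the presynaptic
membrane of each bouton, vesicle markers such as CSP appear as
punctate staining inside it, and activity-dependent mobilization moves
vesicles toward the periphery where the active zones sit. `nmjquant`
turns such images into per-bouton numbers:

- **Bouton segmentation** from the membrane channel, with physical
  areas (pixel count × pixel size²), the type-Ib size filter
  (2.5 ≤ A ≤ 12 µm², inclusive), and a Gaussian-mixture model of the
  size distribution selected by BIC.
- **CSP particle detection** — local maxima of the vesicle channel
  (8-connected, deterministic plateau rule) — and particle densities
  in the **peripheral zone** (all pixels within 200 nm of the bouton
  edge, by Euclidean distance transform) versus the **central zone**
  (the rest): `d_zone = N_zone / A_zone` in particles/µm².
- **Radial density profiles**: successive 3×3 morphological erosions
  decompose the footprint into shells, grouped into bands of 10% (or
  25%) of the bouton area from periphery to center; plus the
  **mobilization ratio** `d_stimulated / d_unstimulated` per zone or
  band.
- **Background-corrected intensity**: mean over the ROI across the
  center slice ± 2 flanking slices, minus a remote/local/combined
  background, normalized so the control group's mean is exactly 1.
- **FM1-43 destaining**: `unload_fraction = 1 − unload_mean / load_mean`
  from paired load/unload frames with combined background subtraction.
- **Manders colocalization** (thresholded M1/M2) between the vesicle
  and an endosome-marker channel inside the Z-replicated bouton mask:
  `M1 = Σ_A(A⁺∧B⁺) / Σ_A(A⁺)`, `M2 = Σ_B(A⁺∧B⁺) / Σ_B(B⁺)`.
- A **synthetic scene generator** that plants boutons, puncta, dye
  signal and colocalized spots with full ground truth, so every
  measurement above is validated by parameter recovery.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Simulate a two-bouton scene with vesicle puncta planted at 2.0/µm² in
the 200 nm peripheral band and 0.5/µm² centrally, then measure it end
to end:

```python
import nmjquant as nq
from nmjquant.synthetic import NoiseModel

truth = nq.make_zone_truth(2, peripheral_density=2.0, central_density=0.5,
                           area_range=(4, 8), seed=7)
scene = nq.render_scene(truth, noise=NoiseModel(gaussian_sd=3.0), seed=8)

masks = nq.segment_boutons(scene.channel("membrane"))
kept, _ = nq.filter_by_area(masks)          # type-Ib size window
for m in kept:
    b = max(truth.boutons, key=lambda t: (t.footprint & m.footprint).sum())
    pset = nq.detect_local_maxima(scene.channel("vesicle"), m,
                                  min_intensity=35.0, smooth_sigma_px=1.0,
                                  background_masks=masks)
    zones = nq.partition_zones(m, scene.calibration)
    d_per, d_cen = nq.zone_density(pset, zones)
    t_per, t_cen = b.zone_density_truth
    print(f"bouton {m.label}: area {m.area_um2:.2f} um2, {pset.n_total} particles")
    print(f"  peripheral density {d_per:.2f} /um2 (planted {t_per:.2f})")
    print(f"  central density    {d_cen:.2f} /um2 (planted {t_cen:.2f})")
```

Output:

```
bouton 1: area 6.90 um2, 9 particles
  peripheral density 2.13 /um2 (planted 2.71)
  central density    1.00 /um2 (planted 1.03)
bouton 2: area 6.43 um2, 9 particles
  peripheral density 2.92 /um2 (planted 2.98)
  central density    0.85 /um2 (planted 0.87)
```

Each bouton's measured densities sit next to the densities actually
planted for it (per-bouton Poisson draws scatter around the requested
2.0/0.5; single boutons carry only a handful of particles, so
individual values are noisy — averages over many scenes recover the
planted parameters tightly, which is what the test suite checks).

A `nmjq` command-line interface wraps the same stages
(`simulate`, `segment`, `particles`, `profile`, `intensity`, `fm`,
`coloc`, `run`, `recover`); scenes travel as per-channel TIFFs plus a
YAML manifest, results as sorted CSV tables.

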