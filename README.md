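# phasorflim

Phasor and lifetime-fitting analysis of NAD(P)H fluorescence-lifetime
imaging (FLIM) data, with a synthetic time-correlated single-photon
counting (TCSPC) simulator for validation.

## The problem

NAD(P)H is an autofluorescent coenzyme whose excited-state lifetime reports
its biochemical state: free NADH self-quenches and decays in about
τ₁ = 0.4 ns, while enzyme-bound NADH decays in about τ₂ = 3.4 ns.  The
balance between the two — and hence a cell's balance between glycolysis and
oxidative phosphorylation — can be read out label-free from per-pixel
photon-arrival histograms F(x, y, t) recorded by TCSPC microscopy.  This
package implements two complementary analyses of such decay cubes and the
aggregation and statistics needed to compare treatments:

- **Time-domain fitting** — per (3×3-binned) pixel with ≥ 20,000 photons,
  single- and double-exponential weighted least-squares fits compared by a
  nested F-test; the amplitude-weighted mean lifetime
  τₘ = (A₁τ₁ + A₂τ₂)/(A₁ + A₂) summarizes each pixel, and 50-ps lifetime
  histograms are decomposed into Gaussian populations.
- **Phasor analysis** — the model-independent transform
  g = ∫F cos(ωt) dt / ∫F dt, s = ∫F sin(ωt) dt / ∫F dt at
  ω = 2π·100 MHz over one 10-ns period.  Single exponentials land on the
  universal semicircle (g − ½)² + s² = ¼; mixtures land on chords.  After
  complex-division correction for the instrument response (estimated from
  the brightest pixel), each pixel is projected onto the chord from the
  pure-free endpoint p₁ (0.4 ns) to the pure-bound endpoint p₂ (3.4 ns);
  the normalized projection is the **bound NAD(P)H fraction**
  f = l/L = A₂τ₂/(A₁τ₁ + A₂τ₂), from 0 (free) to 1 (bound).
- **Compartments and intensity** — background thresholding plus nuclear ROI
  rasterization split each field into nucleus/cytoplasm; intensities are
  corrected by the photobleaching factor b (mean frame intensity over
  first-frame intensity), normalized to same-replicate vehicle controls,
  and converted into a relative concentration proxy intensity/τₘ.
- **Experiment statistics** — interaction-gated factorial ANOVA (type II,
  escalating to type III with sum-to-zero contrasts when an interaction
  term is significant) and Tukey-adjusted pairwise comparisons over
  field-of-view summaries.

No measured data ships with the package: the `simulate` module generates
TCSPC fields photon by photon (exponential mixtures, Gaussian or delta IRF,
period wrapping, Poisson pixel statistics, per-frame bleaching) with exact
ground truth, and the entire test suite runs against it.

## Worked example

Simulate one field whose cytoplasm is an equal-amplitude free/bound NADH
mixture and whose nucleus is pure free NADH, then run the phasor branch of
the pipeline:

```python
from phasorflim.pipeline import RunConfig, run_field
from phasorflim.simulate import FieldPhantom, simulate_field

phantom = FieldPhantom(seed=42, n_frames=3, bleach_rate=0.05)
cube, truth = simulate_field(phantom)

cfg = RunConfig(min_photons=50, fit_lifetimes=False, irf_mode="none",
                background_threshold=1.0)
result = run_field(cube, cfg, masks=truth)
cols = ["compartment", "bound_fraction", "raw_intensity",
        "corrected_intensity", "n_pixels"]
print(result["summary"][cols].round(4).to_string(index=False))
print(f"bleaching factor b = {result['bleaching'].factor:.4f}")
```

```
compartment  bound_fraction  raw_intensity  corrected_intensity  n_pixels
    nucleus          0.1896       145.6420             152.9185        81
  cytoplasm          0.8762       284.7500             298.9767       360
 whole-cell          0.7501       259.1995             272.1497       441
bleaching factor b = 0.9524
```

The cytoplasmic mean bound fraction sits near the ground truth
3.4/3.8 ≈ 0.895 (an equal-amplitude mixture's photon yield is weighted by
A·τ); the nuclear value is pulled above its truth of 0 by 3×3 spatial
binning across the nuclear boundary, and the ordering nucleus < cytoplasm —
the hallmark of free-NADH-enriched nuclei — is recovered.  The 5%-per-frame
bleaching over three frames gives b ≈ 0.95, raising corrected intensities
about 5% above raw.

The same pipeline is scriptable from the shell:

```sh
flim simulate --phantom phantom.json --out field/
flim phasor --cube field/cube.tif --irf none --mask field/truth_masks.tif --out ph/
flim demo --seed 3 --out demo/     # full synthetic factorial study + stats
```

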