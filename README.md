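# nanosense

A software-in-the-loop bench for automated nanopipette-based intracellular
sensing of adherent cells. Everything runs on synthetic data generated from
simple physical models, so the full pipeline — cell detection, z-axis focus
search, pipette-tip localization, template-matching descent, and ion-current
proximity detection — is testable end to end without hardware or downloads.

## What is implemented

- **`nanosense.scene_sim`** — synthetic inputs. Transparent adherent-cell
  phantoms rendered under defocus (image contrast = defocus × refractive-index
  difference × Laplacian of the cell thickness field), z-stacks with per-plane
  seeded noise, an opaque triangular pipette-tip phantom whose blur and
  contrast degrade with defocus, per-cell ground-truth masks, and a virtual
  tip stage.
- **`nanosense.cell_detect`** — the segmentation chain: Gaussian blur →
  grayscale → hybrid triangle/Otsu binarization → morphological close →
  inversion → outer-contour extraction. The hybrid threshold keeps the contour
  count (NOCC) at zero on the negative-defocus side. Penetration sites are
  per-contour area-moment centroids.
- **`nanosense.focus`** — focus measures (NOCC plus Tenengrad, Energy,
  Brenner, Variance), focus curves with min-max normalization, exhaustive
  z-search for the plane of maximal contour count, and curve-quality metrics
  (range, false-maxima count, noise level).
- **`nanosense.tip_detect`** — tip localization: gamma enhancement → Otsu →
  close → invert → longest contour → closed-curve polygon simplification →
  triangle test → apex (sharpest vertex, refined against the full contour).
- **`nanosense.tm_autofocus`** — zero-mean normalized cross-correlation
  template matching and the nonovershoot descent controller that lowers the
  virtual tip until the best match crosses a similarity threshold.
- **`nanosense.proximity`** — distance-dependent ion-current model
  `I(d) = I_inf / (1 + c/d)`, its closed-form inversion for a relative
  current-drop threshold, noisy approach traces, and surface detection with
  baseline estimation, median smoothing, and consecutive-sample confirmation.
- **`nanosense.evaluation`** — site-vs-nucleus-mask matching and TPR/FPR
  bookkeeping with fractional (replicate-averaged) counts.
- **`nanosense.cli_pipeline`** — the orchestrated virtual experiment
  (z-search → detection → path planning → tip autofocus → per-site approach →
  scoring) with a deterministic JSON run report.

## CLI

```sh
nanosense simulate cells --seed 1 --defocus 30 --out out/      # one render + truth
nanosense simulate stack --seed 1 --out out/                   # defocus z-stack (TIFF)
nanosense simulate tip   --z 0 --out out/tip.png
nanosense detect out/cells.png --out sites.csv
nanosense focus-curve out/stack.tiff --metric nocc --out curve.csv
nanosense tip out/tip.png
nanosense autofocus --threshold 0.92
nanosense approach --noise 0 --out trace.csv
nanosense run --config experiment.yaml --seed 1 --out out/     # full experiment
```

`run` accepts a YAML config mirroring `ExperimentConfig` (scene size and
noise, detection parameters, tip geometry, similarity threshold, pipette
geometry, current-drop fraction, seed). All randomness derives from the
single seed; identical config + seed gives byte-identical artifacts.

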