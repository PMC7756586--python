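# cascadeseg

Cascade auto-contouring for CT-like volumes, exercised end to end on
synthetic pelvic phantoms with exact ground truth:

- **volume_io** — NIfTI read/write, resampling to a 2.5 × 1.17 × 1.17 mm
  working grid, HU clipping to [−1000, 3000] and shifting to a [0, 4000]
  working range.
- **phantom** — pelvic phantom generator (ellipsoidal bladder, bent rectal
  tube, spinal-cord cylinder, kidneys, pelvic ring + L4/L5 vertebral blocks,
  Y-shaped vessel with a known bifurcation slice), cohort jitter, and covert
  label-corruption modes for curation experiments.
- **extent** — per-slice organ presence classification (weighted
  cross-entropy, weight = absences/presences) and postprocessing of the
  probability series into one cranial–caudal interval.
- **segmentation** — 2D/3D per-voxel segmenters trained with soft Dice loss
  and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), flip/rotation augmentation,
  multi-label heads (L4+L5 in one model), the coarse → crop → refine
  strategy, and 2D∪3D union fusion.
- **anatomy** — vessel search region anchored on the L4 block, bifurcation
  detection by in-plane connected-component counting, and the nodal-superior
  / para-aortic-inferior border rules (axially adjacent, disjoint).
- **curation** — semi-automatic label curation: half-split cross-training,
  DSC-threshold flagging (0.7 rectum / 0.8 otherwise), pluggable reviewer,
  three iterations by default.
- **metrics** — DSC, mean surface distance and Hausdorff distance (cm,
  KD-tree accelerated, verified against O(n²) oracles), evaluation-time
  border trimming, and cohort aggregation with outlier flagging.
- **cli / pipeline** — configuration-driven orchestration of
  generate / train / predict / curate / evaluate.

The published network architectures are replaced by compact pluggable
models (logistic heads over multi-scale local image features) that honor
the same contracts — losses, optimizer settings, augmentation, routing —
so every pipeline mechanism is tested at desk scale on one CPU.

## CLI

```bash
cascadeseg generate --out scans/ --n 10 --seed 0            # phantom cohort
cascadeseg generate --out noisy/ --n 10 --seed 0 --corrupt 0.2
cascadeseg train --cohort scans/ --structure bladder \
    --structure vertebra_l4l5 --structure vessel --out ckpt/
cascadeseg predict --scan scans/scan_000 --checkpoints ckpt/ \
    --structure vertebra_l4l5 --structure vessel --structure bladder \
    --out pred/scan_000
cascadeseg evaluate --pred pred/ --ref scans/ --out metrics/
cascadeseg curate --cohort noisy/ --structure bladder --out curated/
```

All commands accept `--config config.yaml`; the file is merged over the
shipped defaults (see `cascadeseg.config.DEFAULT_CONFIG`), which encode the
per-structure routing: bony structures through one 3D multi-label model,
spinal cord through a 2D model, compact organs through 3D + refine, the
nodal region through refine + 2D∪3D fusion + the bifurcation border rule.

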