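# macquant

Quantification of phase-separated lipid membrane domains under a
reconstituted actin cortex.

Minimal actin cortices — membrane-anchored actin filaments on a supported
lipid bilayer — reorganize coexisting liquid-ordered (Lo) and
liquid-disordered (Ld) lipid domains: adhering filaments crowd the membrane
and lengthen the Lo/Ld phase boundary until line tension balances the
crowding pressure, and myosin-driven contraction moves, deforms, splits and
fuses whole domains while conserving the total Lo area.  `macquant` turns
two-channel fluorescence time lapses of such experiments (membrane dye
marking the Ld phase; labeled actin) into the quantities that describe this
physics, and fits the two models that summarize it.

## What it computes

Given a calibrated image stack, the pipeline measures per frame:

- **Labeled lipid domains** — illumination-corrected, locally thresholded,
  edge-refined binary masks with per-domain area, perimeter, centroid and
  phase (Lo/Ld);
- **Total boundary contour length** `L` (µm) and its change ΔL against a
  pre-addition baseline frame;
- **Per-phase domain counts and total areas** (splitting/fusion statistics,
  Lo-area conservation);
- **Actin-binding kinetics** — normalized mean actin-channel intensity;
- **Actomyosin clusters** — Laplacian-of-Gaussian detections with subpixel
  centroids, plus **neighbor distances** as Delaunay-triangulation edge
  lengths.

Two models are fitted:

1. **Contour growth** after actin addition,
   `L(t) = L_final · (1 − exp(−(t − t0)/τ))`, with the lag `t0 = 1 min`
   fixed (two free parameters, deterministic multi-start least squares);
2. **Line-tension temperature law**.  With line tension
   `γ ≈ γ0 (TC − T)/TC` (Celsius scale, `TC = 37 °C`) and a
   temperature-independent deposited boundary energy `E = γ L`, the final
   contour-length change obeys `L(T) = A · TC/(TC − T)` with the single
   amplitude `A = E/γ0` solved in closed form:
   `A = Σ L_i f_i / Σ f_i²`, `f_i = TC/(TC − T_i)`.

A desk calculation compares the inter-phase lipid transfer energy
(~1.5 k_BT) with the boundary-elongation energy of 1 pN × 1 nm — the ratio
(~6) explains why contracting actin drags whole domains rather than mixing
the phases.

Because the original microscopy stacks are not deposited, the package
includes a first-class synthetic generator (`macquant.synthdata`): domains
are Fourier-perturbed circles with polygon-exact areas and perimeters,
rendered under a multiplicative illumination gradient with Gaussian noise,
animated by scripted translate/deform/split/fuse events, optionally forced
to follow a prescribed contour-growth curve, with bright Gaussian cluster
spots in the actin channel.  Every sequence carries full ground truth, so
every pipeline stage is validated end to end.

## Worked example

```sh
python examples/01_line_tension_fit.py
```

prints

```
input points (T degC, delta L um): [(24.0, 188.0), (29.0, 314.0), (32.0, 706.3)]
amplitude A = E/gamma0 = 85.6 +- 9.5 um
per-point residuals (um): [-55.7, -82.0, 72.7]

lipid transfer vs boundary elongation energy ratio: 6.15
```

The three input points are the measured final contour-length changes at
24, 29 and 32 °C; the fitted amplitude `A ≈ 86 µm` is the contour-length
change the same boundary energy would produce at 0 °C, where line tension
is at its full value `γ0`.  The 6.15 ratio says one DPPC crossing the phase
boundary costs about six times the energy of elongating the boundary by one
lipid diameter.

The other examples generate synthetic data and run the image pipeline:

```sh
python examples/02_segment_synthetic_timelapse.py   # segmentation + split event
python examples/03_contour_growth_kinetics.py       # kinetic fit, clean + noisy
python examples/04_cluster_neighbor_distances.py    # LoG + Delaunay distances
```

There is also a thin CLI for shell use — `macquant synth | segment |
quantify | clusters | fit | run | reproduce` (see `macquant --help`);
`macquant run config.yaml` executes the whole pipeline from a YAML
configuration and writes CSV/JSON products plus a content-hashed manifest,
byte-identical under a fixed seed.

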