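# depotmetry

Quantification of subcutaneous drug-depot dispersion from micro-CT time
series, built for ex-vivo insulin-pump infusion assays on human skin
explants.

## The problem

Insulin pumps deliver their basal rate as discrete micro-impulses (one
stroke every ~5 min at 1 UI/h). How that insulin spreads through the
subcutaneous tissue — compactly pooled, or finely dispersed along the
interlobular septa — co-determines how fast it is absorbed, because
absorption scales with the depot's surface-to-volume ratio (STVR). In an
ex-vivo assay, a contrast-labeled insulin mix is infused into a skin
explant inside a micro-CT scanner (one reconstructed 3D volume every
5 min over 3 h, 17 µm isotropic voxels) while the pressure inside the
tubing is recorded.

`depotmetry` turns such a session into quantitative measurements:

1. **Segmentation** — each volume is subtracted from its pre-infusion
   reference (frame 1 for odd-indexed frames, frame 2 for even ones:
   the two scanner rotation directions carry a slight mutual tilt), the
   cannula cylinder is removed, the clamped difference is binarized at its
   0.95 quantile, and the 18-connected component containing the cannula
   tip is kept as the depot.
2. **Morphometry** — per frame, the depot volume `V(t)` (voxel counting),
   external surface `S(t)` (smoothed marching-cubes mesh; exposed-face
   counting available as a conservative cross-check), and the **Index of
   Dispersion**

   ```
   R_compact(t) = (3 V(t) / 4π)^(1/3)
   S_compact(t) = 4π R_compact(t)²  =  (4π)^(1/3) (3 V(t))^(2/3)
   IoD(t)       = S(t) / S_compact(t)
   ```

   IoD is dimensionless: 1 for a perfect sphere (maximally compact, worst
   case for diffusion), ~1.24 for a cube, and growing without bound as the
   depot branches along the septa. An IoD of 7 means the depot presents
   7× the tissue-contact surface of the equal-volume sphere.
3. **Layer classification** — hypodermal / dermis–hypodermis limit /
   intradermal / extradermal, from the cannula-tip depth against a
   configured layer map, with per-layer depot volume fractions.
4. **Pressure events** — pump impulses (peaks of the high-pass residual),
   sustained step-wise elevations (occlusions), and matching of elevation
   onsets against air-bubble annotations from the preceding frame.
5. **Phantom generator** — fully synthetic sessions (lobular background
   with septal walls from a Voronoi tessellation, parametric cannula with
   optional air bubbles, a depot growing one impulse per frame
   preferentially along the septa, matched pressure trace) with analytic
   ground truth, used to validate every stage.

## Worked example

Run the whole pipeline on a synthetic session (no input files needed —
the default phantom is a 36-frame, 3 h septal-growth session):

```bash
depotmetry run --out demo_run --seed 42
```

`demo_run/morpho.csv` then holds one row per frame (references flagged,
infusion frames measured):

```
 frame_index  time_min  volume_mm3  surface_mm2      iod                        flags
           1         0         NaN          NaN      NaN reference_frame;pre_infusion
           3        10    0.010558     0.350775 1.507146
          18        85    0.126264     3.626323 2.979402
          36       175    0.241877     6.953960 3.704121
```

Reading this: at 10 min the first impulse has formed a 0.0106 µL depot
already 1.5× less compact than a sphere; by 175 min the depot has grown to
0.242 µL with an IoD of 3.70 — the monotone rise of IoD is the signature
of insulin spreading along the interlobular septa rather than pooling.
`demo_run/classification.json` reports the infusion layer
(`"hypodermal"`, 99.1% of depot voxels in the hypodermis),
`demo_run/events.json` the 34 detected pump impulses (one per 5 min from
the 10 min pump start) and zero occlusion-type step elevations, and
`demo_run/report/` the mean±SD IoD curve, the final-IoD boxplot and a
stats JSON.

Each stage is also exposed separately (`simulate`, `ingest`, `segment`,
`morpho`, `classify`, `pressure`, `report`) for real TIFF-stack sessions;
see `depotmetry <cmd> --help`.

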