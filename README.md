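# tubemap

Unwrap a roughly cylindrical fluorescent vessel (e.g. the zebrafish dorsal
aorta) from calibrated 3D(+T) TIFF stacks into isotropic planar 2D maps, and
quantify what happens on them:

- **tube fitting** (`tubemap.tubefit`) — slice-wise crown-constrained circle
  search (maximize crown fluorescence, penalize lumen signal), propagated
  along the stack to locate the central axis;
- **unwrapping** (`tubemap.unwrap`) — angular max-intensity ring sampling
  (no intensity interpolation) onto a map whose X axis is the circle
  perimeter and Y axis the tube axis, with optional seam-merging map
  duplication and time-lapse support;
- **kinetics** (`tubemap.kinetics`) — apical-constriction dynamics from
  paired junction-spot tracks: pairwise distance with gap handling, double
  20-min unweighted sliding average, closing speed (positive when closing),
  prominence-filtered (> 0.01 µm/min) speed minima, cycle durations and
  track spans;
- **morphometry** (`tubemap.morphometry`) — shoelace areas, best-fit
  rectangle length/width, floor/roof/medio-lateral classification
  (EHT / hemogenic / endothelial) and wrap-aware neighbor counts for cell
  contours traced on maps;
- **phantoms** (`tubemap.phantom`) — ground-truthed generators: cylindrical
  membrane volumes with wrap-aware Voronoi cell tessellation, junction-spot
  enrichment, blur and noise; and oscillatory spot-track pairs with planted
  period, phase plan, dropouts and positional noise;
- **I/O** (`tubemap.io`) — OME-TIFF volumes with µm calibration, CSV
  tracks (`track_id,t,x,y[,label]`, minutes/µm), contour CSVs
  (`cell_id,vertex_index,x,y[,annotation]`) and `key = value` configs.

## CLI

```sh
# fit + unwrap a stack (user supplies the first-slice circle)
tubemap unwrap stack.ome.tif --init-cx 24 --init-cy 24 --init-r 12 \
    --crown 3 --lambda 1.0 --duplicate --out map.tif

# kinetics on a two-track CSV
tubemap tracks tracks.csv --window 20 --passes 2 --prominence 0.01 \
    --frame-interval 2 --out-prefix result

# morphometry + classification of traced contours
tubemap measure contours.csv --floor-x 10 --circumference 40 --out cells.csv

# phantoms with ground truth
tubemap simulate tube --spec tube.cfg --seed 7 --out sim/
tubemap simulate tracks --seed 7 --out sim/
```

## Conventions

Volumes are indexed `(z, y, x)`; the slice index runs along the tube axis
after `reorient`. Positions are µm and times minutes at every I/O boundary;
frame numbers convert via `--frame-interval` (default 2 min). Map X is
circumferential (periodic with circumference `C = width × pixel_size`),
map Y is axial; `pixel_size` equals the axial slice spacing at the
reference (median) radius.
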