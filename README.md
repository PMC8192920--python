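# stentrec

3D reconstruction of deployed coronary stents from segmented intravascular
OCT pullbacks and an angiography-derived vessel centerline.

Cross-sectional OCT shows every strut but not the global 3D configuration
of the scaffold inside the artery; angiography shows the vessel course but
not the struts. `stentrec` fuses the two: it lofts the segmented lumen
contours along the 3D centerline, unrolls the stent struts onto a plane,
reconstructs the planar stent wireframe against the manufacturer's
crown-and-link design template, rolls the wireframe back onto the lumen,
and sweeps the strut cross-section into a CFD-ready surface mesh. The
result is the patient-specific stent geometry — expansion, shape,
malapposition, link positions — suitable for morphometric analysis and
hemodynamic simulation.

For researchers in intravascular imaging and vascular biomechanics who
have per-frame segmentations (lumen contour, stent contour, strut points,
orientation marker) and a centerline, and need the true 3D scaffold.

## Method in brief

1. **Lumen** — contours placed on rotation-minimizing frames at station
   `z_k = k·Δ` (Δ = frame distance), rotated in-plane so the marker maps to
   the transported reference direction, then lofted.
2. **Unroll** — struts stacked on a straight axis, anchored at the distal
   stent-contour centroid, and mapped to
   `(x, y) = (z − z_distal, arclength along the stent contour)`;
   the radial gap of each strut to the contour is stored.
3. **Wireframe** — in the unrolled plane, zig-zag rings are detected
   (peaks/valleys), links are placed per the template's numbered chart,
   wire-shadow gaps are bridged at the template phase, and the pattern is
   continued across the circumferential seam.
4. **Roll-back** — the planar graph is mapped back through the inverse of
   step 2, crowns are rounded with tangent arc fillets, and the circular or
   rectangular strut profile is swept along every edge.
5. **Metrics** — stent length; mean stent diameter,
   `MSD = mean over stations of 2·sqrt(A/π)` from cross-sections every
   0.1 mm; ellipse ratio `X/Y` (furthest pair over max perpendicular
   separation); strut-to-lumen malapposition; Bland–Altman agreement
   (`mean(d) ± 1.96·SD(d)`); and the wall-shear-stress time average
   `TAWSS = (1/T)∫₀ᵀ |τ_w| dt`.

A synthetic phantom generator (`stentrec.phantom`) builds stented vessels
with exact ground truth and simulates the OCT pullback — frame spacing,
segmentation jitter, guidewire shadow, catheter rotation drift — so the
whole pipeline can be validated without physical models. See
`docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

Generate a phantom (3.0 mm stent, 9 rings × 8 crowns, 0.03 mm segmentation
jitter, 30° guidewire shadow) and reconstruct it:

```bash
stentrec phantom --seed 5 --out demo/phantom
# phantom written to demo/phantom (101 frames)

stentrec run --frames demo/phantom/frames.json \
             --centerline demo/phantom/centerline.csv \
             --template demo/phantom/template.json \
             --out demo/recon
```

`demo/recon/metrics.json` then reads:

```json
{
 "max_malapposition_mm": 0.10288264529634657,
 "mean_ellipse_ratio": 1.012392573974078,
 "mean_stent_diameter_mm": 2.655490373699401,
 "n_cross_sections": 159,
 "stent_length_mm": 16.0
}
```

Reading these numbers: the stent length matches the 16 mm template; the
mean stent diameter (2.66 mm) sits below the 3.0 mm deployment diameter
because serial cross-sections include the inter-ring gaps, where only the
three link struts are cut — the ground-truth stent measures the same way;
cross-sections are essentially circular (ellipse ratio 1.01); and with no
injected malapposition the maximum strut–lumen distance stays at the
0.1 mm apposition threshold of the reconstruction. The output directory
also contains `lumen.stl`, `stent.stl`, the unrolled point set, the
wireframe graph JSON, a per-station diameter table, and a manifest with the
configuration hash and per-stage timings.

The same stages are available individually (`reconstruct-lumen`, `unroll`,
`wireframe`, `rollback`, `metrics`) and as library calls
(`stentrec.reconstruct`).

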