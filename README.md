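# cinealign

Geometry-based correction of breath-hold slice misalignment in multiplanar
cine cardiac MR, with graph-cut reconstruction of the left-ventricular (LV)
endocardial surface and contour-overlap validation.

## The problem

A routine cine CMR study acquires a stack of 12–14 parallel short-axis (SA)
slices plus three long-axis (LA) views (2-, 3- and 4-chamber), one slice per
breath-hold. Because the diaphragm settles differently in each breath-hold,
every slice carries its own rigid offset — up to about one slice thickness —
and the delineated contours no longer assemble into a consistent 3-D heart.
`cinealign` projects the 2-D contours into the patient coordinate system
using each slice's DICOM geometry (Image Position/Orientation (Patient),
Pixel Spacing),

```
[x y z 1]^T = [ U du   V dv   0   P ] [u v 0 1]^T ,
```

estimates one rigid correction per slice from the mutual consistency of the
contours (two contours drawn on different planes can only agree along the
intersection line of those planes), and rebuilds the LV surface from the
realigned contour stack as the minimizer of the weighted minimal-surface
energy

```
E(S) = ∫_S d(x, C_inter) dA ,      d(x, C) = min_{y in C} |x − y| ,
```

discretized as a max-flow/min-cut on a Delaunay tetrahedral mesh whose arc
capacities are shared-face area × distance to the interpolated contour
cloud. Reconstructions are scored against the LA LV contours with the
Hausdorff distance H (mm, infinite when a plane misses the surface) and the
region-overlap coefficients Dice D = 2|Re∩Tr|/(|Re|+|Tr|) and Jaccard
J = |Re∩Tr|/|Re∪Tr| (J = D/(2−D) identically); D ≥ 0.7 is the conventional
adequacy threshold.

Since clinical CMR contour data are rarely shareable, the package includes a
first-class analytic phantom — a truncated-ellipsoid LV joined to an atrial
chamber and an aortic stub, sliced exactly like a clinical acquisition —
together with a misalignment simulator, so every stage can be validated
against known ground truth.

## Worked example

```
$ cinealign run-all --seed 7 --out demo_out
...
[realign] outer iteration 19: mean displacement 0.2930 mm
[run-all] 5.08s rms_before=6.98mm rms_after=2.56mm dice_before=0.682 dice_after=0.966
$ head -9 demo_out/report.csv
case,view,H_mm,D,J
before,2CH,21.463505,0.693629,0.530959
before,3CH,25.241893,0.664388,0.497440
before,4CH,22.124030,0.687337,0.523621
before,mean,22.943143,0.681785,0.517340
after,2CH,5.013339,0.972174,0.945855
after,3CH,6.927632,0.963267,0.929137
after,4CH,6.596501,0.962367,0.927464
after,mean,6.179157,0.965936,0.934152
```

One seeded run simulates a misaligned phantom (per-slice translations up to
±8 mm per axis, rotations up to 5°, 0.5 mm delineation noise), realigns it,
reconstructs the LV surface from both the un-realigned and the realigned
contours, and scores each against the phantom's true long-axis LV contours.
Here the RMS contour-to-truth error drops from 6.98 mm to 2.56 mm and the
mean Dice overlap rises from 0.68 (inadequate) to 0.97; the paired
`before`/`after` rows in `report.csv` give Hausdorff (mm), Dice and Jaccard
per long-axis view. The run also writes the corrected contours
(`contours_realigned.json`), the per-slice corrections as unit quaternions +
translations (`corrections.json`) and the surfaces (`surface_*.ply`).

The same steps are available individually (`cinealign phantom | realign |
reconstruct | validate`) and, for scripting, as the library functions
`make_phantom`, `perturb`, `realign`, `reconstruct` and `validate`.

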