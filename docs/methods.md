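# Methods

This note documents the model behind voxpipe's engine, the numerical
conventions of the module catalog, what the synthetic scenes do and do not
emulate, and the design choices made where more than one reasonable option
existed.

## Execution model

A protocol is a strictly linear list of module calls.  The engine threads a
single **current image** through the list: every call receives it (pure-I/O
calls may run with none) together with an `ImageInfo` provenance record, and
returns the image that becomes current.  There is deliberately no second
image slot — a module that needs an auxiliary image (raw intensities for
quantification, a partner label map for co-localisation) reads it from a
work folder where an earlier `save` call put it.  This keeps the language
free of variables and the dataflow trivially auditable: at any point exactly
zero or one image is live.

`ImageInfo` always names the *original* database image of the batch item and
is never rewritten by processing calls; only `channel`/`frame` are updated
by `input`.  This invariant is what makes `?image?`-based naming of outputs
and attachments correct throughout a protocol.

All parameters are strings end to end.  Defaults are merged first, then
every value undergoes keyword substitution (`?image?`, `?project?`,
`?dataset?`, `?ij?`, `?home?`, `?temp?`) against the batch item's context.
Substitution is a single left-to-right scan: substituted text is never
re-scanned, and an unrecognised `?token?` is a hard error rather than a
silent pass-through, because a typo that survived substitution would
propagate into database file names.  `?ij?` is simply the configured work
directory (`EngineConfig.work_dir`).

Failure semantics are per image: the first error inside a protocol skips the
remaining calls for that image and is recorded in the image's run report;
the batch continues.  Long batches over heterogeneous data survive single
corrupt files, at the cost of partially processed images being possible —
the report flags them.

## Store conventions

The database is `root/<project>/<dataset>/<image>.tif` plus one
`attachments/` folder per dataset ("attachments" is therefore a reserved
dataset name).  Attachment linkage is by the `<image>-` filename prefix —
the simplest mechanism that survives copying a dataset folder around with
ordinary file tools.  Images are multi-page TIFFs; axis order, image kind
(intensity/binary/label) and the spatial calibration (XY pixel size, Z step,
unit) are stored in the TIFF description, so write/read pairs are voxel- and
calibration-exact for every supported dtype and a stored label map is typed
back as a label map.  When a file carries no calibration the default is
1.0/1.0/"pixel", which makes volumes equal voxel counts — convenient for
hand-checking.  Writes overwrite silently so reruns are idempotent (one file
per image name, byte-identical for identical inputs).

## Numerical conventions in the catalog

* **Foreground** is strictly `value > threshold` everywhere, so boundary
  cases are decidable in tests.
* **Connectivity** is 26-neighborhood for objects (restricting itself to
  8-neighborhood on single-slice stacks) and 6-neighborhood for the
  background flood in hole filling.  Single-slice stacks are hole-filled
  in-plane; a 3D fill would treat every 2D cavity as open along z.
* **Labels** are consecutive `1..N` in raster order of each object's first
  voxel, re-established after every label-producing or label-filtering
  call.  `keepBiggest` breaks ties by smallest label id.  Both rules exist
  to make reruns byte-identical.
* **Filters** use an ellipsoidal neighborhood with semi-axes
  (radiusXY, radiusXY, radiusZ) voxels and nearest-edge replication at the
  borders; `gauss` interprets the radii as standard deviations.  Radius 0 is
  the identity.
* **Otsu** maximizes between-class variance over the distinct image values
  (candidate thresholds are values, ties resolve to the smallest); `Mean`
  thresholds at the global mean; `IsoData` iterates
  `T ← (mean ≤ T + mean > T)/2` from the global mean to a fixpoint.  A
  constant image has no threshold and is reported as a degenerate
  histogram.  The percentile threshold is the smallest value leaving at most
  the requested percentage of voxels strictly above it.  Hysteresis keeps
  weak voxels (`> low`) only when 26-connected to a strong one (`> high`).
* **Sizes** (`minSize`/`maxSize`) are voxel counts, inclusive on both ends.
* **Geometry** is calibrated: volume = voxel count × voxel volume; surface
  by counting exposed voxel faces with their calibrated areas;
  compactness `36πV²/S³` and sphericity `compactness^(1/3)`.  Face counting
  was chosen over smoothed surface estimators because it admits an exact
  independent oracle (direct face enumeration); the known cost is that
  digital surfaces overestimate smooth ones, so absolute compactness values
  are biased low — comparisons between objects measured the same way remain
  meaningful.
* **Crop** bounds are 0-based and half-open.  **Scale** resamples with
  nearest-neighbor for binary/label data and linear interpolation otherwise,
  dividing the pixel sizes by the factors.  **Math** clamps to the integer
  dtype range.
* **Degenerate inputs**: empty masks and empty label maps propagate as
  empty results with warnings, never as errors, so a blank image cannot
  poison a batch.  Table-producing calls on an empty label map write a
  header-only CSV.
* `numbering` counts partner objects whose centroid voxel (nearest-voxel
  rounding) lies inside each current object; `distances` reports the
  nearest partner by calibrated centroid-to-centroid Euclidean distance.
  These are this package's definitions, chosen for testability.

## Synthetic scenes

`SceneSpec` describes a two-channel 8-bit stack of non-overlapping
ellipsoids: channel 1 is the segmentation channel (objects at 120,
background at 20, Gaussian noise sd 5 — cleanly separable by a global
threshold), channel 2 carries one known integer mean per object (uniform in
[80, 200], background 30) for quantification checks.  The default scene is
(32, 192, 192) voxels at 0.2 × 0.2 × 1.0 µm calibration with six objects,
semi-axes 10–14 voxels in XY and 5–8 in Z, exactly one forced to cross an
X/Y border.  Placement is rejection sampling with non-overlapping (margin-2)
bounding boxes; a scene that cannot be packed raises instead of looping.

The object sizes were chosen so that the worked example's median filter
(radiusXY 4, radiusZ 2) erodes boundaries by only a small fraction of each
object: segmented volumes then stay within 15 % of the analytic ellipsoid
volume `4/3πabc`, and because the smoothing shrinks objects *inward*, the
segmented voxels lie inside the true support — which is what lets per-object
channel-2 means be compared against the generative means at the
`3·sd/√n` sampling tolerance.

What the scenes do **not** emulate: point-spread blur, Poisson/shot noise,
intensity gradients, textured or touching objects, anisotropic PSF tails.
Passing tests therefore demonstrate the correctness of the engine, store and
catalog semantics — not segmentation robustness on real microscopy data,
where thresholds and filters need tuning per dataset.

## Problem sizes

Unit and oracle tests run on small random stacks (~5×8×8, 50–100 instances
per equivalence suite) where brute-force references (BFS flood fill,
exhaustive threshold search, per-voxel neighborhood medians) are exact and
fast.  The worked example runs at the default scene size, where one image
takes a few seconds end to end; the acceptance script runs it twice to
verify byte-level determinism and finishes in well under a minute.

## Known limitations

* TIFF is the only image format; multi-format reading is out of scope.
* No parallel execution, caching or resumable checkpoints; batches are
  strictly sequential.
* The language is deliberately not Turing-complete: no conditionals, loops
  or arithmetic on parameters.
* A parameter may not repeat within a call (duplicates are parse errors);
  inline trailing comments are not supported (`//` must start the line).
* Iterative/model-fitting threshold schemes and GPU filter variants are not
  implemented.
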