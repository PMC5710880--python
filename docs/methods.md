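# Methods

`coloscreen` re-implements an automated screening classifier for H&E-stained
colorectal biopsy tissue images.  Each tissue is assigned one of four
classes — **Positive** (suspicious for carcinoma), **Adenoma**, **Negative**
(no neoplasia), **Unclassifiable** — by a pipeline of quality control, color
normalization, structural (glandular) atypia analysis, cytological atypia
analysis, and a fixed combination rule.  Because no image data is deposited
with the study this package follows, all image-level behaviour is developed
and validated against a built-in synthetic H&E generator with per-pixel
ground truth; the only real data are the two published hospital-level
confusion matrices, which the evaluation module reproduces exactly.

## The synthetic tissue model

A tissue is a stromal fragment (a wobbly ellipse occupying ~50% of a
1024×1024 canvas at 0.92 µm/px) carrying `gland_count` tubular glands and,
in the dissociated-cell mode, isolated signet-ring-like cells.  Each gland
is, from the inside out: an elliptical lumen (radius 1.2–2.2 nuclear
widths), an apical cytoplasm band one nuclear width thick, and a basal rim
of stamped elliptical nuclei whose radial extent is
`rim_thickness_nuclei × nuclear_size_um`.  The phenotype parameters map to
the diagnostic spectrum:

| parameter | negative | adenoma | carcinoma (glandular) | carcinoma (dissociated) |
|---|---|---|---|---|
| rim thickness (nuclear widths) | 0.8–1.4 | 1.9–2.9 | 3.3–4.8 | — |
| stratification | 0–0.08 | 0.1–0.4 | 0.45–0.95 | 0 |
| dissociated cells / 1000 µm² | 0 | 0 | 0 | 0.6–1.4 |
| nuclear size (µm) | 6.5–7.5 | 7.0–8.0 | 8.0–10.0 | 9.0–11.0 |

Stratification — the loss of basal nuclear polarity — jitters rim nuclei
toward the lumen and seeds extra luminal nuclei in proportion to its value.
About 30% of sampled carcinomas use the dissociated mode (poorly
differentiated / signet-ring pattern: no glands, enlarged eccentric nuclei
in pale mucinous cells), which is exactly the pattern structural analysis
cannot see and cytological analysis must catch.

Pixels are rendered through the Beer–Lambert relation
`I = background · exp(−OD)` with OD the sum of per-pixel hematoxylin and
eosin concentrations times the Ruifrok–Johnston unit OD directions
(H ≈ [0.65, 0.70, 0.29], E ≈ [0.07, 0.99, 0.11] after normalization).
Batch effects re-render an image's estimated concentrations under a shifted
`StainProfile` (rotated stain vectors, intensity scale, and a contrast
scale that compresses concentrations toward their tissue mean — the
washed-out-slide failure mode).  Artifacts (Gaussian blur over a coverage
fraction, opaque pen strokes, multiplicative shadow ramps) are composable
operations that also emit ground-truth masks.  Every operation draws from a
`numpy` Generator keyed on (seed, operation name), so all outputs are pure
functions of their seeds.

What the generator does **not** emulate: chromatin texture, crypt
branching/cribriform architecture, inflammatory infiltrate, sectioning and
folding artifacts, scanner optics.  Tests passing on this substrate
demonstrate that each algorithm measures what it claims to measure on
geometry it was not hand-fitted to, not that the pipeline reaches the
published accuracy on real slides (see Limitations).

## Quality control

Focus is scored per tile (default 64 px) as the variance of the Laplacian
of luminance, computed over foreground (stained) tiles only.  The blur
threshold of 7.0 was fixed once as the geometric midpoint between the
lowest sharp-tile score (~19.6) and the highest σ=3-blurred score (~2.5)
over 100 generator tiles and then left alone.  Pen ink is detected as
high-saturation pixels with hue far from the H&E pink–purple band (or very
dark pixels, for black ink), with components under 0.01 mm² dropped;
shadows as regions where a background-only smoothed illumination field
falls >20% below the white point.  A tissue is `unusable` when blurred
fraction ≥ 0.5, pen fraction ≥ 0.2, or shadow fraction ≥ 0.3 (these status
thresholds are conventions, config-exposed); `partial_degraded` tissues
proceed with degraded tiles painted to background so they contribute
nothing downstream.

## Color normalization

Macenko-style estimation: optical density relative to the bright-percentile
white point; the H/E directions are the robust extreme angles (α = 1%)
within the top-2 OD principal plane (computed from the 3×3 second-moment
matrix); the vector with the larger red-channel OD is hematoxylin.
Normalization rescales per-pixel concentrations so their 99th percentiles
match the reference profile and recomposes with the reference vectors.  The
reference estimate shipped in `data/reference_stain.json` was computed once
from a fixed-seed benign generator image (seed 2017).  Degenerate inputs
(under 10⁴ foreground pixels, or an H–E angle ≤ 10°) raise; the pipeline
then analyzes the image un-normalized rather than failing the tissue.

The nuclear detectors deliberately use a *fixed* hematoxylin-concentration
threshold (0.45) rather than an image-adaptive one: on an un-normalized
low-contrast batch, nuclear concentrations fall below it and detection
collapses to under half of truth — reproducing the mechanism by which
low-contrast staining causes missed carcinomas — and normalization restores
detection to within ±20%.

## Structural atypia

Two passes, to bound computation.  At low magnification, nuclear pixels
(hematoxylin threshold) are linked by a closing of one nuclear width into
"glandular nuclear components"; components smaller than 5
nuclei-equivalents of area are noise.  Component rim thickness is
`2 × median(distance transform over the skeleton)` in µm — the median is
robust to branch points and to the scalloped boundary left by individual
nuclei.  Thickness maps to **gland level 1–10** on fixed equal-width bins
spanning 5–55 µm (absolute µm bins, not per-image quantiles, so levels are
comparable across images), visualized with a fixed cool→warm palette.

Only components at or above the trigger level (default 5) get the
high-magnification pass (0.46 µm/px, by resampling when no finer pyramid
level exists): nuclei vs cytoplasm are separated within the dilated
component, and the **arrangement score** is the fraction of angular
cross-sections of the gland whose nuclei approach the lumen closer than
half a nuclear width.  A polarized epithelium keeps a nucleus-free apical
cytoplasm band, so the score is ~0 for single-layer glands and rises toward
1 with stratification.  (An earlier "basal half of the epithelium"
formulation was discarded: for thick rims, nuclei occupy the luminal half
even when perfectly polarized.)

Tissue rating: no measurable component → `unclassifiable` (or `low` when
the tissue is known gland-free); max level ≤ `cut_low` → `low`; max level ≥
`cut_high` or any arrangement score ≥ 0.5 → `high`; otherwise `middle`.
The default cutpoints (3, 8) are starting values; calibration rewrites
them.

## Cytological atypia (MIL)

Nuclei are segmented by hematoxylin threshold plus watershed on the
distance transform; ROIs are non-overlapping 256-px grid tiles keeping
those with ≥ 10 nuclei.  Each ROI is summarized by a 10-feature
morphometric vector (density, mean/sd nuclear area, eccentricity,
hematoxylin concentration, nearest-neighbour distance, large-nucleus
fraction, solidity).  A small feed-forward network (10→16→8→1, tanh/
sigmoid) scores each ROI in [0, 1]; the bag (tissue) probability during
training is a log-sum-exp smooth maximum (τ = 8; noisy-OR is
config-selectable) of instance scores, trained full-batch with Adam on
bag-level cross-entropy — labels exist only per tissue, never per ROI.
The network is implemented directly in numpy with manual backpropagation:
it is ~60 parameters-per-layer small, trains in under a second, and is
bit-deterministic under its seed.

The tissue aggregate is the **mean of the squares of the three largest ROI
scores** (read as mean-of-squares, which is monotone, bounded in [0, 1],
and reduces to the score under saturation; fewer than three ROIs are
zero-padded so small tissues are not advantaged).  `high` atypia iff
aggregate ≥ threshold, with the boundary counting as high — sensitivity to
carcinoma is the design priority throughout.

## Overall classification and calibration

The final class adopts the higher atypia level: quality `unusable` →
Unclassifiable; structural `high` or cytological `high` → Positive;
structural `middle` → Adenoma; both `low` → Negative; structural
`unclassifiable` with cytological `low` → Unclassifiable (with cytological
`high`, rule 2 fires first — the sensitivity-biased resolution of a case
the combination rule must define).  `combine` is a total pure function over
the 4×2×3 input lattice, enumerated exhaustively in tests, and raising
either atypia level never demotes the final class.

Calibration mirrors the priority order on a synthetic validation cohort
(default 22 carcinoma / 53 adenoma / 75 negative = 150 tissues, the
15/35/50 composition such screening systems are tuned on): train the MIL
scorer on the cohort's bags; set the cytological threshold just below
(×0.999) the smallest carcinoma aggregate, so no validation carcinoma is
missed; set `cut_low` to the largest level keeping ≥ 95% of adenomas above
it and `cut_high` one level above the largest adenoma level.  Over-detection
is reported, not optimized — a tolerable cost of sensitivity.

## Evaluation

Predictions and Japanese Group Classification truths are tallied into an
8-row × 4-column confusion matrix (Group 5, lymphoma, carcinoid, Group 4,
Group 3, Group 2, Group 1, Group X × P/A/N/X).  The three screening
indices are

- undetected carcinoma = (n(A|G5) + n(N|G5)) / n(G5) × 100, Group 5 row only,
- undetected adenoma = n(N|G3) / n(G3) × 100,
- over-detected proportion = (n(P|G3) + n(P|G1) + n(A|G1) + n(X|G3) + n(X|G1)) / n(ALL) × 100,

with n(ALL) counting every row (the lymphoma/carcinoid rows enter n(ALL)
but not n(G5) — forced by the published totals).  Percentages are rounded
half-up to one decimal to match printed precision; an index with a zero
denominator is reported as undefined, never as 0.

## Numerical and engineering choices

- Binary closings with large radii use two Euclidean distance transforms
  (O(N) in the radius) instead of structuring-element morphology.
- Coordinates are 0-based, row-major, origin top-left; all crops use
  half-open intervals.  Pyramid levels are sorted coarse→fine.
- Problem sizes: the default canvas is 1024² at 0.92 µm/px (a 4× coarsening
  of a 0.23 µm/px 40× scan — desk-scale, ~1 s per tissue through the full
  pipeline); the end-to-end screening check uses a 150-tissue calibration
  cohort and a 300-tissue held-out cohort, which this package treats as its
  standard experiment size.
- Determinism: generator, MIL training, and the full classify path are
  bit-reproducible given seeds; there is no hidden global RNG state.

## Known limitations

- The generator's geometric idealization means absolute performance numbers
  on synthetic cohorts say nothing about accuracy on real slides; only the
  two published confusion matrices anchor the evaluation module to real
  data.
- The min-aggregate cytological threshold is deliberately aggressive; on a
  validation cohort whose weakest carcinoma is atypical it can admit
  noticeable over-detection (the intended trade-off).
- Lymphoma and carcinoid are not modelled or trained classes; they exist
  only as evaluation-vocabulary rows.
- Blur is flagged, never corrected; an overall-blurred tissue is
  Unclassifiable by design.
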