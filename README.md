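# coloscreen

Automated screening classification of H&E-stained colorectal biopsy tissue
images, for pathology quality-control workflows: instead of a second
pathologist double-checking every slide, a classifier flags the tissues
worth re-checking.  Each tissue image is assigned one of four classes —
**Positive** (suspicious for carcinoma), **Adenoma**, **Negative** (no
neoplasia), or **Unclassifiable** — by a pipeline of

1. **quality control** — variance-of-Laplacian focus scoring per tile, pen-ink
   and shadow masks; degraded tissues are excluded or masked;
2. **color normalization** — Macenko-style stain-vector estimation in optical
   density space and re-projection onto a reference H&E profile, removing
   staining batch effects;
3. **structural atypia** — glandular nuclear components are extracted at low
   magnification, their rim thickness (2×median skeleton distance)
   discretized into gland levels 1–10 on fixed 5–55 µm bins, and thick
   glands get a high-magnification nuclear-polarity (arrangement) score;
4. **cytological atypia** — nuclei-dense ROIs scored in [0, 1] by a
   multi-instance-learning neural network; the tissue aggregate is the
   mean square of the top-3 ROI scores, S = ⅓·Σ max₃(sᵢ)², thresholded
   into high/low;
5. **overall classification** — the higher atypia level wins: structural or
   cytological *high* → Positive, structural *middle* → Adenoma, both
   *low* → Negative; unusable image quality → Unclassifiable.

Screening performance is summarized by three indices over a confusion
matrix of Japanese Group Classification truths (Group 1 … Group 5, Group X,
plus lymphoma/carcinoid rows) against P/A/N/X predictions:

- undetected rate of carcinoma = (n(A|G5) + n(N|G5)) / n(G5) × 100
- undetected rate of adenoma = n(N|G3) / n(G3) × 100
- over-detected proportion = (n(P|G3) + n(P|G1) + n(A|G1) + n(X|G3) + n(X|G1)) / n(ALL) × 100

where n(a|b) counts tissues with pathologist diagnosis *b* predicted *a*.
The over-detected proportion is the fraction of tissues sent for re-check.

Since no image dataset accompanies the original study, the package ships a
**seeded synthetic H&E generator** (tubular glands with nuclear rims and
lumina, adenoma→carcinoma rim thickening and stratification, dissociated
signet-ring cells, stain batch shifts, blur/pen/shadow artifacts, full
per-pixel ground truth) that serves as the test substrate for every image
operation, plus the two published hospital confusion matrices as packaged
fixtures.  See `docs/methods.md` for the model details and limitations.

## Worked example

Calibrate on a small synthetic validation cohort, then classify a rendered
signet-ring-pattern carcinoma (gland-free, dissociated cells — the pattern
only cytology can catch):

```python
from coloscreen import TissuePhenotype, render_tissue, classify_tissue
from coloscreen.calibration import calibrate

cal = calibrate({"carcinoma": 12, "adenoma": 12, "negative": 12}, seed=5)
phen = TissuePhenotype(
    class_label="carcinoma", gland_count=0, rim_thickness_nuclei=1.0,
    stratification=0.0, dissociated_cell_density=1.2, nuclear_size_um=10.5, seed=303,
)
tissue, truth = render_tissue(phen)
result = classify_tissue(tissue, cal.model, cal.config, tissue_id="demo")
```

which prints:

```
final_class = Positive
structural  = low (max gland level 1)
cytological = high (top-3 aggregate 0.998, threshold 0.996)
quality     = ok
explanation = ['rule2: higher atypia level adopted -> Positive']
```

Structural analysis sees only thin (level-1) fragments — there are no
glands to measure — but the MIL scorer rates the dissociated-cell ROIs near
1, the top-3 aggregate clears the calibrated threshold, and the
higher-atypia rule promotes the tissue to Positive.

The same pipeline is available from the shell:

```bash
coloscreen generate --out-dir cohort --n-negative 5 --n-adenoma 29 --n-carcinoma 5 --seed 7
coloscreen calibrate --out-config cal.yaml --out-model mil.json --seed 7
coloscreen classify --cohort-dir cohort --model mil.json --config cal.yaml --out-dir reports
coloscreen evaluate --truth truth.csv --predictions reports/predictions.csv
coloscreen evaluate --fixture tokyo     # indices of the packaged reference matrix
```

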