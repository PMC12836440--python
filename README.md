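# condylefd

Box-counting fractal analysis of condylar trabecular bone on panoramic
radiographs, with the cohort statistics and tabular classifier benchmark
used to evaluate the fractal dimension (FD) as a marker of
temporomandibular disorder (TMD).

Degenerative change in the mandibular condyle alters the complexity of
its trabecular bone texture. The box-counting fractal dimension
summarizes that complexity in a single number: a 100 × 100-pixel region
of interest (ROI) over the condyle is background-corrected, binarized,
morphologically opened, inverted, and skeletonized, and the skeleton's
FD is estimated as

```
FD = −slope of the OLS fit of log N(ε) on log ε
```

where N(ε) is the number of grid cells of edge ε containing at least
one skeleton pixel. A 1-pixel curve has FD ≈ 1, a filled region FD ≈ 2;
lower condylar FD indicates reduced trabecular complexity and is the
signal separating TMD patients from controls.

The package is aimed at oral-radiology and dental-imaging researchers
who want a scriptable, reproducible replacement for interactive
macro-based FD measurement, plus the downstream layers such studies
report: per-cell descriptives, Shapiro–Wilk-gated group comparisons
with pooled-SD Cohen's d, Bonferroni correction, ICC(2,1) observer
agreement, and a six-family classifier benchmark (random forest,
logistic regression, SVM, gradient boosting, k-nearest neighbors,
XGBoost) on the features {age, gender, LC_FD, RC_FD}.

## Worked example

```python
from condylefd import ROISpec, fd_from_image, make_trabecular_texture

image = make_trabecular_texture(size=128, complexity=0.6, seed=1)
record = fd_from_image(image, ROISpec(x=14, y=14, width=100, height=100),
                       subject_id="demo", side="left")
print(f"fractal dimension = {record.fd:.4f}  (r^2 = {record.r_squared:.4f})")
```

prints

```
fractal dimension = 1.2869  (r^2 = 0.9752)
```

i.e. the skeletonized texture fills space distinctly more than a curve
(FD 1) but far less than a solid region (FD 2) — the range where
condylar trabecular bone lives — and the log–log box counts are close
to linear (r² 0.98), so the single-slope summary is adequate. On a real
radiograph, replace the synthetic texture with
`load_grayscale("opg.png")` and anchor the ROI on the condyle.

The `examples/` directory contains one narrative script per capability
(`fractal_dimension_basics.py`, `preprocess_and_measure.py`,
`cohort_statistics.py`, `classifier_benchmark.py`); each builds a small
input, runs the method, and explains the numbers it prints. The same
functionality is reachable from the shell:

```bash
condylefd fd --image opg.png --roi 412,105 --out fd.json --save-steps steps/
condylefd simulate --seed 42 --out cohort.csv
condylefd stats --cohort cohort.csv --out stats/
condylefd train --cohort cohort.csv --seed 42 --out ml/
```

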