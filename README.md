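# leafmargin

Models and quantification tools for auxin-PIN-CUC patterning of the leaf
margin.

Complex leaves (such as those of *Cardamine hirsuta*) place lateral
outgrowths where the margin builds new auxin maxima: neighboring cells
reorient their PIN1 auxin-efflux carriers so their transport converges on
one cell, and the resulting auxin peak marks the site of a leaflet or
serration. CUC transcription factors, expressed in a bounded boundary
domain of the margin, are the instructive input: they drive PIN
phosphorylation (via WAG kinases) and thereby change how PIN polarizes.
This package implements that patterning logic as a testable cell-grid
model, together with the cell-level and organ-level measurements the
biology is read with. It is aimed at plant developmental biologists and
modelers who want to probe the polarization hypotheses or reuse the
quantification steps.

## What is in the box

* `leafmargin.tissue` — the margin strip: cell grid with 4-neighborhood
  adjacency, MD/PROX identity ramps whose product defines the CUC domain
  (`cuc = cuc_max * md * prox`), auxin source at the distal tip, and
  wild-type / cuc-mutant / clone-mosaic scenario templates.
* `leafmargin.dynamics` — the core model. Auxin obeys

      da_i/dt = production - turnover + D * sum_j (a_j - a_i) - sum_j J_ij,
      J_ij = T (eff_i P_ij a_i - eff_j P_ji a_j),

  and each cell allocates a fixed PIN budget over its membranes either
  up-the-gradient (UTG, toward auxin-rich neighbors) or with-the-flux
  (WTF, reinforcing membranes with net efflux). The CUC-dependent
  phosphorylated fraction `phi = cuc^h / (K_c^h + cuc^h)` either switches
  the rule from UTG to WTF (**PMM**) or multiplies transport efficiency by
  `epsilon` (**EMM**); `utg_only` is the CUC-blind control.
* `leafmargin.patterns` — net-polarity fields and direction classes,
  polarity-convergence detection, middle-column auxin profiles, emergent
  maximum detection, and seeded noise-robustness ensembles.
* `leafmargin.quantify` — microscopy-style cell-table analyses: membrane
  dominance polarity calls, the five-cell reversal-position estimator,
  polarity frequency tables with a chi-squared test, point-biserial
  correlation, per-sample expression regressions, and 4x4-cell ROI
  selection.
* `leafmargin.morphometry` — leaf silhouettes as polygons and the
  Normalized Difference Margin Complexity,
  `NDMC = (P_contour - P_hull) / (P_contour + P_hull)`.
* `leafmargin.synth` — generators with planted ground truth standing in
  for segmented microscopy data: margin cell tables (planted reversal
  front, planted reporter correlation) and lobed leaf silhouettes.

The numbered scripts under `analysis/` run the package end to end and
write their tables under `results/`; `docs/methods.md` documents the model,
parameter choices and limitations.

## Worked example

```python
import leafmargin as lm

wt = lm.make_template("wt")                 # 14x5 strip, CUC on rows 7-11
params = lm.ModelParams(variant="pmm")      # baseline calibration
result = lm.run_to_steady_state(wt, params)

field = lm.net_polarity(result.final_state, wt.tissue, params.P_tot)
profile = lm.column_profile(result.final_state, wt.tissue, wt.tissue.mid_col)
print(lm.detect_emergent_maxima(profile, source_row=2))
```

prints

```
[(13, 2.0826...)]
```

— a single emergent auxin maximum at row 13 of the middle column, just
proximal to the CUC domain (rows 7-11), with amplitude about 2.1 a.u.
against a profile median near 0.8. The polarity field shows the band cells
repolarized basally (the CUC-dependent reversal) and the cells around row
13 transporting into the new convergence, while the same parameters on a
`cuc_mutant` template leave the distal source as the only maximum. Running

```
python analysis/01_simulate_margin_models.py
```

prints one line per scenario, e.g.

```
wt_pmm         converged=True  emergent maxima=[(13, 2.082...)]  basal CUC-domain cells=8
cuc_mutant_pmm converged=True  emergent maxima=[]  basal CUC-domain cells=0
```

and `analysis/02_noise_robustness.py`, `03_cell_quantification.py`,
`04_leaf_complexity.py` cover the noise ensembles, the cell-table
statistics and the silhouette complexity sweep.

## Command line

A thin CLI wraps the same functions:

```
leafmargin simulate --variant pmm --out out/           # state + profile + SVG
leafmargin ensemble --variant emm --noise-target auxin --amplitude 0.10 \
    --n-reps 20 --seed 7 --out out/
leafmargin quantify --table cells.csv --analysis reversal --out out/
leafmargin morphometry --silhouette leaf.csv --out report.yaml
leafmargin synth --kind cells --seed 1 --out cells.csv
```

Cell tables are plain CSV with the documented header
(`cell_id,x_um,y_um,dist_tip_um,ch_cuc,ch_wag,ch_pin,seg_distal,
seg_proximal,seg_lat1,seg_lat2,group`); templates and parameter sets are
YAML; silhouettes are two-column vertex text or line-segment SVG paths.

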