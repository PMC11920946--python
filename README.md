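# pupilfield

**Tracking covert visual attention from pupillometry in dynamic scenes.**

Covert attention — attention deployed away from where the eyes point —
normally requires probe tasks or EEG to measure.  `pupilfield` implements
a physiological alternative: the pupillary light response (PLR) to a
dynamic stimulus is modelled region by region across the visual field,
and the fitted *regional weights* reveal where attention was deployed,
because luminance changes in attended regions drive the pupil more
strongly than their physical magnitude warrants.

The package is for researchers in psychophysiology, vision science and
cognitive neuroscience who record eye tracking and pupil size while
participants view movies or other rich stimuli, and who want a
fixation-compatible, response-free index of covert spatial attention.

## The model

The visual field is tessellated gaze-contingently (a central disc + 5
eccentricity rings × 8 sectors = 41 retinotopic regions).  Per frame
transition, each region's mean-luminance change `e_r[k]` (cd/m²) is
extracted with the tessellation re-centred on the momentary gaze.  Each
stream is convolved with a gamma-family pupil response kernel

    h(t) = (t / t_max)^n · exp(n (1 − t / t_max)),    n = 10.1, t_max = 0.93 s,

negative-signed for luminance increments (constriction), positive for
decrements (dilation), and the observed per-frame change of the z-scored
pupil is modelled as a non-negatively weighted sum:

    Δpupil[k] = Σ_r w_r (h ⊛ e_r)[k] + ε[k],    w_r ≥ 0.

Weights are fitted by constrained least squares on the first 70 % of each
trial and scored (R², RMSE) on the held-out 30 %.  Right-minus-left side
means of the weights then quantify three drivers of covert attention:
stimulus-driven (bottom-up) capture, instruction-driven (top-down)
allocation, and the inherent leftward bias of healthy adults
(pseudoneglect).

## Worked example

A complete synthetic experiment (36 participants × 4 attention
conditions × 8 × 60-s movie trials, the design the analysis targets) with
all three attentional drivers switched on, analysed end to end:

```python
import pupilfield as pf

cohort = pf.simulate_cohort(seed=0)       # known ground truth
stats = pf.analyze_cohort(cohort)         # preprocess -> fit -> statistics
print(stats.report())
```

```
Covert-attention drivers
================================================
bottom-up r (amplitude of luminance changes): estimate = 0.4996, stat = 0.500, df = 34, p = 0.001919
bottom-up r (number of luminance changes): estimate = 0.4943, stat = 0.494, df = 34, p = 0.00218
top-down contrast (attended - unattended weight): estimate = 2.526e-06, stat = 1.651, df = 35, p = 0.1077, d = 0.28
pseudoneglect (right - left weight): estimate = -4.728e-06, stat = -3.798, df = 35, p = 0.0005569, d = -0.63
gaze control (more-gazed - less-gazed weight): estimate = -3.067e-07, stat = -0.291, df = 143, p = 0.7718, d = -0.02
gaze control r (dw vs horizontal gaze): estimate = 0.07299, stat = 0.073, df = 142, p = 0.3846
driver regression (AIC-selected): dw ~ composite
  selected interactions: none
  mean held-out R^2 of pupil model: 0.481
```

Reading the output: the pupil model explains ~48 % of held-out pupil
change variance.  Weight asymmetries correlate positively with saliency
asymmetries (bottom-up, r ≈ 0.50), the attended side carries higher
weights (top-down, positive contrast; a deliberately moderate effect in
this noisy regime), and the right-minus-left weight difference is
negative (pseudoneglect, d ≈ −0.6) — while neither gaze-control test
shows a gaze confound, because the model is gaze-contingent.  Signs and
magnitudes recover the generative ground truth; single-seed p-values
fluctuate (the validation suite quantifies recovery across 20 cohort
seeds).

A single participant × condition fit is a statsmodels-style results
object:

```python
cell = cohort.participants[0].cells["left"]
trials = [pf.preprocess_trial(t) for t in cell.trials]
fit = pf.fit_condition(trials, kernels=cohort.kernels())
print(fit.summary(cohort.region_map))
```

```
Pupil response model (non-negative regional weights)
========================================================
n samples (train/test):  4093 / 1731
held-out R^2:            0.3902
held-out RMSE:           0.0027
training R^2:            0.6771
active regions (w > 0):  38 of 41
--------------------------------------------------------
...per-region weight table (region, ring, sector, weight)...
```

`fit.weights` is a pandas Series over region ids,
`fit.plot_weights(region_map)` renders them as a visual-field map, and
`pf.side_weights(fit, region_map)` returns the left/right means and
their difference.

## Command line

The same pipeline runs from a shell on plain-text datasets:

```bash
pupilfield simulate   --out data/raw --seed 1 --participants 8 --trials 4
pupilfield preprocess --data data/raw  --out data/proc
pupilfield fit        --data data/proc --out data/fits
pupilfield attention  --data data/proc --out attention.json
pupilfield erp        --data data/proc --out erp.json
pupilfield report     --data data/raw  --out report.json
```

Every output table carries the configuration hash and seed in a header
comment; excluded trials are logged with the rule that triggered the
exclusion.

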