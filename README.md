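# enose

Odor classification for electronic noses built on chemiresistive
(single-walled carbon-nanotube) sensor arrays. The package implements the
full processing chain from raw 66-channel device frames to a cross-validated
odor classifier, plus a synthetic session simulator so the whole chain can
be developed and tested without hardware.

**Who it is for.** Anyone working with e-nose devices that record a
resistance vector per frame over a three-phase measurement protocol
(air → odor exposure → air): distillery/food QC, volatolomics, gas-sensing
research.

## The method

A measurement session is 300 frames at 1.8 s/frame, split into three equal
phases: pre-exposure air (A), odor exposure (B), post-exposure air (C). Each
frame's 64 sensor channels collapse into 15 odor features *f1..f15* by
averaging like-behaving channels (reference channels are excluded). Each
feature column *S* then passes through:

1. **Smoothing** — Savitzky–Golay filter, window 51, degree 3:
   `S_smooth = F_51,3(S_raw)`.
2. **Drift correction** — an OLS line `D_p(t) = a + b·t` fit to the first
   100 samples (phase A) is extrapolated over the session and removed:
   `S_drift = S_smooth − D_p + S_smooth[0]`.
3. **Normalization** — centre-reduction over the whole session:
   `S_norm = (S_drift − μ) / σ` (population σ).

From the drift-corrected signal, per-column scalar indicators summarize the
transient response: `R` (max over phase B), `R0` (mean over phase A),
`R10..R75` (means over the leading 10–75 % of phase B), `Ind1 = R − R0`,
`Ind2 = (R − R0)/R0`, and `Ind3 = Ind2 / sqrt(Σ_i ((R0_i − R_i)/R0)²)` with
`R0_i` the drift-line prediction at sample *i*. One indicator per odor
feature gives a fixed width-15 classifier input.

The exposure class is under-represented 1:2 by protocol design, so SMOTE
(k = 4 neighbours, per-substance) balances it. Five scikit-learn models
(Gaussian NB, logistic regression, 100-tree Gini random forest, MLP, RBF
SVM) are compared by stratified 5-fold cross-validated accuracy, indicator
by indicator; PCA projection is available for visual inspection.

## Worked example

```python
import enose as en

# simulate the standard protocol: 4 substances x 5 campaigns x 300 frames
sessions = en.simulate_dataset(en.default_signatures(), n_campaigns=5,
                               noise_schedule=en.default_noise_schedule(5),
                               seed=42)
processed = [en.preprocess_session(s) for s in sessions]

table = en.build_feature_table(processed, indicator="R")      # 20 x 15
acc = en.evaluate_cv(table, en.ModelSpec("random_forest"), folds=5, seed=0)
print(f"RF 5-fold accuracy on indicator R: {acc:.2f}")
# RF 5-fold accuracy on indicator R: 1.00

tp = en.build_feature_table(processed, granularity="timepoint")
print(len(tp), int((tp.phase == "B").sum()))
# 6000 2000
aug = en.smote_augment(tp, cfg=en.SmoteConfig(4, 1.0, 0))
print(len(aug))
# 8000
```

The simulated dataset reproduces the protocol accounting (6000 labelled
time points, 2000 in the exposure phase, 8000 after +100 % SMOTE), and on
the default well-separated signature preset the random forest recovers the
class structure perfectly from indicator `R`.

The same pipeline is scriptable from the shell:

```bash
enose simulate --out sessions.csv --seed 42
enose featurize --in sessions.csv --out table.csv --indicator R
enose train --config config.yaml --out rundir
```

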