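# tacfit

Model selection and time-integrated activity estimation for whole-body
time-activity curves in molecular radiotherapy.

## What this is for

After a therapeutic administration of [131I]I-NaI (metastatic
differentiated thyroid carcinoma), the whole-body fraction of injected
activity FIA(t) is measured a few times during hospitalisation and once
at a late follow-up.  Dosimetry needs the area under that curve, the
time-integrated activity coefficient

&nbsp;&nbsp;&nbsp;&nbsp;τ = ∫₀^∞ FIA(t) dt = Σᵢ Aᵢ/λᵢ  [h],

where FIA(t) = Σᵢ Aᵢ·exp(−λᵢt) is a mono-exponential (MEf, i = 1) or
bi-exponential (BEf, i = 1, 2) retention model.  With only 4-20 noisy
points per patient, the hard part is choosing the model family and
getting τ without large bias.  `tacfit` implements, and benchmarks
against each other on synthetic patient-like curves:

* **fit + AICc** — bounded trust-region least squares of both families
  (curve-stripping starting values), scored by the corrected Akaike
  criterion AICc = N·ln(SS/N) + 2K + 2K(K+1)/(N−K−1);
* **fit + AICc-W** — τ model-averaged with Akaike weights
  wᵢ = e^(−Δᵢ/2)/(1+e^(−Δᵢ/2));
* **fit + F-test** — the extra-sum-of-squares test
  F = ((SS_ME−SS_BE)/SS_BE)/((DF_ME−DF_BE)/DF_BE) at α = 0.05;
* **ML1 + ML2** — a soft-voting pair of logistic regressions classifies
  the family from the raw (t, FIA) coordinates, then per-parameter
  AdaBoost/gradient-boosted-tree ensembles predict (Aᵢ, λᵢ) directly.

The synthetic generator, the chains, and the benchmark harness
(classification accuracy and Δτ distributions versus the number of curve
points N) are all part of the package; see `docs/methods.md` for the
model, the sampling band, and every numerical choice.

## Worked example

Simulate four noisy 6-point curves (two per family) and run the
fit + F-test chain:

```
$ tacfit simulate --n-points 6 --n-me 2 --n-be 2 --noise 0.05 --seed 42 --out data
wrote 4 curves to data
$ tacfit fit --in data/tacs.csv --model auto-ftest --out fits.csv
fitted 4 curves -> fits.csv
```

`fits.csv` (columns abridged):

```
 curve_id chosen_model     A1  lambda1     A2  lambda2  f_stat  p_value     tau
        0          MEf 0.9402   0.0274    NaN      NaN  0.8301   0.5464 34.3205
        1          MEf 0.8916   0.0468    NaN      NaN  2.9293   0.2545 19.0390
        2          MEf 0.9612   0.0272    NaN      NaN  0.4039   0.7123 35.3953
        3          BEf 0.5058   0.0536 0.4715   0.0160 21.8504   0.0438 38.8899
```

Curves 0-1 are true mono-exponentials and are kept as MEf (p ≫ 0.05).
Curves 2-3 are true bi-exponentials: curve 3 is detected (p = 0.044 <
0.05) and fitted as BEf, while curve 2 — the textbook small-N failure
mode — is *not* distinguishable from a mono-exponential at six points
(p = 0.71) and is fitted as MEf.  Its τ (35.4 h vs. a true 37.1 h, −4.7 %)
is still usable here; across a whole test set such misclassifications
are what produce the negative tail of the Δτ distribution at small N.
The generating parameters are in `data/truth.csv`.

The ML route works the same way from the shell (`tacfit train`,
`tacfit classify`, `tacfit predict --class-from ml1`), and everything is
also a library API (`tacfit.fit_both`, `tacfit.f_test_select`,
`tacfit.TACModelChain`, ...).  The full benchmark over a sweep of N is
`tacfit benchmark --n-set 4,5,6,...,20 --seed 0 --out report/`, which
writes per-N classification accuracies and Δτ summaries as CSV.

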