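# painloop

**Closed-loop pain decoding and adaptive stimulus control — a tested
simulation and analysis toolkit.**

`painloop` reimplements, as a fully synthetic and reproducible pipeline, the
analysis chain of a closed-loop brain-machine interface for pain: a decoder
reads out the probability that a just-delivered electrical stimulus was
high-intensity from multivoxel brain responses, and a trial-and-error
controller uses that probability as its only feedback to learn which of two
stimulators to trigger — steering stimulation toward low pain.  Around that
loop sit the behavioral analyses such a study needs: a Bayesian model of how
subjects track stimulus frequency (and how the resulting uncertainty couples
to pain ratings), and a temporal contrast enhancement (onset hyperalgesia /
offset analgesia) test of endogenous pain modulation.

It is aimed at researchers in computational neuroscience and neuroengineering
who want to prototype, stress-test, or teach closed-loop neurofeedback
designs without access to scanner data: every input is generated by the
package's own synthetic-data module with known ground truth.

## The models

**Decoder.**  Trial features are session-baseline z-scored voxel responses
averaged over the TRs where the hemodynamic response peaks (TRs 3–5).
Classification uses variational-Bayes sparse logistic regression with
automatic relevance determination (ARD): each weight $w_j$ has a prior
$\mathcal N(0, \alpha_j^{-1})$ whose precision $\alpha_j$ is estimated
(Jaakkola–Jordan local bound + MacKay fixed-point updates); irrelevant voxels
acquire huge precisions and are pruned.  Performance is reported by
stratified 10-fold CV as accuracy / sensitivity / specificity (high pain =
positive) and the mean retained-voxel count.

**Controller.**  Decoded $P(\text{pain})$ is scaled to $[-1,1]$ and drives a
delta-rule value update for the chosen action $a \in \{\text{high, low}\}$:

$$Q_{t+1}(a) = Q_t(a) + \alpha\,(-P_{\text{scaled}} - Q_t(a)), \qquad \alpha = 0.5,$$

with ε-greedy selection (explore with probability ε = 0.4, uniformly over
both stimulators; otherwise argmax of Q) and values reset to 0 at each of
the 6 sessions of 30 trials.

**Frequency learning.**  Subjects track the relative frequency of high/low
stimuli with a Beta–Bernoulli model restarted at Beta(1, 1) each session;
memory can leak with factor ω (an observation at lag $t$ counts
$e^{-t/\omega}$).  The per-trial uncertainty predictor is the surprisal
$-\log_2 p$ of the realized stimulus under the pre-update posterior mean
$p(h\mid N_h,N_l) = (N_h+1)/(N_h+N_l+2)$.  Rating residuals (identity and
session trends removed) are regressed on surprisal; ω is selected by a BIC
grid search ($\mathrm{BIC} = n\ln\hat\sigma^2 + \kappa\ln n$), and group
correlations are summarized by Fisher-z transforms with one-sample t tests.

**Temporal contrast enhancement.**  Continuous 0–10 ratings of a
45–46–45 °C thermal train (7 s per phase) are z-normalized within
subject+condition; the modulation magnitude is $T2_{\max} - T3_{\min}$, and
the post-minus-pre change is compared between an experimental and a control
group via pooled-SD Cohen's d with a percentile-bootstrap CI.

## Worked example

Run the full experiment replica (decoder CV → closed loop → frequency model
→ contrast analysis) on synthetic data:

```bash
painloop run-replica --seed 2
```

Key excerpts of the printed JSON report:

```json
"closed_loop": {
  "high_pain_percentage": 36.95906432748538,
  "mean_q_high": -0.2260562740438088,
  "mean_q_low": -0.03566572764383198,
  "paired_t": -3.943600581269906
},
"frequency_model": {
  "group_omega": 10,
  "mean_beta1": 0.8160359414559842
},
"contrast": {
  "cohens_d": 0.9787291337767348,
  "ci": [0.48082144089861034, 1.5981766913701758]
}
```

Reading this: the controller delivered high pain on ~37% of trials (below
the 50% a blind controller would give) and learned to value the low-pain
stimulator above the high-pain one (mean Q(high) = −0.226 vs
Q(low) = −0.036, paired t = −3.94 across 19 simulated subjects).  The
frequency-learning fit recovered the generating leak (ω\* = 10) and
uncertainty coupling (β₁ ≈ 0.82 for a true 0.8), and the contrast pipeline
yields a group effect of d ≈ 0.98 with a bootstrap 95% CI excluding zero.

Equivalent library calls:

```python
import painloop as pl

res = pl.run_closed_loop(pl.calibrated_emission_model(), seed=1)
print(res.high_pain_percentage())
print(res.summarize_values().summary())
```

Other CLI entry points: `make-synthetic`, `train-decoder`, `simulate-loop`,
`fit-frequency-model`, `contrast-analysis`.

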