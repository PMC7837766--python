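# Methods

## Data representation

A cumulative DVH is stored as the dose `D_v` at each percent volume
`v = 1%, …, 100%` (bin width Δv = 1%), in Gy, double precision. On this
equal-volume grid the generalized equivalent uniform dose is the power mean

    EUD(a) = ( Σ_j (Δv/100%) · D_j^a )^(1/a),  Δv/100% = 0.01,

evaluated in log space (doses scaled by their maximum before
exponentiation) so large `a` does not overflow. `a = 1` is the mean dose;
`a → ∞` approaches the maximum dose. The maximum dose is defined as the
dose at the 1% bin — the 0% tail is not on the sampled grid and
extrapolating to it would be arbitrary. Resampling an arbitrary cumulative
curve onto the grid interpolates linearly in the (volume → dose) direction;
where several doses share one volume (a flat stretch of the cumulative
curve) the maximum dose is taken, the conservative choice for serial
organs. Equality comparisons on doses use 1e-9 Gy absolute tolerance.

Per organ the model inputs are the nine DVHs produced by nonmodulated
conformal fields at gantry angles 160, 200, 240, 280, 320, 0, 40, 80,
120 degrees, in that fixed order.

## Model

A stacked GRU (default one layer) runs over the 100 volume steps in
ascending volume order; the per-step input is the vector of the nine beam
doses at that volume divided by the prescription dose (70 Gy). A dropout
layer (p = 0.5) sits between the top hidden state and a one-unit affine
head shared across steps; dropout is active only during training
(inverted dropout). Per-step outputs are multiplied back by the
prescription dose, clipped at zero, and made monotone non-increasing by a
running maximum taken from the 100%-volume tail — the repair never changes
an already monotone curve and never alters the global maximum. The target
plan dose is never fed back as an input (no teacher forcing), so
prediction needs only the beam DVHs.

The sequence direction is a configuration flag; ascending is the default
so the clinically critical high-dose head is consumed first while the
recurrence still sees the whole curve.

The GRU forward pass, backpropagation through time, and Adam are
implemented in NumPy in `dvhgru.nn` (float64 throughout, PyTorch-layout
gate packing, Uniform(−1/√H, 1/√H) initialization). The backward pass is
verified against central finite differences to ~1e-5 relative in the test
suite; all randomness (initialization, dropout masks, batching) flows from
explicit seeds, so fits are bit-reproducible.

## Loss and per-organ training

Training minimizes the sensitivity-weighted squared error

    f(DVH', DVH, k) = (1/n) Σ_p Σ_i s(D_i, k) (D'_i − D_i)²,
    s(D_i, k) = D_i^(k−1) / Σ_j D_j^(k−1),

with `n` the number of patients in the batch and the weights computed per
patient from the target plan doses and treated as constants (no gradient
flows through `s`), keeping the loss a proper weighted MSE. At `k = 1` the
weights are uniform (1/100 per bin) and `f` is plain MSE; the per-bin
1/n_bins factor enters only through `s`, so for `k > 1` the loss is
normalized by the weight sum rather than the bin count — exactly the
printed form. The weights are scale invariant, so computing them on
normalized or Gy-scale targets is equivalent. The derivative of the EUD
with respect to a single dose bin, which motivates the weighting, is not a
public operation: it is recovered implicitly by differentiating the loss.

Each organ gets its own model, trained full batch with Adam at learning
rate 1e-3 (50 sequences of length 100 fit trivially in one batch).
Defaults: hidden size 32 and 400 epochs, sized so a per-organ fit takes on
the order of ten seconds on one CPU with this NumPy trainer while leaving
the synthetic mapping fully learnable; both are configuration-exposed.
Optional early stopping (patience on a validation loss) returns the
parameters of the best recorded validation epoch. A non-finite loss aborts
with the epoch and learning rate in the diagnostic.

Organ defaults (loss exponent `k`, EUD exponent `a`; serial ⇔ a = 8):

| organ | k | a | | organ | k | a |
|---|---|---|---|---|---|---|
| brainstem | 8 | 8 | | larynx | 1 | 1 |
| spinal cord | 15 | 8 | | parotid L/R | 1 | 1 |
| optic nerve L | 3 | 8 | | temporal lobe L/R | 1 | 1 |
| optic nerve R | 2 | 8 | | chiasm | 1 | 8 |

The optic-nerve values differ between the two sides despite symmetric
anatomy; this is data-dependent and surfaced as-is rather than resolved.

`grid_search_k` replays the trial-and-error selection: one model per
candidate `k`, scored on a held-out validation split by
`|μ_EUD| + σ_EUD`, plus `|μ_Dmax| + σ_Dmax` for serial organs — the
composite mirrors the reporting statistics; ties break toward smaller `k`.

The "previous method" comparison arm is a deliberately simple stand-in for
earlier multi-organ predictors: one 3-layer GRU trained jointly on all
organs with the uniform `k = 1` loss and an organ-identity one-hot
appended to each step's input. It is labelled as a stand-in wherever it is
reported.

## Evaluation

Per test patient, `δ_i = predicted − planned` endpoint in Gy, with
endpoints EUD(a) always and the maximum dose for serial organs only.
`μ = mean(δ)`; `σ = sqrt(Σ(δ_i − μ)²/n)` uses the population denominator
`n`, not `n − 1` — deliberately different from most library defaults, and
worth remembering when comparing to `np.std(..., ddof=1)`. Methods are
compared patient-wise by a two-sided Wilcoxon signed-rank test on the
signed `δ` pairs (a flag switches to |δ|): zero differences are discarded;
for n ≤ 15 the exact null is enumerated over all sign assignments of the
tie-averaged ranks with `p = 2·min(P(W ≤ w), P(W ≥ w))` capped at 1;
larger n uses the normal approximation with tie correction (no continuity
correction). The 0.05 significance convention is recorded with the report,
not enforced anywhere. Agreement is summarised by ordinary least squares
of predicted on planned values with the Pearson `r`, pooled across organs
and endpoints by default (per-organ regressions are available — pooling
mixes organs with different `a`, which is how such scatter summaries are
conventionally shown). Boxplot summaries use linearly interpolated
quartiles (NumPy's default convention) and whiskers at the most extreme
points within 1.5·IQR of the box.

## Synthetic cohort

Clinical cohorts are private, so experiments run on a seeded generator
with the statistical structure the method assumes. Per patient a latent
anatomy factor `x_p ~ Uniform(0.5, 1.5)` scales all doses; beam `b` of an
organ with dose scale `M` contributes
`D_b(v) = x_p · M · w_b · (1 − v/100)^γ_b`; the plan is the mixture
`Σ_b c_b D_b(v)` plus i.i.d. Gaussian noise (default σ = 1 Gy), repaired
to a monotone curve by a running maximum from the tail — chosen over
isotonic alternatives because it preserves the high-dose head that
serial-organ losses target — and clipped to 1.2× the 70 Gy cap. The
default profiles cover the ten standard head-and-neck organs with dose
scales 20–60 Gy; serial organs get one sharper beam so a modest hot head
exists. With noise off, the plan is an exact linear function of the nine
beam doses, so ground truth is known and a capable model can drive the
training loss toward zero.

`serial_scenario` is the stress fixture for the weighted loss: one beam is
sharp (γ = 6) and strong, concentrating 45% of the plan mixture on a
small sub-volume, with noise σ = 1.5 Gy; the head then spans tens of Gy
across patients while 99% of the curve is dominated by broad beams, making
the maximum dose the hard part of the prediction.

What the generator does **not** emulate: anatomical geometry and
overlap/distance features, target-volume coverage normalization,
inter-organ correlations within a patient beyond the shared latent factor,
multi-modal patient subgroups, and beam-model physics. Passing tests
therefore demonstrate that the pipeline recovers a learnable beam-to-plan
relationship under controlled noise — not clinical-grade accuracy on real
plans.

## Experiment configurations

Two experiments deviate from the package defaults, for stated reasons:

* **Noiseless recovery** (acceptance test and script): dropout off,
  hidden 32, 400 epochs. The check is that optimization can drive the loss
  to ~0 on an exactly learnable mapping; an active dropout ridge penalty
  makes that impossible by construction and biases predictions low.
* **Serial-organ k replay**: hidden 8, dropout off, 1000 epochs, cohort of
  60 (40 train, of which 10 validate the k grid {1, 8, 15}; 20 test). The
  benefit of `k ≫ 1` is a capacity-allocation effect: it decides where a
  model that cannot fit everything spends its capacity. With a generously
  sized network both arms converge fully on this family and the effect
  vanishes; the small hidden state reproduces the intended regime (scarce
  capacity relative to the sharp head), and dropout is off so the
  comparison isolates the loss weighting. Under this configuration the
  grid prefers `k > 1` and the selected arm's max-dose error spread beats
  the uniform-loss arm in most seeds, with the 3-layer joint baseline
  doing no better than the per-organ weighted arm on average.

Problem sizes throughout (80-patient cohorts, 50/30 splits, 400–1000
epochs) are the package's own defaults chosen to keep any single
experiment in the minutes range on one CPU.

## Known limitations

* The NumPy trainer is single-threaded BLAS-bound; it is sized for
  50-sequence cohorts, not large-scale training.
* Checkpoints serialize weights as JSON number lists — exact and portable,
  but not compact.
* The previous-method arm approximates earlier multi-organ predictors
  structurally (depth, joint training, uniform loss); it is not a
  reimplementation of any specific published system.
* Differential DVHs, absolute-volume (cc) DVHs, NTCP/TCP models, and
  DICOM-RT parsing are out of scope; the CSV exchange format is the
  package's interface to planning systems.
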