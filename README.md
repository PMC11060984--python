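# mskpinn

Multi-resolution physics-informed recurrent networks for sEMG-driven
musculoskeletal motion prediction and Hill-type muscle parameter
identification.

## The problem

Surface electromyography (sEMG) measures muscle electrical activity
non-invasively; mapping it to joint motion is central to rehabilitation
assessment and assistive-device control. The forward-dynamics chain for a
single-degree-of-freedom elbow is

    u(t) = e(t − d)                                  (delayed excitation)
    a(t) = (exp(A·u) − 1) / (exp(A) − 1)             (activation dynamics)
    Fᴹᵀ  = f₀ᴹ (a·fl(l̃ᴹ)·fv(ṽᴹ) + fp(l̃ᴹ)) cos ϑ     (Hill-type muscle)
    I q̈  = R_bi(q)·Fᴹᵀ_bi + R_tri(q)·Fᴹᵀ_tri + E(q)  (equation of motion)

with a rigid tendon, law-of-cosines muscle paths over the hinge, gravity
and passive joint end-stops in E(q). The inverse problem — recovering the
maximum isometric forces f₀ᴹ and optimal fiber lengths l₀ᴹ of the
antagonist pair from (sEMG, motion) recordings — is ill-conditioned and
noise-sensitive.

`mskpinn` trains a gated recurrent unit (GRU) surrogate of the forward
dynamics with teacher forcing on m history steps, minimizing a composite
physics-informed objective

    J(θ, Γ) = J_data(θ) + β · J_res(θ, Γ),

where J_data is the mean squared one-step-ahead motion misfit and J_res is
the mean squared residual of the equation of motion evaluated at the
surrogate's predicted kinematics, with the parameter vector
Γ = {f₀_Bi, l₀_Bi, f₀_Tri, l₀_Tri} among the trainables. Training proceeds
coarse-to-fine through a wavelet multi-resolution ladder (Daubechies-2):
the network first learns the mapping on low-pass projections of the
signals, then transfers its weights to progressively finer scales until the
raw data; the parameter read-out happens at the full scale. The package
also ships the synthetic verification study: sinusoidal antagonist sEMG
envelopes with controlled Gaussian noise, ground-truth motions solved by an
adaptive Runge–Kutta integrator, and a scale-depth comparison over multiple
initialization seeds.

Everything is pure scientific Python (numpy/scipy/PyWavelets/pandas),
including a small reverse-mode autodiff tape and the GRU
backpropagation-through-time kernel.

## Worked example

```python
import numpy as np
from mskpinn import ElbowModel, MultiResolutionPIGRU, generate_verification_set

model = ElbowModel()                      # reference forward-dynamics setup
trials = generate_verification_set(1, model=model, seed=0)
pigru = MultiResolutionPIGRU(
    train_trials=[trials[i] for i in (0, 1, 3, 4)],
    test_trial=trials[2],
    msk_model=model,
)
res = pigru.fit(seeds=[0])
truth = {"f0_Bi": 300.0, "l0_Bi": 0.6, "f0_Tri": 300.0, "l0_Tri": 0.4}
print(res.summary(truth))
```

prints (about a minute on one core):

```
Multi-resolution physics-informed GRU fit
==========================================================
scales [-2, -1, 0]  epochs/scale [300, 300, 300]  hidden 50  history m=2  seeds [0]
beta 0.001  derivative finite_difference
----------------------------------------------------------
parameter       estimate      seed std
f0_Bi         245.0456 N       0.0000
l0_Bi           0.5000 m       0.0000
f0_Tri        299.7155 N       0.0000
l0_Tri          0.4430 m       0.0000
----------------------------------------------------------
mean %error vs truth: f0_Bi:-18.32%  l0_Bi:-16.66%  f0_Tri:-0.09%  l0_Tri:+10.74%
----------------------------------------------------------
rollout on test trial: MSE 2.046e-02  R2 0.650  NMSE 7.000e-04
```

The estimate block lists the identified muscle parameters in physical
units with their spread over initialization seeds (a single seed here, so
zero). The rollout line scores the model on the held-out trial in fully
autoregressive mode — the network sees measured motion only through the
two-sample seed and then feeds back its own predictions for the remaining
498 steps; R² = 0.65 means the surrogate explains about two thirds of the
held-out motion variance from the (noisy) sEMG alone. The triceps maximum
isometric force is recovered to a tenth of a percent; the biceps pair is
recovered with a systematic offset, a known limitation of the surrogate's
capacity discussed in `docs/methods.md`.

A command-line interface exposes the same workflows:

```sh
mskpinn synth --case 1 --seed 0 --out data/
mskpinn train data/trial_1.csv data/trial_2.csv data/trial_4.csv data/trial_5.csv \
        --test data/trial_3.csv --scales 3 --out fit/
mskpinn verify-experiment --case 1 --out results/
```

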