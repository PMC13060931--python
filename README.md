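# driftssm

State-space models with **drifting orthonormal emission subspaces**,
for tracking representational drift in neural population recordings.

## The problem

Linear dynamical systems (LDS) explain high-dimensional neural activity
`y_t ∈ R^N` with low-dimensional latent dynamics `x_t ∈ R^D` read out
through a fixed emission matrix `C`. But within a session the mapping
from latent content to recorded channels can change gradually —
*representational drift* — while the underlying computation stays
stable. A fixed-`C` model absorbs drift by inflating its latent
dimension and blurring its dynamics.

`driftssm` keeps the latent dynamics shared across the session and lets
the emission matrix move: `C^{(k)}` is constrained to the Stiefel
manifold `St(N, D) = {C : CᵀC = I}` and performs a smooth Gaussian
random walk over trial blocks,

    x_{t+1} = A x_t + b + q_t,   q_t ~ N(0, Q)
    y_t     = C^{(k)} x_t + r_t, r_t ~ N(0, R)
    C^{(k)} = h(z^{(k)}) = U_base (I − B(z))(I + B(z))^{-1} [I_D; 0]
    z^{(k+1)} = z^{(k)} + e^{(k)},  e^{(k)} ~ N(0, diag(τ²))

where `B(z)` is a skew-symmetric matrix built from the displacement
`z`, mapped to a rotation by the Cayley transform. One part of `z`
rotates the basis within the subspace; the other tilts the subspace
itself. Per-coordinate drift rates `τ²` let each subspace axis rotate
at its own speed. Fitting is by structured mean-field variational EM:
exact Kalman smoothing for the states, extended Kalman smoothing for
the displacement chain, closed-form M-steps with a conjugate
Inverse-Gamma update (and clipping) for `τ²`.

Drift is quantified with principal angles and the geodesic Grassmann
distance `d_G(C_1, C_2) = (Σ_d θ_d²)^{1/2}` (normalized by its maximum
`(π/2)√D`), plus per-dimension drift angles in degrees.

See `docs/methods.md` for the full model, inference details, and
default hyperparameters.

## Worked example

Simulate the reference synthetic session (750 trials of 30 timesteps,
10 channels, a 2-D latent rotating ~15°/step, the emission subspace
drifting ~0.8° per 5-trial block), hold out 12 random blocks, and
compare the drift model against a plain LDS:

```python
import numpy as np
from driftssm import (simulation_config, sample_smds, make_splits,
                      StiefelDriftSSM, LinearGaussianSSM, drift_report,
                      grassmann_distance)

params, sizes = simulation_config("main")
data, truth, _ = sample_smds(params, sizes["n_blocks"],
                             sizes["trials_per_block"], sizes["T"], seed=0)
split = make_splits(data, n_splits=1, heldout_blocks_per_split=12, seed=0)[0]
train = data.subset_blocks(split["train"])
held = data.subset_blocks(split["heldout"])

model = StiefelDriftSSM(n_components=2, max_iter=25).fit(train)
baseline = LinearGaussianSSM(n_components=2, max_iter=25).fit(train)

print("drift model held-out log-likelihood: ", round(model.score(held), 1))
print("LDS baseline held-out log-likelihood:",
      round(baseline.score(held.pooled(), held.lengths), 1))

rec = np.median([grassmann_distance(model.emissions_[i], truth.C_blocks[b],
                                    normalized=True)
                 for i, b in enumerate(train.block_labels)])
print("median recovery error (normalized Grassmann):", round(rec, 3))

report = drift_report(model.fit_result_)
print("peak drift per dimension (deg):", np.round(report.peak_per_dim, 1))
print("session drift, first vs last block (normalized):",
      round(report.pairwise[0, -1], 3))
```

Output:

```
drift model held-out log-likelihood:  -6147.9
LDS baseline held-out log-likelihood: -6156.0
median recovery error (normalized Grassmann): 0.02
peak drift per dimension (deg): [8.1 7. ]
session drift, first vs last block (normalized): 0.071
```

The drift model scores higher on held-out blocks than the LDS (whose
single emission matrix must average over the whole drifting session);
its per-block subspace estimates land within 0.02 normalized Grassmann
distance of the ground truth; and the drift report recovers the ~7–8°
of subspace rotation the generator accumulated over the session.

Both estimators follow scikit-learn conventions (`fit`, `score`,
`get_params`/`set_params`, fitted attributes with trailing
underscores) and also accept the concatenated layout
`fit(X, lengths=..., blocks=...)`.

A command-line interface wraps the same pipeline:

```
driftssm simulate --out session.h5 --seed 7
driftssm fit --data session.h5 --out fits/ --config run.yaml
driftssm drift --data session.h5 --out report/ --dim 2
```

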