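# biophoton-qc

Quality assessment of *Isatis indigotica* (woad) leaves from ultra-weak
photon emission. Living tissue emits a faint photon flux tied to its
metabolic state; after a light pulse this emission decays over minutes
(delayed luminescence, DL), and at rest it settles to a steady spontaneous
rate (SPE). This package implements the full analysis chain that turns
photon-count time series into herbal-quality indicators for leaves grown
under salt or drought stress, and ships a synthetic-study generator so the
whole pipeline runs and is tested end to end without instrument data.

## The model

DL decay is described by the hyperbolic-cosecant-squared law

```
I(t) = A · csch²(t/B + C)
```

with intensity scale `A` (counts/s), characteristic time `B` (s) and phase
factor `C` (dimensionless). Three macroscopic descriptors follow from a
fitted (A, B, C):

* initial intensity `I₀ = A·csch²(C)`,
* decay time `T = B·(arcsinh(√m·sinh C) − C)`, the unique time at which
  `I(T) = I₀/m` (here `m = 3`),
* window-mean intensity `I_W = (A·B/W)·[coth C − coth(W/B + C)]` over the
  `W = 300 s` measurement window.

SPE is summarized as `CPS = N − n` (mean sample rate minus dark-count
rate). The strength indicators `I₀`, `I_W`, `CPS` are normalized per
sample by `× thickness / mass`. Seven candidate parameters per sample
(A, B, C, I₀, I_W, T, CPS) are screened for stress-discriminative value
with cross-validated L1-penalized logistic regression (λ_min and 1-SE
selections), groups are compared with two-tailed unpaired t-tests and PCA,
and parameters are related to quality endpoints — five active-compound
contents, photosynthetic pigments, relative electrical conductivity, ROS
production rate and antibacterial MIC — through a Spearman correlation
network (edges at P ≤ 0.05). A pharmacopoeial rule flags groups whose
indirubin content falls below 0.02 %.

## Worked example

```python
from biophoton_qc import GuFit, derive_dl_parameters, simulate_dl_trace, fit_gu_model

# decay descriptors for a known parameter triple
d = derive_dl_parameters(GuFit(A=100, B=10, C=0.5, converged=True, residual_norm=0))
print(d.I0, d.T, d.Iw)
# 368.2694376831169 3.1077118937728154 3.8798447124621767

# recover the triple from a Poisson-noised trace over a 30 counts/s background
trace = simulate_dl_trace(1500, 10, 0.5, background_rate=30, seed=1, sample_id="leaf")
fit = fit_gu_model(trace, background_rate=30)
print(round(fit.A, 1), round(fit.B, 2), round(fit.C, 3))
# 1461.7 10.09 0.496
```

`I₀ ≈ 368.3 counts/s` is the emission at the instant detection starts,
`T ≈ 3.11 s` the time for it to fall to a third, and `I_W ≈ 3.88 counts/s`
the mean intensity over the 300-s window. The fitted triple lands within a
few percent of the simulated truth at realistic count levels.

The full pipeline runs from the shell:

```
biophoton-qc run --out out --seed 2
biophoton-qc report --out out
# selected at lambda_min: ['A', 'B', 'C', 'Iw']
# MIC consensus:    control e_coli 128 ... drought s_aureus 1024 ...
# quality:          salt_high indirubin 0.0176  passes False
```

which simulates a five-group study (control, three salinity levels,
drought; six samples per group), fits every decay curve, computes CPS and
the physiological indices, calls MICs from the simulated plates, screens
parameters, exports the correlation networks (GraphML + edge list) and
writes a manifest with content hashes for reproducibility.

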