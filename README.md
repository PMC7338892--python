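# neurocca

Online canonical correlation analysis (CCA) with multi-compartment
neuron models.

Normative models of neural computation derive a circuit's architecture,
dynamics and plasticity rules from a principled objective function.
`neurocca` implements a family of such models in which the objective is
CCA: a pyramidal neuron with two dendritic compartments performs online
single-channel CCA; a network of such neurons with asymmetric
anti-Hebbian lateral connections performs multi-channel CCA by
deflation; and a neuron with `k` dendritic compartments performs online
multiview (sum-of-correlations) CCA.  The package is aimed at
computational neuroscientists studying dendritic learning rules, and at
anyone who wants streaming, biologically constrained CCA solvers with
exact offline references.

## The models

**Single channel.**  Given centered paired samples `x_t ∈ R^n`,
`y_t ∈ R^m`, CCA maximizes `(1/T) Σ_t (aᵀx_t)(bᵀy_t)` subject to unit
projection variances.  Writing the distal and proximal dendritic
currents `c_a = aᵀx`, `c_b = bᵀy` and the somatic output
`c = c_a + c_b`, stochastic gradient ascent/descent on the Lagrangian
gives the plasticity rules

```
a ← a + η_a (c − α c_a) x          α ← α + (η_α/2)(c_a² − 1)
b ← b + η_b (c − β c_b) y          β ← β + (η_β/2)(c_b² − 1)
```

where the dendritic variables `α, β` enforce the variance constraints
homeostatically and converge to `1 + ρ₁` at the fixed point.

**Multi-channel.**  `d` such neurons interact through a strictly
lower-triangular lateral matrix `M`:
`c_i = c_a,i + c_b,i − Σ_{j<i} M[i,j] c_j`, with the local anti-Hebbian
update `M[i,j] ← M[i,j] + η_m c_i c_j`.  The triangular architecture
realizes deflation — neuron `i` learns the `i`-th canonical pair — and
`M` decays to zero at the fixed point.  A non-local baseline derived
from the standard multi-channel Lagrangian (whose decorrelation
multipliers require compartment currents of other neurons) is included;
it fails to converge under online training, which motivates the
deflation network.

**Multiview.**  A single neuron with `k` compartments,
`c = Σ_i a^(i)ᵀ x^(i)`, ascends the SUMCOR objective — the sum of
pairwise correlations of the per-view projections — with each
compartment running exactly the single-channel rules.

The exact offline solutions (whitened-SVD CCA; analytic or full-batch
multiview references) are provided as oracles, along with the metrics
used to evaluate training: normalized objective, data-weighted angular
error, absolute (mean pairwise) objective, and constraint diagnostics.

## Worked example

```python
import neurocca as nc

ds = nc.make_gaussian(n_x=5, n_y=5, T=10_000, scale_divisor=100.0, seed=1)
oracle = nc.solve_cca(ds, d=3)
state, trace = nc.train_network(ds, d=3, n_steps=400_000, seed=0, oracle=oracle)
print(oracle.rho)
print(trace.final_window_mean("normalized_objective"),
      trace.final_window_mean("angular_error"),
      trace.final_window_mean("max_abs_M"))
```

prints

```
[0.9937 0.898  0.8546]
0.9997 0.1164 0.0827
```

— the exact canonical correlations of the 10-dimensional Gaussian
benchmark, and the trained network's normalized objective (1 means the
pooled CCA objective of the learned weights equals the optimum), its
angular error against the exact solution in radians, and the largest
surviving lateral weight (near zero, as the deflation fixed point
requires).  The scripts in `examples/` walk through each capability —
single neuron, deflation network, multiview neuron on the known-optimum
svd-max construction, and image-derived views — and print what the
numbers mean.

A thin CLI mirrors the library for batch use: `neurocca generate`,
`train`, `evaluate`, `compare`, `reproduce-multichannel`,
`reproduce-multiview` (see `--help`).

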