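# ricciphase

Forman–Ricci curvature network entropy for time-varying weighted networks:
characterize the state of a complex network and detect phase transitions
between states.

## The problem

A time-varying complex network — a gene-contact map across a cell cycle, a
social or political affinity network across years, a neural architecture
across training epochs — moves between *phases*: stretches where its
topological character is invariant, separated by abrupt reorganizations.
Detecting those transitions from snapshots alone, without knowing the
generating model, is the problem this package addresses, for systems
biologists and network scientists working with weighted undirected graph
sequences.

## The method

Every edge `e = {i, j}` of a weighted graph gets its Forman–Ricci
curvature

    FR(e) = w(e) ( w(i)/w(e) + w(j)/w(e)
                   − Σ_{e_i ~ e} w(i)/√(w(e) w(e_i))
                   − Σ_{e_j ~ e} w(j)/√(w(e) w(e_j)) ),

which collapses to `4 − d_i − d_j` on unit weights — a local, O(degree)
measure of how hub-like an edge's neighbourhood is.  The state of a
snapshot `G_t` is the Shannon entropy of its curvature distribution,

    H_R(G_t) = − ∫ f_RC(x) log2 f_RC(x) dx   [bits],

with `f_RC` estimated nonparametrically by a Daubechies-4 wavelet series.
Along a parameter sweep or time axis, transitions show up as peaks of
`|dH_R/dα|`; boundaries come from thresholding the derivative at
`γ = peak/5`, and time-axis change points from jumps `|ΔH_R|` above a
robust noise scale.  Details and conventions: [docs/methods.md](docs/methods.md).

The package ships seeded generators for four synthetic study families
(α-parameterized preferential attachment, Watts–Strogatz rewiring, a
planted-community SBM schedule with merges, weighted multifractal
networks), adapters for edge lists, dense/Hi-C contact matrices, MLP
weight snapshots and roll-call vote matrices, and a CLI.

## Worked example

Sweep the growing-network family through its attachment exponent and
locate the transition:

```python
import numpy as np
import ricciphase as rp

def factory(alpha, seed):
    return rp.random_growing(rp.RGNConfig(N=1000, alpha=alpha, seed=seed))

grid = np.round(np.arange(0.5, 2.01, 0.05), 3)
trace = rp.entropy_sweep(factory, grid, realizations=50, seed=7)
deriv = rp.first_derivative(trace)
report = rp.transition_boundaries(deriv, rp.default_gamma(deriv))
print(f"plateaus: {trace.mean_entropy[0]:.2f} -> {trace.mean_entropy[-1]:.2f} bits")
print(f"transition at alpha = {report.peak_location}, "
      f"boundaries ({report.boundary_low}, {report.boundary_high})")
```

prints

```
plateaus: 4.50 -> 7.63 bits
transition at alpha = 1.3, boundaries (0.6, 1.55)
```

The entropy sits on a low plateau (~4.5 bits) while attachment is weakly
preferential — degrees stay concentrated, curvature spread is narrow — and
on a high plateau (~7.6–8 bits) once super-linear attachment condenses the
graph onto hubs.  The derivative peak at α ≈ 1.3 marks the finite-size
onset of that condensation (the critical value α = 1 is approached from
above as N grows), and the γ-rule brackets the transition region.

The same pipeline from the shell:

```sh
ricciphase sweep --model rgn --sweep-param alpha \
    --values 0.5,0.75,1.0,1.25,1.5,1.75,2.0 \
    --fixed '{"N": 1000}' -R 20 --seed 7 --out trace.csv
ricciphase detect --trace trace.csv --out report.json
```

For a time axis instead of a sweep: generate the planted-community SBM
schedule (`rp.sbm_sequence()`), compute `rp.entropy_over_sequence(seq)`,
and pass the trace to `rp.detect_change_points` — the two community merges
appear as jumps of ≈ 0.48 and ≈ 0.13 bits at t = 11 and t = 21.

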