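# myxolife

Simulation and statistics for the evolution of cooperative life-history
traits in *Myxococcus xanthus* under repeated population bottlenecks.

*M. xanthus* runs a social life cycle: starving cells aggregate into
fruiting bodies where a minority become stress-resistant spores,
spores germinate with the help of diffusible public goods, and the
population regrows. When laboratory populations are propagated through
this cycle with either a stringent (1%) or a relaxed (15%) bottleneck
between cycles, different cooperative traits are enriched — and
sporulation and germination trade off against each other. This package
provides, for people studying that kind of question:

* **`myxolife.simulator`** — a forward simulator of the synthetic life
  cycle. Each of *N* cells carries a sporulation ability *s* and a
  germination ability *g* in [0, 1]. Per cycle:
  1. *Sporulation* (social): cells with *s* ≥ 0.5 are cooperators, the
     rest exploiters. Cells are randomly paired; C–C cooperators
     sporulate with probability γ·*s* (γ = cost-of-cooperation
     discount) with payoff K = γ·½·Σ*s*; in C–E pairs exploiters
     siphon D/*n* ability from cooperators (D = difference of mean
     abilities, *n* = sharing divisor) and post-transfer abilities
     ≥ 0.5 sporulate (payoffs L, M); E–E pairs never sporulate (N = 0).
  2. *Germination* (communal): every spore germinates with probability
     ε·mean(*g*), where ε is the privatization factor.
  3. *Bottleneck*: a random fraction β survives.
  4. *Growth*: binary fission back to carrying capacity, each daughter
     mutating *g* by Uniform(±0.1) and *s* by −1.15 times that step
     (the sporulation–germination trade-off); out-of-range daughters
     die.

  Readouts are the relative spore productivity and relative
  germination efficiency, log₁₀ ratios of the realized per-phase
  retention rates against the ancestral (first) cycle.
* **`myxolife.assay_stats`** — the empirical toolkit: CFU accounting,
  sporulation/germination efficiencies, development-competition
  metrics D_i = log₁₀[N_i(t3)/N_i(t0)], W_ij = D_ij − D_ji,
  C_ij = D_ij − D_i (with marker-based co-culture deconvolution),
  life-cycle relative fitness with the signed-square-root transform,
  density-dependence regressions, trait correlations, and a
  Shapiro–Wilk/Levene-gated, Benjamini–Hochberg-corrected test
  pipeline.
* **`myxolife.synthetic_assays`** — seeded generators of synthetic
  assay tables (log-normal biological noise, Poisson colony counts)
  with embedded ground truth, so the whole pipeline is testable
  end-to-end without wet-lab data.

## Worked example

```python
from myxolife import SimConfig, run_simulation

cfg = SimConfig(gamma=0.98, epsilon=0.5, beta=0.01,     # stringent regimen
                n_max=10_000, n_cycles=10, readout_cycles=(10,), seed=42)
res = run_simulation(cfg)
m = res.metrics[10]
print(f"relative spore productivity:    {m.rel_spore_productivity:+.3f}")
print(f"relative germination efficiency: {m.rel_germination_efficiency:+.3f}")
print(f"cooperator proportion, cycle 10: {dict(res.pc_series)[10]:.3f}")
```

prints

```
relative spore productivity:    +0.074
relative germination efficiency: -0.169
cooperator proportion, cycle 10: 0.747
```

Under a low cost of cooperation (γ = 0.98) and strong privatization of
germination goods (ε = 0.5), ten cycles of evolution leave the
population sporulating ~1.2× better than its ancestor while
germinating worse (the +/− log-ratio pair) — the trade-off signature
of the stringent-bottleneck regimen — and cooperators dominate (75%).

The same machinery is exposed on the command line:

```bash
myxolife simulate --gamma 0.98 --epsilon 0.5 --beta 0.01 \
    --n-max 10000 --n-cycles 10 --readout 10 --seed 42 --out run1
myxolife sweep --gamma-grid 0.6,0.8,0.98 --epsilon-grid 0.5,0.9 \
    --replicates 3 --seed 7 --out sweep1
myxolife synth --kind competition --seed 4 --out data1
myxolife stats data1/dataset.csv --kind competition --out stats1
```

Every command writes a JSON manifest (config echo, seeds, output
inventory, extinction/warning flags) next to its outputs and is
byte-identical under a fixed seed.

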