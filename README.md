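# gridperturb

Grid cells fire at the vertices of a spatial lattice as an animal moves, and
competing circuit models — recurrent attractor networks with aperiodic,
partially periodic (torus) or fully periodic connectivity, and feedforward
summation of already-tuned inputs — all reproduce that tuning. `gridperturb`
implements a simulation and analysis toolkit for telling these mechanisms
apart with simple *global* perturbations (inhibitory synaptic gain, neural
time constants, temperature) combined with sparse recordings.

The central object is the **distribution of relative phase shifts (DRPS)**.
Two cells' relative phase is the offset of their spatial tuning curves as a
fraction of the shared tuning period, `delta_ij = (d_ij mod lambda)/lambda`,
wrapped to [−1/2, 1/2). When a perturbation stretches the population
pattern's period by a factor `1 + alpha`, a cell pair originally K pattern
periods apart shifts in relative phase by K quanta of size

    Delta = alpha / (1 + alpha),

so the histogram of pre-to-post shifts `|delta_pre| − |delta_post|` over all
pairs is quantal, with `2M` peaks for an M-bump pattern (valid while
`M·Delta < 1/2`). How the DRPS width `sigma_DRPS` evolves with perturbation
strength discriminates the candidate circuits:

| mechanism | spatial tuning period | DRPS |
|---|---|---|
| aperiodic recurrent | changes smoothly | widens steadily and smoothly |
| partially periodic recurrent | changes | no change, then step to maximal width |
| fully periodic recurrent | changes | stays narrow, peaked at zero |
| feedforward | unchanged | stays narrow, peaked at zero |

The package provides: recurrent weight construction for all three
architectures (`net_core`), linear-nonlinear-Poisson network simulation with
sub-Poisson spiking on quasi-random 1D trajectories (`lnp_sim`), a cortical
Hodgkin–Huxley variant with Q10 temperature scaling (`chh_sim`), spatial
tuning and population-pattern measurement (`tuning_measures`), the DRPS with
peak counting, periodicity scoring, stretch-factor inference, bootstrap
phase uncertainty and subsampling analysis (`phase_drps`), a grid-to-place
Hebbian association model probing phase resets in novel environments
(`place_reset`), and an end-to-end perturb–measure–classify protocol with a
CLI (`workbench`, `gridperturb` command).

## Worked example

Classify the architecture of a simulated aperiodic network from inhibitory
gain perturbations at gamma_inh = 1.165, 1.33, 1.66 against baseline:

```python
from gridperturb.workbench import ProtocolConfig, run_protocol

report = run_protocol(ProtocolConfig(architecture="aperiodic", seed=1))
for m in report.measurements:
    print(f"gamma={m['strength']:<6} period change={m['period_change']:.3f} "
          f"sigma_DRPS={m['drps_width']:.3f}")
print(report.classification.label)
```

```
gamma=1.0    period change=0.000 sigma_DRPS=0.000
gamma=1.165  period change=0.196 sigma_DRPS=0.127
gamma=1.33   period change=0.309 sigma_DRPS=0.194
gamma=1.66   period change=0.786 sigma_DRPS=0.206
aperiodic recurrent
```

The spatial tuning period grows with perturbation strength (ruling out a
feedforward origin) and the DRPS width rises steadily and smoothly — the
aperiodic-recurrent signature. Running the same protocol on a fully
periodic network keeps the DRPS pinned at zero at every strength (97–99% of
pairwise shifts within 0.025 of zero; `fully periodic recurrent`), and on a
partially periodic network the DRPS stays at baseline until a whole
activity bump is inserted, then jumps to its maximal width
(`partially periodic recurrent`).

The same analyses are available from the shell:

```sh
gridperturb simulate --topology aperiodic --gamma-inh 1.33 --seed 7 --out run_pert/
gridperturb drps --pre run_base/ --post run_pert/
gridperturb protocol --architecture fully_periodic --out report/
```

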