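# pggpunish

Agent-based simulator for the **spatial public goods game with costly
punishment**, the model behind the evolutionary emergence of "moral" and
"double-moral" behavior. It is aimed at researchers in evolutionary game
theory and quantitative social/biological modelling who want a fast,
reproducible implementation of the four-strategy lattice model, its
observables and its well-mixed baseline.

## The model

Players occupy an L×L square lattice with periodic boundaries and play the
public goods game in overlapping groups of size *G* = 5 (each player plus
its four nearest neighbors; every player belongs to five such groups).
Four strategies compete:

| strategy | contributes | punishes defectors |
|---|---|---|
| cooperator **C** | yes | no |
| defector **D** | no | no |
| moralist **M** | yes | yes |
| immoralist **I** | no | yes |

In a group, contributions (1 per cooperative player) are multiplied by the
synergy factor *r* and split equally among all *G* members. With
*n<sub>C</sub>, n<sub>D</sub>, n<sub>M</sub>, n<sub>I</sub>* the strategy
counts among a focal player's *G* − 1 partners and *c* the number of
contributors in the group,

- P<sub>C</sub> = r·c/G − 1
- P<sub>D</sub> = r·c/G − β·(n<sub>M</sub>+n<sub>I</sub>)/(G−1)
- P<sub>M</sub> = P<sub>C</sub> − γ·(n<sub>D</sub>+n<sub>I</sub>)/(G−1)
- P<sub>I</sub> = P<sub>D</sub> − γ·(n<sub>D</sub>+n<sub>I</sub>)/(G−1)

where β is the punishment fine and γ the punishment cost. Strategies
spread by noisy imitation: a random player x collects its total payoff
Π<sub>x</sub> over all five of its groups, a random neighbor y does the
same, and y adopts x's strategy with the Fermi probability
w = 1/(1 + exp((Π<sub>y</sub> − Π<sub>x</sub>)/K)), with noise K = 0.5 by
default. One Monte Carlo iteration is L² such elementary updates; optional
mutation replaces the updated strategy with a random one at rate μ.

In the well-mixed (mean-field) version of this game, defectors always win:
cooperators out-earn moralists (the "second-order free-rider problem") and
defectors out-earn cooperators. The point of the spatial model is that
local interactions invert this — punishers segregate into clusters, beat
defectors at cluster interfaces when β/γ is large enough, and can
eliminate non-punishing cooperators entirely, or survive in two-strategy
coexistence phases (D+M, M+I, C+D) depending on (r, β, γ).

## Worked example

The moralist–immoralist coexistence scenario (r = 3.5, β = 0.12,
γ = 0.005):

```python
from pggpunish import ModelParams, Strategy, classify_phase, simulate

params = ModelParams(r=3.5, beta=0.12, gamma=0.005)   # K=0.5, G=5 defaults
state, traj = simulate(params, L=100, t_max=14400, seed=1, record_every=10)

print("cooperators extinct at iteration", traj.extinctions[Strategy.C])
print("defectors   extinct at iteration", traj.extinctions[Strategy.D])
print("final phase:", classify_phase(traj, window=1000).label)
print("final fractions (C, D, M, I):", traj.fractions[-1].round(4))
```

prints

```
cooperators extinct at iteration 61
defectors   extinct at iteration 4489
final phase: M+I
final fractions (C, D, M, I): [0.     0.     0.4781 0.5219]
```

Cooperators are eliminated almost immediately (the synergy factor is too
low for them to resist defectors), after which the two punishing
strategies jointly defeat the defectors: immoralists survive only by
exploiting the moralists' punishment efforts, while moralists profit from
the extra punishment the immoralists contribute — the model's "unholy
collaboration". The same run is available from the shell:

```bash
pggpunish run --r 3.5 --beta 0.12 --gamma 0.005 --L 100 --t-max 14400 \
    --seed 1 --snapshot-at 0 --snapshot-at 250 --out out/
```

which writes `trajectory.csv` (columns `t,f_C,f_D,f_M,f_I`), plain-text
lattice snapshots and a JSON manifest sufficient to reproduce the run.
`pggpunish scan` runs (β, γ) phase grids, `pggpunish rewire` sweeps
degree-preserving lattice rewiring, and `pggpunish mixed` integrates the
well-mixed replicator baseline.

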