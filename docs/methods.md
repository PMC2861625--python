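# Methods

## Model

Players sit on a fully occupied L×L square lattice with periodic boundary
conditions. Each player carries one of four strategies: cooperator (C),
defector (D), moralist (M), immoralist (I). C and M are *cooperative*
(contribute 1 to each group's pool); D and I are *defecting*; M and I are
*punishing*.

**Groups.** The default interaction structure assigns each player to five
overlapping groups of size G = 5: the group it centers (itself plus its
four von Neumann neighbors) and the four groups centered on those
neighbors. Variants with Moore (G = 9) and extended neighborhoods
(G = 13: Manhattan-distance-2 diamond; G = 21: 5×5 block minus corners;
G = 25: full 5×5 block) are available; in every case a player belongs to
1 + degree groups and `ModelParams.G` must equal degree + 1.

**Payoffs.** In one group, with c the number of contributors including the
focal player where applicable, the focal player earns r·c/G from the pool,
pays 1 if it contributed, loses β/(G−1) per punishing partner if it
defects, and pays γ/(G−1) per defecting partner if it punishes. A player's
total payoff Π is the sum over all of its groups, always recomputed from
the live configuration. The 1/(G−1) scaling keeps fines and costs
comparable across group sizes. These expressions imply the model's
defining order relations, which the test suite checks exhaustively for
G = 5: P_I ≤ P_D and P_M ≤ P_C with equality exactly when no partner
defects, and P_C − P_D = r/G − 1 + β(n_M+n_I)/(G−1), positive for a
sufficiently large fine.

**Dynamics.** Random sequential updating: an elementary update draws a
focal player x uniformly, draws one of its neighbors y uniformly, and y
adopts x's strategy with the Fermi probability
w = 1/(1 + exp((Π_y − Π_x)/K)). With probability μ the updated player's
strategy is then replaced by one of the four strategies uniformly at
random (including its current one). One iteration (Monte Carlo step) is
n_players elementary updates. Only the drawn neighbor can change per
update, so each strategy count moves by at most 1 per elementary update.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| r | synergy factor on pooled contributions | dimensionless | required (> 0) |
| β | punishment fine per punishing partner, scaled by 1/(G−1) | payoff | 0 |
| γ | punishment cost per defecting partner, scaled by 1/(G−1) | payoff | 0 |
| K | imitation noise of the Fermi rule | payoff | 0.5 |
| μ | mutation probability per elementary update | — | 0 |
| G | group size (focal + partners) | players | 5 |
| L | lattice side | sites | 100 in the scenario drivers |

K = 0.5 places the dynamics in the selection-dominated regime (K → 0 is
deterministic imitation of better payoffs, K → ∞ a coin flip); it is the
conventional noise level for Fermi-rule lattice studies of this game and
is exposed as an ordinary parameter. Initial conditions put each strategy
on 25% of the sites, either i.i.d. uniform (default) or as an exact
balanced random permutation (`balanced=True`).

## Engines, randomness, reproducibility

The production engine is a numba-compiled kernel (~10⁷ elementary
updates/s on one core); a pure-python reference engine implements the
identical update law through the readable payoff code and is used for
cross-checks on small lattices (the suite compares both payoff paths
against a brute-force group-enumeration oracle, and the two engines
statistically against each other). Initialization draws from
`numpy.random.default_rng(seed)`; the kernel's update stream is numba's
Mersenne twister seeded deterministically from `RunConfig.seed` via
`SeedSequence`; the python engine takes all draws from the single state
generator. Given its seeds every run is bit-reproducible.

Both engines short-circuit elementary updates in which focal and neighbor
already share a strategy: such an adoption is a no-op, so payoffs and the
adoption uniform are skipped (mutation draws still occur when μ > 0).
This changes the raw random stream relative to a naive implementation but
not the distribution of trajectories, and speeds up late, coarsened
configurations several-fold.

Extinction times are recorded at iteration granularity: the reported value
is the iteration during which a strategy's count first reached zero. With
μ = 0 extinctions are absorbing, so this is exact.

## Observables

- **Fractions/trajectories**: per-iteration strategy counts, sampled every
  `record_every` iterations (plus the initial and final configuration).
- **Phase classification**: the set of strategies with strictly positive
  count throughout a trailing window of the run, labelled in canonical
  C+D+M+I order. A strict count > 0 criterion (not a fraction cutoff) is
  used because extinctions are absorbing at μ = 0. A surviving set {C, M}
  with μ = 0 is flagged as *neutral voter coexistence*: with no defecting
  players all payoffs are equal, w ≡ 1/2, and the C–M competition is an
  unbiased voter model whose fixation probability equals the initial
  fraction (verified on a 4×4 torus against the martingale property);
  runs are not stopped in this regime, since coarsening continues.
- **Clusters**: connected same-strategy components under 4-neighbor
  lattice adjacency (regardless of the group neighborhood, matching how
  domains are read off snapshots); on non-lattice graphs the interaction
  adjacency is used.
- **Interface density**: fraction of edges joining unlike strategies — the
  natural coarsening order parameter, since coexistence is governed by
  payoff balance at cluster interfaces.

## Well-mixed baseline

Because each payoff is linear in partner counts, expected payoffs over a
group of G−1 partners drawn i.i.d. from frequencies x are closed-form
(`expected_payoffs`), and E[P_C] ≥ E[P_M], E[P_D] ≥ E[P_I] on the whole
simplex — in the mean field, punishment is always second-order-dominated,
and the replicator dynamics ẋ_s = x_s(E[P_s] − ⟨P⟩) drives generic
interior states to full defection. Integration uses `scipy`'s LSODA with
rtol 1e−8/atol 1e−10 and per-evaluation renormalization onto the simplex;
the frequency sum is conserved to ≤ 1e−9. A finite-population well-mixed
imitation simulator with freshly drawn random partners per payoff
evaluation (`simulate_wellmixed`) serves as a stochastic cross-check.
When β = γ = 0, D and I have identical payoffs and their ratio is a
replicator invariant, so the all-D endpoint statement applies on the
I = 0 face.

## Experiments

`phase_scan` classifies each (β, γ) cell at fixed r by the modal phase
over replicates; cells with disagreeing replicates are flagged as
candidate phase boundaries rather than resolved. Per-cell seeds derive
from `SeedSequence([base, bits(beta), bits(gamma), replicate])` using the
parameters' IEEE-754 bit patterns, so results are independent of grid
ordering and individual cells can be recomputed in isolation.
`rewiring_sweep` applies degree-preserving pairwise edge swaps (each link
marked independently with probability Q, marked links randomly paired and
endpoint-exchanged with bounded retries on conflicts) — the only local
move that preserves every node's degree exactly — then averages final
fractions over replicates (default 10). Connectivity of rewired graphs is
checked and reported, not enforced. `mutation_comparison` reports the
first iteration at which the moralist fraction exceeds a threshold for
each μ, with censoring at the horizon.

## Problem sizes and scenario milestones

The published phase diagrams require lattices up to Θ(10⁶) sites and up to
10⁷ iterations near phase boundaries; this package's bundled tests and
drivers instead target the desk-scale worked scenarios on L = 100 (the
size the model's snapshot figures use): the moralist–immoralist
coexistence scenario (r = 3.5, β = 0.12, γ = 0.005; cooperators extinct
within 250 iterations, defectors within 12000, M+I surviving), the
cooperator–defector coexistence scenario (r = 4.4, β = 0.1, γ = 0.3;
C and D both persist through 10⁴ iterations), and the second-order
free-rider elimination scenario (r = 4.4, β = 0.1, γ = 0.1; immoralists
die early, cooperators vanish, moralists reach a majority with a minority
of defectors; checked at 5×10⁴ iterations). Full-resolution phase
diagrams remain an explicitly long-running optional job via `ScanSpec`.

The generator of initial conditions and the scenario parameter sets above
*are* the study conditions; passing tests demonstrate the model's
qualitative phases and worked milestones at these sizes, not the
quantitative location of phase boundaries at the thermodynamic limit.

## Known limitations

- Transition-order classification (continuous vs discontinuous phase
  boundaries) is out of scope; boundary cells are only flagged.
- Antisocial punishment, success-driven migration, coevolving punishment
  levels and heterogeneous-degree networks are not modelled.
- The Q → 1 rewiring approximates a random 4-regular graph by one pass of
  random pairwise re-matching of marked links; it is not an exactly
  uniform sample from 4-regular graphs.
- Extinction times on small lattices include a finite-size accidental
  component; the scenario milestones are only meaningful at L ≈ 100 or
  larger (the suite checks that accidental extinctions recede with L).
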