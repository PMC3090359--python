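# Methods

## The model

`sproutsim` simulates sprouting angiogenesis as a stochastic rule-based
(agent-based) system on a 2-D lattice — the in-silico analogue of a
Matrigel tube-formation well. Four entity types live on an `m x n` grid
of sites, each represented by a Boolean occupancy layer:

* **EC** — endothelial cells, whose cumulative occupancy pattern *is*
  the vessel network;
* **VEGF** — the pro-angiogenic growth factor;
* **sVEGFR-1** — the soluble decoy receptor, anti-angiogenic;
* **Ado** — adenosine, a pro-angiogenic modulator.

Row 0 is the bottom of the grid and carries the *initial vessel*: a
contiguous, centered run of `ini_ec` ECs. Molecules are scattered
uniformly at random (without replacement, independently per layer) at
initialization, the discrete analogue of an isotropic starting
distribution.

Each *cycle* has two phases:

1. **Rule application.** Every EC present at cycle start is visited in
   a uniformly shuffled order. The EC is *eligible* to divide under

   * **R1**: at least one site of its neighbourhood carries VEGF **and**
     no site of its neighbourhood carries sVEGFR-1 (the decoy receptor
     vetoes the division), or
   * **R2**: R1 **or** at least one neighbourhood site carries Ado —
     adenosine licenses division regardless of sVEGFR-1, encoding the
     hypothesis that Ado both enhances VEGF activity and antagonizes
     the decoy receptor.

   An eligible EC actually divides with probability `p_execute` (random
   motility / response heterogeneity); if it does, one EC-free
   neighbour site chosen uniformly at random gains a daughter EC. The
   parent stays in place — "divides and moves" is read as sprout
   extension — and molecules are not consumed. Daughters act from the
   next cycle, which caps front advancement at one row per cycle and is
   consistent with the design point that a full-height grid traversal
   takes of the order of the grid height in cycles under ideal growth.

2. **Diffusion.** Every molecule performs one step of a blocked random
   walk: it picks one of its 4 nearest (von Neumann) neighbour sites
   uniformly at random and moves there unless the target is off-grid or
   already holds an entity of the same type at that moment (entities are
   processed in a uniformly shuffled order; blocked moves are aborted).
   Counts are conserved per layer for the whole run.

The grid has hard walls (a well has walls, no wrap-around). Eligibility
consults the neighbourhood only, not the EC's own site.

### Outputs

* **Vessel network area** = final EC count / total sites
  (`numECs / gridArea`), in [0, 1].
* **Network reach** = maximum EC row index: the vertical distance in
  site units from the initial vessel to the farthest network tip, a
  proxy for maximum branch length. A Euclidean variant
  (`network_reach_euclidean`, distance to the nearest bottom-row vessel
  cell) is provided but not the default, since the initial vessel spans
  the whole bottom row.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `rows x cols` | 300 x 300 | lattice (gridArea = 9.0e4 sites) |
| `ini_ec` | 300 | initial vessel length (full bottom row) |
| `n_vegf`, `n_svegfr1` | 40000, 8000 (control) | molecule counts; the control keeps sVEGFR-1/VEGF = 1/5, the baseline ratio observed in vitro |
| `n_ado` | 0 | added adenosine |
| `num_cycles` | 300 | cycles per simulation |
| `p_execute` | 0.05 | probability an eligible EC executes the rule in a cycle |
| `ruleset` | R1 | R1 = VEGF/sVEGFR-1 control model, R2 = Ado-mediated model |
| `num_sim` | 50 (desk scale) | replicates per condition; batch replicate *i* uses seed `base_seed + i`, condition *j* of a preset uses the block starting at `base_seed + j*num_sim` |

Neighbourhoods are config-overridable (`ec_neighbourhood`,
`diffusion_neighbourhood`). Moore (8 sites) is the default for EC rules
and daughter placement — it maximizes branching flexibility and matches
the diagonal branches seen in snapshots; von Neumann (4 sites) is the
default for diffusion ("nearest neighbour" moves).

Preset sweep grids (overridable by building conditions directly):
added sVEGFR-1 `{0, 1000, 2000, 5000, 12000, 32000, 72000}` on top of
the control 8000; added Ado `{0, 1000, 2000, 4000, 8000, 12000,
16000}`; the combined panel holds added sVEGFR-1 = 2 x Ado with Ado in
`{2500, 5000, 10000, 20000}`; verification sweeps run 100 cycles with
VEGF in `{5000, 10000, 20000, 40000, 80000}` at sVEGFR-1 = 10000 and
sVEGFR-1 in `{1000, 5000, 10000, 20000, 50000}` at VEGF = 10000
(endpoints anchored by the published close-up condition VEGF = 10000,
sVEGFR-1 = 50000). These grids bracket the documented landmarks —
departures from control beyond ~1000 added sVEGFR-1, reduction
saturation from ~40000 total sVEGFR-1, Ado growth saturation beyond
8000.

## Numerical and implementation choices

* **Two engines, one stream.** The model is implemented twice: readable
  per-site reference operations (`sproutsim.rules`) and numba-compiled
  kernels (`sproutsim.engine`). Both consume a single
  `numpy.random.Generator` under a fixed draw protocol — every visited
  EC consumes exactly two uniforms whether or not it divides; diffusion
  snapshots each layer's entities in row-major order each cycle, draws
  one permutation and one uniform per entity — so the two engines
  produce bit-identical states. The suite asserts this equality and,
  independently, chi-squared agreement of output distributions over
  10,000 disjoint seeds.
* **Cycle bookkeeping.** The cycle being executed is numbered
  `grid.cycle + 1`: actors are ECs with `ec_birth_cycle <= grid.cycle`,
  daughters are stamped `grid.cycle + 1`, and the counter increments
  after diffusion. This makes "initial ECs act in the first cycle" and
  "daughters skip their birth cycle" simultaneously true.
* **Ties and degenerate cases.** Daughter-site choice maps a uniform
  draw to an index by `min(int(u * n_free), n_free - 1)`; a centered
  vessel of odd remainder shifts toward the lower column index;
  zero-variance batches get a zero-width confidence interval and
  self-comparisons report p = 1; an EC-free run reports reach 0 from
  `run_simulation` while the strict `network_reach` metric rejects an
  empty layer.
* **Statistics.** Welch (unequal-variance) t-tests for condition
  contrasts; t-based 95% CIs around batch means; Spearman rank
  correlation on pooled per-replicate (area, reach) pairs — pooling
  per replicate rather than per condition is deliberate, since
  condition means would correlate near 1 and mask replicate-level
  noise. No multiple-testing correction is applied; raw p-values are
  reported.

## What the experiments emulate — and what they do not

Batches of seeded replicates emulate repeated independent Matrigel
assays under one molecular condition. The model deliberately omits:
continuous concentrations and PDE diffusion, membrane-bound VEGFR-1
signalling, EC death/detachment/anastomosis, molecule production,
degradation and consumption, endogenous adenosine, chemotactic bias of
daughter placement, and any third spatial dimension. Passing tests
therefore show that the *rule system* reproduces the qualitative
response structure (VEGF up / sVEGFR-1 down / Ado rescue, area-reach
coupling); they do not validate quantitative correspondence to any
in-vitro measurement.

## Desk-scale reproduction and known limitations

The canonical experiments used 1000 replicates per condition; this
package's acceptance runs use 50 (and 4 for the cycle-count sweep),
which is sufficient for the summary statistics involved, with seeds
fixed by the caller.

Two documented behaviours of this implementation are worth flagging:

* **Added-sVEGFR-1 span.** Under the neighbourhood-veto reading of R1,
  eligibility at 80000 total sVEGFR-1 is ~(1 - 0.889)^8 ≈ 2e-8: growth
  freezes and the sweep minimum approaches the initial-vessel floor
  (area ≈ 0.0033). The min-to-max span of the added-sVEGFR-1 sweep is
  therefore necessarily close to 100% of the control mean (measured
  ≈ 90%), not the ~10% sometimes quoted for such scenarios — a small
  span is only possible if heavy sVEGFR-1 leaves growth largely intact,
  which the literal veto rule forbids. The normalization of
  `min_max_change_percent` is exposed (`control`, `min`, `grid`)
  because the reading of "percent change" is genuinely open.
* **No pre-saturation steady state.** Molecule counts are conserved and
  eligibility probabilities are stationary, so the growth front
  advances indefinitely until the grid fills; mean area keeps rising
  roughly linearly between 300 and 1500 cycles (measured ≈ 0.058 →
  0.28 in the Ado-treatment setting). A steady state of the mean area
  at a few hundred cycles would require a depletion or inhibition
  mechanism the rule system does not contain. The corresponding
  stability check in the acceptance suite documents this honestly and
  fails.
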