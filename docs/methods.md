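# Methods

## The problem

De novo molecular design with reinforcement learning asks a generative
SMILES policy to propose compounds that score well under an expensive
"oracle" — a pharmacophore-overlay similarity score or a docking energy in
a real campaign. The oracle dominates the cost of such a campaign, so the
figure of merit is not the number of good molecules generated but the
number of unique hits *per oracle call*. molseal implements a
sample-efficient variant of this loop: an inner active-learning (AL) cycle
trains a cheap uncertainty-aware surrogate on the oracle labels collected
so far and uses an acquisition function to decide which freshly generated
molecules are worth an oracle call; all other molecules are scored by the
surrogate (or ignored by the policy update, depending on the weighting
scheme).

## Generative policy and RL update

The policy is an autoregressive SMILES language model: a multi-layer GRU
over a tokenized SMILES vocabulary (multi-character tokens — `Cl`, `Br`,
bracket atoms, `%NN` ring closures — are atomic). It is implemented
directly in numpy (forward, backward-through-time, Adam) and is deliberately
compact so that pretraining on the fixture corpus takes minutes on one CPU.
Defaults are 3 layers, embedding 128, hidden 256; the test and acceptance
experiments use a single layer with embedding 64 and hidden 160, which
reaches ≈90% valid SMILES after 18 epochs on the 20 000-molecule fixture
corpus. Sampling is ancestral at temperature 1; sequences that reach the
length cap without emitting the end token are marked invalid.

Pretraining produces the *prior*; the *agent* starts as an exact copy and
is the only network RL ever updates. The RL target is the augmented
log-likelihood

    log P_aug(x) = log P_prior(x) + α · MPO(x),        α = 128

and the update minimizes the weighted difference between augmented and
agent likelihood (wDAP),

    L = (1/|X|) Σ_x w(x) · [log P_aug(x) − log P_agent(x)]²,

with Adam at learning rate 1e-4. The squared difference moves the *agent*
likelihood toward the augmented target; the configuration exposes an
alternative reading (difference against the prior) behind a flag, but that
form has no gradient with respect to the agent and is not exercised.
Per-molecule weights w(x) are 1 for oracle-labelled compounds always, and
for surrogate-labelled compounds follow the configured scheme: 1
(full belief), a constant such as 0.75/0.25, an uncertainty gate
(1 if surrogate sd ≤ 0.025 or 0.05, else 0), or 0 (zero-surrogate — the
update sees oracle labels only, with the AL loop acting purely as a
curator).

Two REINVENT-style memory mechanisms shape the reward. The diversity
filter records scored compounds per Murcko scaffold (minimum score 0.2,
bucket size 100) and zeroes the reward of any scaffold past its bucket.
The replay buffer keeps the 100 top-scoring unique SMILES and re-injects a
random sample of 10 into every update batch. Design choices here: replay
entries re-enter with weight 1 (they are curated oracle-scored top
compounds) and are exempt from the diversity filter; the buffer is sampled
*before* the current epoch's compounds are inserted, so replay is strictly
historical; the diversity filter acts on the final aggregated MPO score,
before the update and before replay insertion. Invalid SMILES receive MPO
0 with weight 1, are excluded from oracle candidacy, and never consume
oracle budget.

## MPO scoring

Each scoring component produces a raw value mapped into [0, 1] by a
transform. The aggregate is a product of *penalty* components (applied
multiplicatively, unweighted, untransformed) times the weighted geometric
mean of the *non-penalty* components. The default panel: QED (identity),
molecular weight (double sigmoid, low 200 / high 550 / divisor 550 /
steepness 20), hydrogen-bond donors (reverse sigmoid, low 2 / high 6 /
k 0.5), structural alerts (penalty; a shipped, replaceable SMARTS list of
reactive groups and 8+-membered rings), and the oracle score (sigmoid
0.3/0.65/0.3 for the similarity oracle; reverse sigmoid −13.5/−6/0.2 for
docking).

The sigmoid is base-10: t(x) = 1/(1 + 10^(−k′(x−c))) with c = (low+high)/2
and k′ = 10k/(high−low); the reverse form negates the exponent. This form
reproduces both published anchor points exactly (0.6 → 0.92 and
−11.4 → 0.73 at two decimals) and those anchors are golden tests. The
double sigmoid is the product of a rising sigmoid centered at `low` and a
falling one at `high`, both with base-10 slope steepness/divisor, giving
≈1 across the design range and 0.5 at its edges.

When the oracle component is a surrogate prediction it is a Gaussian random
variable (mean = ensemble mean, sd = ensemble spread) on the raw score
scale. The induced MPO distribution is summarized by Monte-Carlo: draw S
joint realizations (components independent given the molecule), transform
and aggregate each, report sample mean and sd. S = 1000 by default; the
sample-mean standard error scales as 1/√S and S = 1000 agrees with dense
quadrature to within Monte-Carlo error (both tested). Fully deterministic
inputs short-circuit to the exact aggregate with sd = 0.

## Surrogate and training pool

The surrogate is a random forest (200 trees, max depth 30, min split 2)
on z-scaled physicochemical descriptors, regressing the *raw* oracle value;
transforms are applied downstream, so transform parameters can change
without invalidating the pool. Uncertainty is the per-tree prediction sd,
uncalibrated; the uncertainty-gate thresholds are interpreted on this raw
sd scale. The scaler (invariant columns dropped) is refit at every
surrogate refit on the current pool, which is the only distributional
anchor while the generator drifts. The training pool keeps the m = 1000
most recent labelled compounds (unique by canonical SMILES, re-acquisition
refreshes label and recency); an adaptive-subsampling mode instead selects
the m compounds the model is most uncertain about in train/predict/acquire
cycles (cycle 1 trains on a random seed split, later cycles on the
selection so far).

Descriptor sets: `full` is the complete RDKit physchem suite (~210 values,
non-finite entries zeroed); `fast` is an 11-descriptor subset used by the
desk-scale experiments, where it keeps per-epoch featurization cost
negligible while containing every descriptor the synthetic oracles read.

## Acquisition

Per epoch the agent samples N_batch compounds; each of N_loops inner loops
ranks the remaining valid candidates and sends N_acquired/N_loops of them
to the oracle, then refits the surrogate (including after the last loop, so
the next epoch starts fresh). The very first loop, with an empty pool, is
always random. Rankings: `greedy` (predicted mean), `ucb`
(mean + β·sd, β = 1, optimism oriented along the oracle's direction —
docking minimizes), and `mpo_greedy`/`mpo_ucb`, the same formulas on the
Monte-Carlo mean and sd of the predicted MPO distribution (always
maximized, since desirability is directionless in [0, 1]). Ties break by
generation order. Defaults are N_batch 256 / N_acquired 128 / 1 loop; the
optimized configuration is 512/64/2 with zero-surrogate weights and UCB
(AL/RL ratio 0.125).

Virtual-screening mode (`run_vs_al`) applies the same pool, surrogate and
acquisition machinery to a fixed library with no generator and no RL;
exhausting the budget over the whole library provably recovers the
brute-force hit set.

## Synthetic oracles and fixture data

Real overlay and docking oracles are replaced by deterministic functions of
a fixed six-descriptor profile (MW, logP, ring count, HBD, HBA, TPSA),
z-scaled by fixed reference constants chosen to match the spread of the
fixture chemistry:

* **PseudoROCS** = exp(−d²/2b²), d the Euclidean distance to a drug-like
  target profile (MW 360, logP 3, 3 rings, HBD 1, HBA 4, TPSA 70). Hit
  threshold 0.6, maximize. Bandwidth b = 1.0 puts ≈1% of the fixture corpus
  above threshold — rare enough that oracle-call efficiency is a meaningful
  axis, common enough to be learnable.
* **PseudoDock**: a second kernel affinely mapped onto [−13.5, −4.0]
  kcal/mol; hit threshold −11.4, minimize. Its target (MW 480, logP 4.5,
  4 rings, HBD 4, HBA 7, TPSA 110; b = 3.0, ≈0.2% base hit rate)
  deliberately rewards larger, greasier, donor-rich compounds, emulating
  the well-documented exploitability of docking scores — the very reason
  generative campaigns pair docking with drug-likeness components and an
  HBD cap. This tension is what makes MPO-distribution acquisition behave
  differently from raw-affinity acquisition.
* A Gaussian-noise wrapper adds N(0, sd²) to any base oracle with a
  seeded stream, for noise-robustness experiments.

Both oracles are smooth functions of the same descriptor space the
surrogate sees, so active-learning acceleration is demonstrable at desk
scale by construction; a harder PseudoROCS variant mixes in a
molecular-complexity term (BertzCT) hidden from the default featurization.

The fixture corpus is assembled from a fragment grammar: 1–3 ring systems
(aromatic and saturated, mono- and bicyclic) joined by small linkers
(bond, CH₂, O, NH, amide, sulfonyl, …) with 0–3 substituents inserted at
carbon positions. Assemblies that violate valence are redrawn, so the
emitted corpus is 100% parseable, ≈85% unique at 20 000 molecules, and
spans MW ≈ 80–500. What it does *not* emulate: stereochemistry, charged
species, macrocycles, tautomers, and the long-tail token diversity of
ChEMBL — so a high validity fraction here says the policy learned this
grammar, not that it would reach the same validity on ChEMBL-scale
chemistry.

## Orchestration, seeds, determinism

A master seed spawns independent child streams (sampling, acquisition,
Monte-Carlo, replay, surrogate) via `numpy.random.SeedSequence`, so
machinery that only exists in some modes (e.g. the surrogate in RL-AL)
never perturbs the streams shared with the pure-RL path. This gives the
exact degeneracy: with N_acquired = N_batch and one loop, the RL-AL
trajectory is bit-identical to pure RL under the same seeds. Runs are
reproducible log-for-log given a config; the JSONL log carries the full
config, one record per generated compound, and one per epoch.

The oracle-budget stop condition counts labels, not epochs, so
configurations with different N_acquired are comparable at a fixed call
budget; a `stop_at_hit_scaffolds` condition supports calls-to-N-hits
comparisons without spending the rest of a budget.

## Scale of the shipped experiments

The published campaigns run to 30 000 oracle calls on ChEMBL-scale priors.
The shipped experiments use the package's own desk-scale conditions: the
20 000-molecule fixture corpus, the compact single-layer prior above, a
2048-call budget with a 20-unique-hit-scaffold target for the
efficiency comparison (5 paired seeds), and 14-epoch runs (3 paired seeds,
S = 250) for the docking-oracle acquisition comparison. Under these
conditions the optimized RL-AL configuration reaches 20 hit scaffolds in a
median of a few hundred oracle calls versus ≈2000 for pure RL; the
comparisons assert direction, not magnitude.

## Known limitations

* The policy network is a stand-in at toy scale, not a replica of the
  production REINVENT architecture or vocabulary.
* Surrogate uncertainty is raw ensemble spread; no calibration is applied,
  so gate thresholds are heuristic.
* The synthetic oracles are smooth and descriptor-determined; they cannot
  exhibit the activity cliffs, conformer sensitivity, or scoring-function
  noise of real overlay/docking oracles, and absolute hit counts are not
  comparable to published values.
* Wall-clock benchmarking, external oracle adapters (command-template
  interfaces are declared but untested), and arithmetic-mean MPO
  aggregation are out of scope.
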