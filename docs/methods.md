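# Methods

`paretomol` implements a multi-objective de novo molecular design
pipeline for the adenosine-receptor / hERG selectivity problem: generate
drug-like molecules with high predicted affinity for chosen targets
(e.g. adenosine receptors A1 and A2A) and low predicted affinity for an
anti-target (the hERG potassium channel, whose blockade is
cardiotoxic). This note records the models, the parameters that matter,
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## Data model and preprocessing

Input molecules are SMILES strings. Preprocessing keeps the largest
organic fragment of each record (stripping counter-ions), neutralizes
charges, canonicalizes with RDKit, and rejects molecules that are
unparseable, contain elements outside the organic subset
{H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}, or fall outside 5–100
heavy atoms (configurable; the bounds cover drug-like space).
Deduplication is by canonical SMILES, keeping the first occurrence.

Activity tables carry one row per measurement with a pChEMBL-style pX
value (−log10 potency). Labeling rules:

* rows with no measured activity, or flagged "Not Active", get
  pX = 3.99 — just below the pX = 4 inactive floor — and sample weight
  0.1;
* replicate measurements of one compound–target pair are aggregated by
  the mean of the defined pX values;
* records at or above the bioactivity threshold pX = 6.5 are positives
  with weight 1.0; everything below is down-weighted to 0.1.

The weighting keeps the much larger negative/unlabeled set from
dominating the regression while still teaching the model its range.

## QSAR reward model

Each molecule is featurized into 2067 dimensions: a 2048-bit ECFP6
(Morgan radius-3) fingerprint plus 19 physicochemical descriptors
(molecular weight, logP, H-bond acceptors/donors, rotatable bonds,
amide bonds, bridgehead atoms, heteroatoms, spiro atoms, heavy atoms,
sp3 carbon fraction, aliphatic/saturated/total/aromatic rings,
heterocycles, valence electrons, TPSA, Wildman–Crippen molar
refractivity, in that fixed order). Features are min-max scaled to
[0, 1]; a feature constant in the fit set maps to 0 and out-of-range
values are clipped — min-max is undefined there and the forest is
insensitive to the convention.

The regression model is a random forest (default 1000 trees) fitted
with the 1.0/0.1 sample weights. Splitting uses the squared-error
(variance-reduction) criterion, the standard choice for regression
forests; the Gini index sometimes quoted for such models is a
classification criterion and does not apply to a regression target.
The out-of-bag R² is logged and stored with the model. Prediction
returns NaN for unparseable SMILES; downstream reward code treats NaN
as "invalid molecule".

Parameter recovery is evaluated as held-out R² on *measured* records
only: the pX = 3.99 imputed labels are training devices, not
measurements, and scoring against them would mix label convention into
the recovery estimate. On the synthetic structure–activity table
(n = 2000, noise 0.2 pX units) the protocol recovers the planted rule
with held-out R² ≈ 0.95. Test and acceptance runs use 200-tree forests
with `max_features = 0.2`; tree count beyond a few hundred changes R²
by well under 0.01 on these problem sizes.

## SMILES generator

The generator is an autoregressive language model over an atom-level
token vocabulary (bracket atoms, `%nn` ring closures and two-letter
elements are single tokens; GO and EOS control tokens occupy indices 0
and 1). Architecture:

    embedding (vocab → 128)
    → [LSTM block: 3 layers, width 512] × 3
      (between blocks: ReLU, then a learned projection back to 128)
    → causal multi-head self-attention (4 heads × d_k = 128)
    → linear → vocabulary logits

Nine recurrent layers in total, organized as three 3-layer blocks with
an inter-block rectifier and projection; attention is applied once, on
the final block's output. Per head the attention is standard scaled
dot-product, softmax(QW_q (KW_k)ᵀ/√d_k)·VW_v, heads concatenated and
projected by W_o, with no residual connection. The attention mask is
causal so that teacher-forced training and step-by-step sampling see
identical distributions; without the mask the training-time attention
would peek at future tokens the sampler cannot have.

Training minimizes teacher-forced negative log-likelihood (GO
prepended, EOS appended, padding masked out of the loss, loss averaged
over the batch) with Adam at learning rate 1e-3, batch 512 at full
scale. Gradients are clipped to global L2 norm 5 — the usual safeguard
for recurrent nets, which otherwise show occasional seed-dependent
divergence. Sequences are bucketed by length into batches so padding
work is minimal; batch order is shuffled each epoch. Fine-tuning is the
same procedure on a target-ligand corpus. Sampling is autoregressive
from GO with optional temperature (0 = greedy); sequences are cut off
at `max_len` (default 100 tokens).

The network is implemented directly on numpy arrays with hand-written
backpropagation (embedding, LSTM, linear, causal attention, softmax
cross-entropy, Adam), in float32; the test suite gradient-checks every
layer against central differences in float64, and checks the batched
attention against a per-position brute-force oracle and the stepwise
(sampling) path against the batched path.

## Multi-objective rewards

Predicted pX is normalized by a fixed affine map over [4, 9], clipped
to [0, 1], so the bioactivity threshold pX = 6.5 lands exactly at
reward 0.5. (A batch-relative variant is available behind a flag, but
it cannot anchor the threshold at 0.5 and is not the default.) Per
objective: high-affinity targets take the normalized value, low-affinity
anti-targets its complement 1 − x, and invalid molecules score 0 on
every objective. A molecule is *desirable* when it is valid and every
objective reward reaches that objective's threshold (default 0.5);
with one objective this reduces to pX ≥ 6.5, and the conjunction is the
natural multi-objective extension.

**Weighted scheme.** Per cycle, each objective's ratio
r_i = N_below / max(N_above, 1) counts molecules below/above its
threshold; weights w_i = r_i / Σr normalize (uniform if every r_i = 0,
and the denominator guard handles N_above = 0). The final reward is
R* = Σ w_i R_i. Lagging objectives therefore gain weight each cycle.

**Pareto scheme.** Rewards are clipped against thresholds
(x_j = 1 if R_j > t_j else R_j/t_j), the batch is split into
non-dominated fronts (fast non-dominated sort, checked in tests against
an O(N²) peeling oracle), and within a front molecules are ordered by
ascending mean Tanimoto distance (2048-bit Morgan fingerprints) to the
other front members — structural outliers rank higher, a diversity
pressure replacing NSGA-II crowding distance. The exact distance the
scheme should use is a genuinely open design point; mean pairwise
Tanimoto distance within the front is this package's choice, and the
function is injectable. Fronts are laid out worst-first, desirability
is re-imposed as the primary sort key, and the global rank k maps to

    R* = 0.5 + (k − N_undesired) / (2 N_desired)   if desirable
    R* = k / (2 N_undesired)                        otherwise

placing desirable molecules in [0.5, 1) and undesirable ones in
[0, 0.5). When one class is empty the occupied class uses its own block
formula. Ties in distance keep input order (stable sorts throughout)
for determinism.

## Reinforcement learning

Three models share one architecture: the **agent** (trained), the
**crover** (crossover source, refreshed only at syncs) and the
**prior** (pretrained weights, permanently frozen). During sampling,
per sequence and step: a mutation draw below the mutation threshold
(default 0.01) takes the step distribution from the prior; otherwise a
crossover draw above the crossover threshold (default 0.5) takes it
from the crover, else from the agent. All three models consume the
chosen token so their hidden states stay aligned. The mutation and
crossover variables are drawn unconditionally so limit cases
(thresholds 0/1) are random-stream-identical to plain agent sampling.

Each cycle: sample a batch → score every objective → aggregate to R*
by the chosen scheme → select ⌈20%⌉ of the batch by roulette. Only
valid molecules are solutions: under the Pareto scheme invalid samples
are excluded from the ranking altogether and receive final reward 0
(their all-zero reward vectors would otherwise occupy rank slots — and,
having empty fingerprints, maximal Tanimoto distances — earning reward
the policy update would then reinforce); the weighted scheme likewise
zeroes them. Roulette selection is fitness-proportional, sequential
without replacement, with a uniform fallback when all scores are zero.
The selected molecules drive a REINFORCE update of the agent, maximizing
Σ_b R*_b Σ_t log G(y_t | y_<t) via one Adam step on the re-run
teacher-forced batch. An all-zero reward batch is skipped outright so
it is exactly a null update (an Adam step with zero gradient would
still move parameters through stale momentum). The checkpoint with the
highest epoch mean R* is retained; every `crover_sync_interval` epochs
(default 250) both the agent and the crover are reset to it.

Per-cycle metrics: validity (parseable fraction), desirability
(desirable fraction), uniqueness (fraction of canonical structures new
within the batch and against the accumulated set), mean reward. Final
ranking uses the composite score 0.4·desirability + 0.4·R* +
0.2·uniqueness, where uniqueness here is a per-molecule 0/1
first-occurrence indicator (a batch-level fraction is not attributable
to one molecule), and returns the top 10 by default.

## Synthetic data

The fixtures module generates all test inputs at run time:

* **Corpus** — concatenations of 16 chain-extendable fragments (alkyl
  chains, carbonyl/amide/ester linkers, phenyl/pyridyl/furyl/
  cyclopentyl branches), 2–8 fragments per molecule, ≥5 heavy atoms,
  under a heavy-atom budget. Every entry is valid and survives
  standardization by construction.
* **Structure–activity table** — pX = 4 + 5·min(#marker, 2)/2 +
  N(0, σ), clamped to [3, 10], with ~10% of rows emitted without pX to
  exercise the unlabeled-record path. Default σ = 0.2 pX units, a
  realistic inter-assay spread.
* **Toy predictors** — the same rule without noise, used as cheap
  objective oracles in reinforcement-learning runs.
* **Random scored batches** — uniform reward vectors plus random
  fingerprints for the Pareto machinery's property tests.

These fixtures have the statistical shape the method assumes but are
not a bioactivity simulator: the planted rule is a single additive
substructure effect, chemistry is limited to a 13-token grammar, and
activity cliffs, assay artifacts and scaffold bias are absent. Passing
tests demonstrate that the machinery is correct and that the training
dynamics behave as designed at desk scale; they do not certify
performance on real ChEMBL-scale data.

## Problem sizes

Experiments are sized for a single CPU. Scaled pretraining uses a
5,000-molecule corpus and a reduced generator (embedding 64, one
2-layer LSTM block of width 128, 4-head attention, batch 128) for 30
epochs, then samples 1,000 sequences; validity comes out around
0.96–0.97 across seeds. The scheme-comparison runs use an even smaller
generator (embedding 32, one 2-layer block of width 64) with 200 RL
epochs of 64-molecule batches, crover sync every 50 epochs, and three
noise-free substructure objectives — two sought ring systems and one
penalized common ring system — mirroring the dual-target-plus-
anti-target objective pattern at toy scale. QSAR recovery uses n = 2000
records and 200 trees.

## Known limitations

* Full-scale runs (millions of molecules, 1000+ epochs, 512-wide
  9-layer generator) are out of desk scope; absolute metric values from
  such runs are not reproduced here.
* REINFORCE is used without a baseline; reward normalization through
  the Pareto rank map partly plays that role.
* The evolutionary sampler mixes step distributions rather than
  performing explicit sequence-level crossover; this matches the
  hidden-state-lockstep design the reward loop assumes.
* The vocabulary is corpus-dependent; checkpoints embed their
  vocabulary and refuse mismatched models at sampling time.
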