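# Methods

## Model

A molecule is represented by the multiset of its SMILES attributes. The
tokenizer first normalizes the string — stereochemistry markers `/`, `\`,
`@` are removed (the model cannot use that information) and every `)` is
folded into `(`, because the attribute vocabulary of this method spells
branch-neighbour pairs only in the `(` form (`Cl(`, `2(`, `c(` …) — then
scans left to right: `Cl` and `Br` are single tokens, `[...]` bracket atoms
are single opaque tokens, `%NN` ring closures are single tokens, every other
character stands alone. Single tokens are the `Sk` attributes; adjacent
token pairs, spelled with the larger-leading-character token first (ties
broken by full-token comparison), are the `SSk` attributes. Ring-closure
digits are counted as the same attribute wherever they occur.

Each attribute occurring in at least `T` compounds of the active training
set is *active* and carries a real correlation weight; all others are
blocked (weight 0). `T` counts compounds containing the attribute, not
total occurrences (a flag selects the alternative; the two coincide at
`T = 1`, the only published setting). The descriptor `DCW(T, N)` of a
molecule is the weighted sum of its active attribute counts, and the model
is the ordinary-least-squares line `pLC50 = C0 + C1·DCW` fit on the active
training set only.

## Monte Carlo optimization

Weights start uniform in `init_range` (default (−1, 1)) under a seeded
generator. One epoch visits every active attribute in a fresh random
permutation; a visit draws a step `δ ~ Uniform(0, step_max]` (default
`step_max = 0.1`), evaluates `CW+δ` and `CW−δ` with the calibration line
refit on the active set, and accepts the better proposal only if it
strictly increases the target function. A visit repeats this (fresh `δ`
each trial, capped at 50 trials) until a proposal fails; worsening moves
are never accepted. The per-epoch history records the target value and R²
on the active, passive and calibration sets.

Target functions: `TF0 = R²A + R²P − w·|R²A − R²P|` with `w = 0.1` (the
discrepancy term penalizes train/train disagreement; the flattened published
rendering of the formula is ambiguous about the sign, and a config switch
selects the other convention), and `TF1 = TF0 + 0.25·IIC` with IIC computed
on the calibration set under the current calibration line. Published run
presets: TF0 with `DCW(1, 3)` and TF1 with `DCW(1, 15)`.

A state whose descriptor is constant on any modeling set is assigned
`TF = −∞` and can never be accepted; if no finite state is ever reached the
optimizer raises a degenerate-descriptor error.

## Statistics

R² is the squared Pearson correlation; CCC is Lin's concordance
(population-variance form); Q² is leave-one-out cross-validation of the
univariate line, computed in closed form through leverages; F is
`R²(n−2)/(1−R²)`, printed rounded to the nearest integer. IIC is
`r · min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺)` with residuals `Δ = observed −
predicted` split at zero (ties `Δ = 0` belong to the non-negative class).
Conventions for degenerate cases: both one-sided MAEs zero → ratio 1;
exactly one residual class empty with the other non-zero → ratio 0. The
residual-sign clustering diagnostic reports overall and per-cluster R²
(clusters `Δ < 0` vs `Δ ≥ 0`); a cluster with fewer than 3 points has an
undefined R², flagged rather than raised.

## Applicability domain

The statistical defect of an attribute compares its compound frequencies
`nA, nP, nC` (probabilities `p = n/size`) across the three modeling sets:

    dk = |pA−pP|/(nA+nP) + |pA−pC|/(nA+nC) + |pP−pC|/(nP+nC)

An attribute absent from any one of the three sets gets the maximal defect
1.0 — an attribute invisible to the calibration set is maximally
unreliable. A compound's defect `Dj` sums `dk` over its non-blocked
attributes, once per occurrence; attributes never seen in any modeling set
(possible at prediction time) contribute 1.0 per occurrence, while
seen-but-blocked (rare) attributes contribute nothing. The compound is
inside the domain iff `Dj < 2·D̄` (strict), with `D̄` the mean `Dj` over
the active training set (configurable to the union of the three modeling
sets). Out-of-domain compounds still receive predictions, flagged in every
output.

## Interpretation

Because a single optimization run is stochastic, mechanistic reading uses
several independent probes (default 3) with seeds derived from one base
seed. An attribute whose weight is strictly positive in every probe is a
promoter of endpoint increase; strictly negative in every probe, a promoter
of decrease; anything else (including an exact zero) is unstable. No
minimum frequency is required for promoter status.

## Synthetic data

The generator assembles syntactically valid SMILES-like strings from a
closed vocabulary and assigns `endpoint = c0* + Σ w*(attr)·count(attr) +
Normal(0, σ)`, so the generating model lies inside the model class and
recovery can be judged against a known truth. Defaults: 200 compounds,
chain length 4–10 over C/N/O/S/Cl (carbon 3× as likely), branch probability
0.25, true weights spanning roughly the magnitude range of fitted weight
tables, intercept 1.2, σ = 0.1 × SD of the noiseless signal. Noise can be
given as an absolute SD instead; an atypical-compound option offsets a
chosen fraction of endpoints by a constant to produce the two-cluster
observed-vs-predicted pattern seen with structurally heterogeneous data.

Three vocabulary presets: `identifiable` (default; chains and `(C)`/`(Cl)`
branches only) guarantees a full-column-rank attribute-count matrix, which
recovery tests require. The rank constraint is why it excludes double
bonds: a token that never occurs at a string boundary, like `=`, has pair
counts summing to exactly twice its own count — an exact linear dependency.
`rings` adds double-bond units, ring templates and more branch types;
`brackets` additionally adds bracket atoms and `%NN` closures to exercise
the tokenizer. What the generator deliberately does not emulate: real
chemical constraints (valence, aromaticity), and any structural difference
in difficulty between the four split sets — noise is i.i.d. across
compounds. Passing recovery tests therefore demonstrate that the
optimization machinery works, not that real toxicity data behaves this way.

## Numerical and design notes

- The calibration line, R², CCC, IIC and Q² are computed directly from
  centered dot products; the line is refit at every Monte Carlo proposal,
  so these run in O(n) per proposal with no model-fitting library in the
  inner loop.
- Splits assign each compound independently with the given probabilities
  (default 25% each) and redraw until all four sets are non-empty; set
  sizes therefore fluctuate binomially, as repeated random splits of one
  dataset do in practice. Exact-quota splitting is deliberately not used.
- Model JSON artifacts round-trip bit-exactly (floats serialized via
  shortest-round-trip repr, keys sorted); identical seed + config + data
  reproduce byte-identical artifacts.
- Dispersion in multi-split reports is given both as population and sample
  standard deviation, since the published summaries do not define their
  estimator.
- Table outputs round R²-family statistics to 4 decimals, RMSE/MAE to 3
  significant figures and F to the nearest integer, and the validation row
  reports only n, R², RMSE and MAE, mirroring the published layout.

## Known limitations

- With strict-improvement single-attribute moves, TF1 optimization has a
  structural stall: once the calibration-set residuals balance (IIC ratio
  at its kink maximum), every further single-coordinate fit improvement is
  taxed more by the ratio term than it gains, so noiseless recovery
  plateaus around R² ≈ 0.95 rather than 1. Exact per-coordinate line
  search — an upper bound for any step distribution in this move class —
  stalls the same way, while TF0 (no IIC term) converges to R² ≈ 0.9997 on
  the same data. At machine-precision fits the IIC ratio of float-noise
  residuals is effectively random, so the true weight vector is not even
  the TF1 optimum.
- Under TF0, epoch-level active-training R² can dip by ~1e-3: the target
  accepts moves whose passive-training gain outweighs a small
  active-training loss. The trajectory is rising but not strictly monotone.
- Because generated noise is i.i.d. across sets, the in-sample
  active-training R² of a fitted model systematically exceeds the
  calibration-set R²; the inverted ordering reported for real
  pharmaceutical data (calibration above training) reflects structural
  heterogeneity that this generator does not reproduce.
- Attribute probabilities use compound frequencies; published defect
  values are reproduced in convention (zero at equal probabilities, 1.0
  for set absence) but individual printed defect values are not exactly
  recoverable from printed frequencies, suggesting unpublished details in
  the original software's accounting.
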