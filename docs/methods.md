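# Methods

## Profile model

A seed alignment of α rows over the 20 amino acids (gap characters `-` and
`.`) is turned into a length-L profile HMM with match, insert and delete
states per column. Estimation is by maximum likelihood with additive
pseudocounts:

* match emissions: `(count + c) / (depth + 20 c)`, where depth excludes
  gaps and ambiguity characters and `c` is the pseudocount (default 1.0);
* insert emissions: uniform background (1/20);
* transitions: counted from each row's match/delete column path, smoothed
  with `c` over {M→M, M→I, M→D} (3 outcomes), {D→M, D→D} (2) and entry
  {B→M1, B→D1} (2); insert transitions are fixed at I→M = I→I = 0.5.

Both builds of a model share these emission estimates and differ only in
alignment topology. A model's **consensus sequence** is the per-column
arg-max emission (ties broken alphabetically).

## Alignment engines

Scores are log₂ odds ("bits") against a uniform background; flanking
sequence outside the aligned region is free (background-scored).

**Glocal** Viterbi enters the model at position 1 (match or delete, using
the estimated begin probabilities) and leaves after position L, so
`model_span` is always `(1, L)`; the sequence flanks are unconstrained.
Delete chains are handled per DP row with a vectorized prefix-max over the
cumulative D→D transition scores.

**Multihit local** Viterbi enters at any match position with probability
1/L, exits freely after any match, and may restart for additional domains
at a charge of `MULTIHIT_RESTART_BITS = 1` bit (restart probability 0.5).
The parse is recovered by traceback; ties prefer fewer domains. Every
non-empty sequence yields at least one domain (best-scoring, possibly
negative).

Each alignment carries `per_position_scores`: position k collects its
emission, any following insert block, the transition to k+1, and (at the
first position) the entry term, so the array sums to the bit score exactly.
Both engines are verified against independent brute-force path enumeration
for all models L ≤ 3 × all sequences of length ≤ 4 over a 4-letter
alphabet (`tests/bruteforce.py`).

## Null statistics

Per model and build, bit scores of `n_null` random uniform sequences
(lengths uniform in [L/2, 2L], default n_null = 200; 150 in the acceptance
study) are fit to a Gumbel law by maximum likelihood
(`scipy.stats.gumbel_r.fit`). The fit is location-equivariant to machine
precision and recovers the scale parameter within 10 % at n = 5000.
E-values use the full survival function

    E(s) = Z · (1 − exp(−exp(−λ (s − μ))))

with Z the search database size (the library size during calibration, per
the convention that E-values must match the downstream scan).

## Calibration

For target model m: positives are m's degapped seed rows
(`m/seed1 …`), negatives the other models' consensus sequences
(N_neg = N_total − 1). Both builds search all queries at a permissive
cutoff (E ≤ 1000). Hits are **stratified**: within a query, a glocal hit is
paired with the local hit of maximal model-span overlap (ties to the
smaller model start); unpaired hits are orphaned. Each paired glocal hit is
**reconstructed** over its local partner's model-span window by re-summing
its stored per-position bit contributions; the windowed score gets a new
E-value under the glocal build's own Gumbel parameters. The identity window
[1, L] reproduces the original score and E-value exactly.

Per build, the per-query E-value (reconstructed/orphaned minimum for
glocal; best domain for local) enters a **calibration table**: negatives
sorted ascending define the FP = k boundary as the k-th order statistic;
ROC and precision–recall staircases sweep the distinct observed E-values.
FPR = FP / N_neg. The reporting grid FP ∈ {1, 5, 10, 15, 20, 25, 30, 40,
50, 60, 70, 80, 90, 100} reproduces, at 16294 negatives, the conventional
FPR values 6.14e-5 … 6.14e-3.

## Build selection

For FP limit x, the partial AUC is the right-continuous step integral of
the ROC staircase over FPR ∈ [0, x/N_neg]; past the detected negatives the
staircase extends flat. The normalized difference is

    diff(x) = (AUC_glocal − AUC_local) / (x / norm_n),

with `norm_n` defaulting to the library size (the sign is invariant to
this). Over an ordered FP set A (default {1, 5, 10, 20, …, 100}),
`count_y = #{x ∈ A : diff(x) > 0}`. `count_y = |A|` selects the glocal
build; `count_y = 0` the local build; anything between is undetermined
(the sensitivity ranking fluctuates with x) and runs local downstream. A
flag `literal_printed_mapping` restores an alternative label pairing that
swaps the lower two classes; the default follows the criterion's prose.
Suffix sweeps of A (dropping the smallest x first) report how the totals
shift; totals always partition the library.

## Annotation workflow

* **Stage 1** — scan each query against the N glocal-selected models
  (cutoff E ≤ 24) and the M local models (cutoff E ≤ 0.1); the asymmetric
  cutoffs correspond to the largest FP ranks sampled for each build.
  `top_n_override` can cap N (ranking glocal models by count_y, then mean
  diff); N = 0 and N = N_total give the pure-local and pure-glocal
  extremes.
* **Stage 2** — one glocal re-alignment per distinct (query, model) pair
  among the local detections, so every final annotation spans [1, L].
* **Stage 3** — FP(FPR) assignment: a hit's E-value is placed in the
  calibrated FP-grid boundary intervals and assigned the nearer margin in
  log₁₀ E-value (exact midpoints go to the larger FP). E-values below the
  FP = 1 boundary get the `FP<1` sentinel, beyond the last boundary
  `beyond-grid` (rendered `>grid`); sentinels carry FPR = NaN.

The **concordance screen** compares FP_glocal and FP_local for
dual-assigned records: |ΔFP| ≤ 4 is concordant, ΔFP < −4 (local build
markedly less significant on the common FPR scale) is flagged for
scrutiny; sentinel-valued records are excluded and reported separately.

## Speed model

With T_local the measured local-scan time over the M local models,
T_realign the stage-2 re-alignment time, and T_glocal the time of a
reference glocal scan of the same M models, the predicted speed-up over a
pure glocal search is `f = T_glocal / (T_local + T_realign)`, bounded above
by `T_glocal / T_local` and strictly decreasing in T_realign. Wall-clock
values are reported, never asserted: both engines here are Python dynamic
programs of similar cost, so desk-scale `f` is near 1, unlike optimized
production scanners where the local engine is orders of magnitude faster.

## Synthetic fixtures

`FixtureSpec` defaults: 30 models, lengths 60–90, α = 8 seed rows at
conservation p = 0.95 around a uniform-random consensus, 30 queries (20 %
implant-free decoys) with one implant each (5 % substitution) between
background linkers of 5–20 residues. Uniform background matches the
engines' null so implant log-odds are calibration-consistent. Per-column
seed identity has expectation p + (1 − p)/20 (checked against binomial
bounds). The `weakened_local` set marks models whose *local* build is
estimated from a seed copy substituted at rate 0.9; this leaves that
profile essentially uninformative, so its positives interleave with
negatives while the clean glocal build still separates them — the condition
for a uniform glocal advantage over the whole FP set. Everything is
reproducible from `rng_seed` via independent `SeedSequence` spawn keys.

## Numerical choices and limitations

* Probabilities are converted once to log₂ tables; an extra emission
  column with zero log-odds absorbs ambiguity characters.
* Traceback comparisons use a 1e-9 relative/absolute tolerance; score
  equalities asserted in tests are exact where the algebra guarantees it
  (reconstruction identity, per-position sum).
* Gumbel fitting rejects degenerate (constant or tiny) samples.
* The generator does not model realistic amino-acid composition, indel-rich
  evolution or non-globular segments; libraries are small, so FP grids are
  truncated to the available negatives and many fixture hits legitimately
  fall below the FP = 1 boundary.
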