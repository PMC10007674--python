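# Methods

## Aggregation model

A fuzzy measure (capacity) on the index set N of K views is a set function
m : 2^N → [0,1] that is monotone under inclusion with m(∅) = 0 and
m(N) = 1. All measures here are *symmetric*: m(X) depends only on |X|, so a
measure is stored as an (n+1)-vector indexed by cardinality
(`CardinalityMeasure`). The shipped family is the power measure
m_q(X) = (|X|/n)^q, q > 0. The two boundary entries are assigned exact 0
and 1 rather than computed through the power, so the capacity axioms hold
without floating-point drift; `validate_measure` re-checks boundaries,
monotonicity and range and names the offending index on failure.

The discrete Choquet integral of x ∈ [0,1]^n with respect to m is

    C_m(x) = Σ_{i=1..n} (x₍ᵢ₎ − x₍ᵢ₋₁₎) · m(A₍ᵢ₎),   x₍₀₎ = 0,

with x₍₁₎ ≤ … ≤ x₍ₙ₎ the increasing sort and A₍ᵢ₎ the indices of the
n − i + 1 largest components; symmetry reduces m(A₍ᵢ₎) to a cardinality
lookup. The integral is an idempotent, monotone, internal
(min ≤ C_m ≤ max) aggregation function; with the power measure it
interpolates from max (q → 0) through the arithmetic mean (q = 1) to min
(q → ∞). Ties in x are provably inconsequential — tied components produce
zero differences — so no tie policy is needed inside the integral; this is
property-tested rather than assumed. Accumulation runs in fixed ascending
order, making results bit-reproducible. A second, independently coded form
Σ x₍ᵢ₎·(m(A₍ᵢ₎) − m(A₍ᵢ₊₁₎)) (`choquet_oracle`) exists only as a
cross-check in the tests.

## Consensus protocol

For one capture (a C × K matrix, one softmax column per view) every class
row is Choquet-aggregated independently and the consensus class is the
maximum fused response. Design choices where the protocol was genuinely
open:

* **No renormalisation.** The fused vector is generally not a probability
  distribution and is reported as-is; the argmax decision depends only on
  ordering. A display-time renormalisation helper exists and never affects
  decisions.
* **Tie-break** is the lowest class index, with a `tie_broken` flag in the
  output; at tolerance 1e-12 two fused responses count as tied.
* **q default = 1.** No exponent is canonically fixed for this protocol;
  q = 1 (the mean) is the neutral default, and `--q` sweeps are first-class
  in the CLI and experiment runner.
* **Input hygiene.** Scores must lie in [0,1]; violations up to 1e-9
  (softmax export rounding) are clamped with a warning, larger ones are
  errors. Softmax columns must sum to 1 within 1e-4, downgradeable to a
  warning for rounded exports. K = 1 is supported and makes Choquet fusion
  exactly the single-view pass-through.

## Evaluation

Per class (one-vs-rest): Prec = TP/(TP+FP), Rec = TP/(TP+FN) and
F_β = (1+β²)·Prec·Rec/(β²·Prec+Rec), reported for β = 0.5 and 1. Summary
values are **macro-averaged** (unweighted over classes); macro is chosen
because it lets precision and recall move independently in a single-label
multiclass problem, where micro-averaging collapses both to accuracy.
Reports label the averaging mode explicitly. 0/0 slots (a class never
predicted or never present) are defined as 0 and logged, never NaN. TN is
not tracked; no reported metric needs it. Counts come from
scikit-learn's multilabel confusion matrix; the derived metrics are
cross-checked against scikit-learn's macro P/R/F in the tests.

## Synthetic multi-view generator

The simulator emulates per-view classifier *outputs*, not images: each
view's column is a Dirichlet draw on the C-simplex, which is the natural
stand-in for a softmax vector. Per capture, a true class is drawn
uniformly; each view independently is *corrupted* with probability
`p_corrupt` — its column drawn Dirichlet(alpha_noise·1) with no information
about the truth, a simple proxy for occlusion or background confusion —
and otherwise drawn with `alpha_signal` added on the true class.

Parameters (units: Dirichlet concentrations are dimensionless):

| parameter      | default              | meaning |
|----------------|----------------------|---------|
| C              | 38                   | class count of the reference problem |
| K              | 4                    | cameras per capture |
| alpha_noise    | 1.0                  | base concentration on every class (flat prior) |
| alpha_signal   | 20 clean, 8 degraded | boost on the true class in an informative view |
| p_corrupt      | 0.05 clean, 0.35 degraded | probability a view carries no signal |

The `clean` regime stands in for homogeneous-background lab imagery
(strong, rarely-corrupted views); `degraded` for field-like clutter where
a trained model frequently misfires. The degraded defaults are qualitative:
they are tunable conditions chosen to place single-view macro-F1 in the
0.55–0.65 band that a clutter-degraded classifier plausibly occupies, not
measurements of any real model. True classes are uniform; real datasets'
class imbalance is not modelled. Views are corrupted independently;
correlated failures (all cameras blinded at once), calibration error and
inter-view correlation of informative outputs are not modelled either —
passing the simulation study therefore demonstrates the fusion mechanism's
robustness to independent view dropout, not performance on real imagery.

Reproducibility: one root seed; per-capture streams are spawned from it
(`numpy.random.SeedSequence.spawn`), so batches are bit-identical under any
generation order and any subset of captures can be regenerated.

## Robustness study and problem sizes

`run_experiment` simulates one batch and scores every requested fusion mode
(Choquet per q, mean/min/max, each single view and their unweighted
average) against the truth. The packaged study uses 2000 captures per
batch, 20 seeds per regime for the median fusion gain, and 5000 captures
for the fully-corrupted chance floor (1/C with binomial Monte-Carlo error)
— sizes at which every Monte-Carlo band in the tests is a few standard
errors wide while a full run stays under a minute on one core. Expected
pattern, confirmed by `scripts/acceptance.py`: the Choquet consensus beats
the mean single view in both regimes, and the gain is several times larger
in the degraded regime — robustness from fusion matters most where views
are least reliable.

## Known limitations

* Only symmetric (cardinality-based) measures: no λ-measures, learned
  capacities or view-specific weights; extensibility is via the
  `CardinalityMeasure` contract.
* Only the power-measure family is shipped; arbitrary valid cardinality
  tables can be supplied via JSON.
* The generator's degraded regime is a stylised corruption model (see
  above); conclusions transfer to real camera arrays only qualitatively.
* Macro averaging is fixed in the reports; micro/weighted averaging is not
  implemented.
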