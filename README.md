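# choqfuse

Decision-level fusion of multi-view classifier outputs with the discrete
Choquet integral, for robust consensus classification — the setting is a
plant-disease monitor where K cameras each photograph the same plant and a
per-view classifier emits a softmax vector over C disease classes (the
reference instance is C = 38 classes, K = 4 cameras). A single view is
easily fooled by occlusion or background clutter; fusing the views yields a
decision that degrades far more gracefully.

## The method

Each capture is a C × K matrix of per-view class probabilities. For every
class c, its K view scores x = (x₁, …, x_K) ∈ [0,1]^K are aggregated with
the **discrete Choquet integral** with respect to a fuzzy measure m:

    C_m(x) = Σᵢ (x₍ᵢ₎ − x₍ᵢ₋₁₎) · m(A₍ᵢ₎),

where x₍₁₎ ≤ … ≤ x₍K₎ is the increasing sort of x, x₍₀₎ = 0, and A₍ᵢ₎ is the
index set of the K − i + 1 largest components. The measure is the symmetric
**power measure** m_q(X) = (|X|/K)^q with q > 0, so m(A₍ᵢ₎) depends only on
cardinality. At q = 1 the integral is the arithmetic mean; q → 0 tends to
the maximum and q → ∞ to the minimum, so one exponent spans the whole
optimistic-to-conservative range. The consensus class is the maximum fused
response (ties broken to the lowest class index, flagged in the output).

Evaluation uses macro-averaged precision, recall and
F_β = (1+β²)·Prec·Rec / (β²·Prec + Rec) with β ∈ {0.5, 1}.

Because no images or trained networks are consumed, a built-in simulator
generates per-view softmax outputs directly on the probability simplex:
Dirichlet columns with a concentration boost on the true class, and a
per-view corruption probability under which a view carries no information
about the truth. A `clean` regime emulates homogeneous-background lab
imagery; a `degraded` regime emulates field-like clutter (weaker boost,
frequent corruption). See `docs/methods.md` for the model and defaults.

## Worked example

Simulate 200 degraded-regime captures and run the single-view vs fused
comparison:

```
choqfuse simulate --regime degraded --n 200 --seed 42 --out-dir demo --experiment
```

`demo/experiment_report.csv` (abridged):

```
mode,q,accuracy,Prec,Rec,F0.5,F1
choquet,1.0,0.975,0.977,0.969,0.972,0.968
single_view:0,,0.615,0.603,0.594,0.586,0.578
single_view:3,,0.665,0.647,0.646,0.635,0.629
single_view_mean,,0.615,0.602,0.601,0.587,0.580
```

With 35% of views corrupted, any single camera identifies the disease in
only ~60% of captures (macro-F1 ≈ 0.58), while the four-camera Choquet
consensus reaches macro-F1 ≈ 0.97: corrupted views contribute flat, small
scores that the fusion averages away. The same pipeline runs step by step:

```
choqfuse fuse demo/batch_scores.csv --q 1 --out demo/preds.csv
choqfuse evaluate --predictions demo/preds.csv --truth demo/batch_labels.csv --out demo/report.csv
```

which logs `macro metrics over 200 captures: {'Prec': 0.9767, 'Rec':
0.9688, 'F0.5': 0.972, 'F1': 0.9684}`. Score matrices are long-format CSV
(`capture_id, class, cam0, …`); predictions and reports are CSV with a JSON
provenance comment (q, measure, tie-break rule) plus a JSON twin.

The library API mirrors the CLI: `power_measure`, `choquet`, `fuse_views`,
`predict_batch`, `confusion`/`evaluate`, `SimulationConfig`,
`simulate_batch`, `run_experiment`.

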