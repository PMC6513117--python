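# funcsig

Sign-dependent functional module detection in multivariate activity
recordings, via a global-mode-corrected random-matrix null model.

## What problem this solves

Neural and other biological recordings — e.g. single-cell PER2::LUC
bioluminescence from the suprachiasmatic nucleus (SCN), calcium imaging,
region-level fMRI — often hide a modular organization in which groups of
units are positively correlated internally and *negatively* correlated
across groups (phase-opposed oscillator populations, excitation/inhibition
balance). Standard workflows miss it: thresholding the correlation matrix
into a network discards the negative entries and makes the answer depend on
an arbitrary threshold, while signed-modularity methods use null models
with independent matrix entries that misprice the metric constraints of
correlation matrices and tend to *merge* anticorrelated groups when a
strong system-wide rhythm shifts all correlations positive.

`funcsig` is for experimentalists and analysts who have an `N x T`
unit-by-time matrix and want a threshold-free, statistically filtered
partition into sign-contrasted modules — the recording's *functional
signature* — plus the statistics that describe it.

## Method in brief

1. **Null model.** Pearson correlation matrix `C`; the spectrum of a
   structureless recording with the same noise level and the same global
   mode is a Wishart bulk with edges

   `lambda_± = (1 − lambda_max/N)(1 ± 1/sqrt(Q))²`, `Q = T/N`,

   where `lambda_max` is the largest empirical eigenvalue. The global mode
   *left-shifts* the noise bulk: the higher `lambda_max`, the lower the
   noise ceiling `lambda_plus`. The correction is applied only when a
   global mode is actually present (sign-uniform leading eigenvector).
2. **Filtering.** Eigenvalues strictly between `lambda_plus` and
   `lambda_max` are structural; `C_filt = Σ_s λ_s v_s v_sᵀ` keeps exactly
   the noise- and trend-free modular information.
3. **Modules.** Maximize
   `Q(σ) = (1/C_norm) Σ_ij [C_filt]_ij δ(σ_i, σ_j)` with a Louvain-style
   optimizer whose output is stable under node moves, pairwise merges and
   module dissolution — guaranteeing positive total correlation inside
   every module and non-positive total correlation between any two. The
   number of modules is an output. No structural eigenvalues ⇒ "no
   significant structure".

Repeated-run co-classification, consensus partitions, recursive hierarchy
detection, circadian QC, signature statistics (within/between residual
correlations and contrast ratios `δ`), and two baselines (threshold
networks with `S`/`M` curves; signed modularity) are included. See
`docs/methods.md` for the full account.

## Worked example

Generate the planted benchmark — 3 groups of 100 phase-shifted oscillators
behind a strong, slightly detuned global rhythm that drives every pairwise
correlation positive — and run the pipeline:

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from funcsig import (benchmark_config, generate_grouped_oscillators,
                     detect_modules, signature_stats)

rec, truth = generate_grouped_oscillators(benchmark_config(with_trend=True, seed=0))
res = detect_modules(rec, seed=1)
p, cls = res.partition, res.filtered.classification

print(f"lambda_max = {res.bounds.lambda_max:.2f}, "
      f"corrected lambda_plus = {res.bounds.lambda_plus:.3f}")
print("structural eigenvalues:",
      np.round(res.decomposition.eigenvalues[cls.structural_indices], 2))
print(f"modules: {p.n_modules}, sizes = {np.bincount(p.labels)}, "
      f"Q = {p.modularity:.4f}")
report = signature_stats(res.filtered, p)
for m in report.modules:
    print(f"module {m.module}: size {m.size}, "
          f"mean residual {m.mean_residual:+.4f}, delta {m.contrast_ratio:.3f}")
for pr in report.pairs:
    print(f"pair ({pr.module_a},{pr.module_b}): "
          f"mean residual {pr.mean_residual:+.4f}, delta {pr.contrast_ratio:.3f}")
print("ARI vs planted labels:", adjusted_rand_score(truth.labels, p.labels))
```

Output:

```
lambda_max = 296.39, corrected lambda_plus = 0.038
structural eigenvalues: [2.2  1.03]
modules: 3, sizes = [100 100 100], Q = 0.0035
module 0: size 100, mean residual +0.0132, delta 0.000
module 1: size 100, mean residual +0.0069, delta 0.000
module 2: size 100, mean residual +0.0114, delta 0.000
pair (0,1): mean residual -0.0043, delta 0.048
pair (0,2): mean residual -0.0088, delta 0.000
pair (1,2): mean residual -0.0026, delta 0.182
ARI vs planted labels: 1.0
```

Reading this: the global mode soaks up `lambda_max ≈ 296` of the `N = 300`
total variance, pushing the corrected noise ceiling down to `0.038`; the
two surviving structural eigenvalues (2.20, 1.03) lie *below* the
uncorrected Marchenko–Pastur edge (3.15) — without the correction they
would be discarded as noise. The optimizer returns exactly the three
planted groups (ARI = 1): mean residual correlation positive inside every
module, negative between every pair, with near-zero contrast ratios `δ`
(almost no wrong-sign entries). On the same recording the signed-modularity
baseline merges two of the planted groups.

The same pipeline is available from the shell:

```sh
funcsig synth --out fixture --groups 100,100,100 --trend-amplitude 8 --seed 0
funcsig detect --input fixture/recording.csv --out run --seed 1
funcsig baseline --input fixture/recording.csv --out base --method signed
funcsig hierarchy --input fixture/recording.csv --out tree --max-depth 2
```

Every output directory contains a `manifest.json` that replays the run
exactly; identical config + seed give byte-identical artifacts.

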