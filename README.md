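# connsig

Resting-state functional-connectivity classification of three groups
(patient / healthy sibling / healthy control), from regional BOLD time
series to discriminative connectivity signatures:

1. **synthetic** — three-group cohort generator. Subjects are lag-1
   autoregressive Gaussian processes whose stationary cross-sectional
   correlation follows group-specific matrices in which designated edges
   are perturbed: patient-only (*state*), patient+sibling (*trait*) and
   sibling-only (*compensatory*) effects, plus a shared global component
   and motion-like confounds. Ground truth is carried alongside so every
   downstream stage is testable.
2. **preprocess** — initial-volume discard, zero-phase Chebyshev type-I
   band-pass (0.01–0.08 Hz by default), and OLS nuisance regression of
   the global mean signal and motion regressors.
3. **connectivity** — pairwise Pearson correlations over R regions,
   vectorized by the canonical row-major upper triangle (R = 116 gives a
   6670-dimensional edge vector).
4. **model** — per-fold PCA + one-against-rest linear SVMs,
   leave-one-out cross-validation, and a label-permutation test with the
   add-one p-value estimator.
5. **signatures** — per-fold SVM weights are back-projected to edge
   space through each fold's own PCA transform, averaged, ranked by
   absolute magnitude, and the top fraction (5% by default) of each
   one-against-rest classifier yields the state (patient-vs-rest),
   trait (control-vs-rest) and compensatory (sibling-vs-rest) edge sets.
6. **io / cli** — plain-text readers/writers (TSV/JSON/YAML) and the
   `connsig` command-line interface.

## CLI

```sh
connsig simulate  --out sim/ --seed 1 --n-per-group 24,25,22 \
                  --n-regions 30 --n-planted 10,10,10 --delta-r 0.5
connsig preprocess --in sim/ --out pre/
connsig classify  --in pre/ --out clf/ --n-perm 1000 --seed 1
connsig signatures --in clf/ --out sig/ --fraction 0.05 \
                  --truth sim/ground_truth.json
connsig report    --in clf/
```

`simulate` writes per-subject time-series and motion TSVs, a
`labels.tsv`, region labels and `ground_truth.json`; `classify` writes
`results.json` (accuracy, row-normalized confusion matrix in percent,
permutation p-value, full configuration) and the fold-averaged
edge-weight table; `signatures` writes one ranked edge table per
signature. Use `--top-k 330` to pin the selection size instead of the
computed floor(0.05 · E).

## Notes

* PCA component count defaults to the per-fold maximum
  min(n_train − 1, p); SVM cost defaults to C = 1. Both are exposed.
* Correlations are used raw as features; a Fisher-z option exists
  (`--fisher-z`) but is off by default.
* The permutation test reuses each fold's PCA projection across
  permutations — the transform depends only on the training features,
  which label permutation does not change — so the 1,000-iteration null
  is exact but fast.
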