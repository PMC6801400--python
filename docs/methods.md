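# Methods

## Model and procedure

A two-class expression study is a probes × samples matrix **E** (log2
scale, assumed already normalized) with an observed class array over the
samples (case vs. control). A *signature* `g` is an ordered probe subset;
its predictor is a k-nearest-neighbor classifier, its cost `O(g)` the
number of misclassified samples, and its accuracy
`Acc(g) = 100·(1 − O(g)/n)`. The object of interest is the uncertainty set
`M_tol` of signatures with `Acc(g) ≥ Acc_min = 100 − E_tol`, summarized by
the posterior sampling frequency of each probe over sampled members of
`M_tol`.

### Per-probe statistics

Fisher's ratio `FR = (μ₁−μ₂)²/(s₁²+s₂²)` uses unbiased class variances.
The bare two-group function applies no denominator guard (so it matches
the closed form exactly); matrix-level ranking adds
`ε = 10⁻¹² × Var(E)` to the denominator so constant probes score 0 and
rank last instead of dividing by zero. A probe that is constant within
each class but differs between classes gets a huge finite FR — it
separates the classes perfectly and deserves the top rank. Ties in the
ranking break by probe id, making the ranking a deterministic function of
the data. Expression direction is "over" iff the case mean strictly
exceeds the control mean (ties are "under" by convention).

The differentially-expressed candidate pool defaults to probes with
FR ≥ the 90th percentile of the FR distribution; `top_n` selection is
available as an alternative. This is a tuning choice, not a test — no
published criterion exists for this stage.

### Classifier

Euclidean k-NN on per-probe z-scored expression, standardization fitted on
the training fold only. Because subtracting the training mean shifts
query and training points identically, only the training-fold variances
affect neighbor order; the implementation divides squared coordinate
differences by those variances directly. Numerical conventions: k must be
odd (no vote ties with two classes); distance ties at k = 1 resolve to the
first sample in canonical dataset order; a feature constant in the
training fold gets unit scale (its contribution is label-independent and
cannot change neighbor order). LOOCV refits the standardization for every
fold; a cumulative-sum identity makes all leave-one-out fold variances one
vectorized computation, and a shared (fold × sample × feature) array of
scaled squared differences lets the samplers score thousands of probe
subsets by summing feature slices.

### Minimal signature

The minimal ("small-scale") signature is the shortest FR-ranked *prefix*
attaining the maximum LOOCV accuracy over prefixes of length
1..`max_depth` (default `min(pool size, 100)`). Prefix semantics keep the
search deterministic and linear; arbitrary subsets are explored by the
samplers, not here.

### Fisher's-ratio sampler

Network size is uniform on `{1, …, ceil(length_factor·ℓ*)}` with
`ℓ*` the minimal-signature length and `length_factor = 3` by default —
the least-informative size law consistent with "random complexity around
the minimal scale". Membership is drawn without replacement by sequential
weighted draws with renormalization, weight ∝ FR (zero-FR probes keep an
ε = 10⁻¹²·max(FR) weight; infinite-FR probes are capped at 10× the
largest finite FR). Networks are scored by full-data LOOCV and accepted
at `accuracy_min_pct` (default 90, i.e. E_tol = 10). A run that accepts
nothing raises an explicit empty-`M_tol` error rather than returning an
empty posterior.

### Holdout sampler

Bags are stratified 75/25 splits: per class, the training count is
round-half-up(0.75·n_class), adjusted ±1 by largest remainder so totals
equal round(0.75·n); every class must keep ≥2 training and ≥1 validation
samples. Within each bag, ranking, pool selection and minimal-signature
search see the learning fold only; the signature is then scored blind on
the validation fold and accepted at `validation_min_pct` (default 90).
Bags are drawn independently; duplicate partitions are allowed.

### Posterior, consensus, enrichment

Posterior frequency = (#accepted sets containing the probe)/(#accepted);
probes in no accepted set are implicitly 0. Consensus lists take probes
with frequency ≥ cutoff (default: 90th percentile of nonzero
frequencies), split by full-data direction — direction is deliberately
not re-estimated per bag, so each probe appears in exactly one table.
Sampler agreement reports top-n Jaccard and a Spearman correlation of
frequencies over the union of the top-n lists.

Enrichment is an upper-tail hypergeometric test `P(X ≥ overlap)` per GMT
set, BH-adjusted per direction. The default universe is everything the
chip measured (all dataset probes after optional symbol mapping), not the
genome. Probe→symbol collapsing keeps the maximum-FR probe per symbol.
The Reactome-style web query is out of scope; any GMT collection works.

## Synthetic data

The generator emulates normalized log2 microarray data: baseline probe
means uniform on [4, 12], i.i.d. Gaussian within-class noise of sd σ, and
`n_informative` probes whose case mean is shifted by +δ, giving population
Fisher's ratio `δ²/(2σ²)`. Options: a shared latent factor giving pairwise
correlation ρ within the informative block (marginal variance preserved),
and label flipping of a fixed fraction of samples. Informative probes
occupy random positions and are disclosed only via the ground-truth
sidecar, keeping downstream stages blind. Not modelled: probe-level array
artifacts, batch effects, heavy-tailed noise, probe–probe correlation in
the background — so passing recovery tests demonstrates correctness of the
algorithms under a clean Gaussian null, not performance on raw GEO data.

## Validation studies and problem sizes

The package validates itself on fixed study designs (see
`pathsampler.studies`):

* **Recovery design**: 20 samples/class, 500 probes, 5 planted at δ = 2,
  σ = 1 (FR = 2); the Fisher's-ratio sampler draws 2000 networks at a 90%
  floor, the holdout sampler 200 bags at a 90% validation floor; a
  replicate passes when all 5 planted probes sit in the posterior top 10
  (a probe counts as in the top 10 when fewer than 10 probes have strictly
  greater frequency). 20 seeded replicates per sampler.
* **Null design**: the same cohort with nothing planted; labels are
  permuted and the maximum posterior frequency of the observed run is
  compared with the 99th percentile of per-permutation maxima (50
  re-permutations for the Fisher's-ratio sampler, 30 for the holdout
  sampler — a max-statistic permutation calibration). Null runs use a 50%
  acceptance floor so the null posterior is populated; at 90% the null
  correctly yields the empty-`M_tol` error.
* **Oracle sweeps**: Fisher's ratio vs. its closed form on 1000 random
  instances; LOOCV vs. a brute-force refit-per-fold implementation on 200
  random datasets (n ≤ 12, ≤ 5 probes, k ∈ {1, 3}); hypergeometric tail
  vs. exact integer enumeration on every instance with universe ≤ 30; BH
  vs. the direct step-up formula on 500 random p-vectors.

These sizes keep the full validation run around a minute on one CPU while
giving the recovery rates ≥95% headroom; they are the package's reference
conditions, and `scripts/acceptance.py` recomputes all of them from a
single seed.

## Reproducibility

Every random stage consumes a `numpy.random.Generator` seeded explicitly;
the CLI expands one user seed into per-stage seeds by hashing
`"<seed>:<stage>"` (first 4 bytes of SHA-256, mod 2³¹). Two runs with the
same seed produce byte-identical result tables; the run manifest
additionally records configuration, seed, package versions and a wall-clock
timestamp (the manifest is therefore the one artifact excluded from
byte-identity comparisons).

## Known limitations

* The acceptance floors (90%), pool rule (90th FR percentile), network
  size law and bag counts are defaults exposed in the configs, not
  published constants; real studies should calibrate them.
* Prefix-only minimal signatures can miss non-nested optimal subsets.
* k-NN distance metric and z-scoring are design choices; no metric
  learning is attempted.
* Enrichment treats gene sets as flat lists (no topology, no GSEA-style
  rank statistics) and its default universe is chip-centric.
* Expression input must be complete (no NA handling) and already
  normalized; probe collapsing happens only at the enrichment boundary.
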