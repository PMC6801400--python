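# pathsampler

Sampling the uncertainty space of two-class phenotype prediction on gene
expression data, to find *defective pathways* rather than a single "best"
biomarker list.

## The problem

In a typical transcriptomic case/control study (tens of samples, tens of
thousands of probes) the classification problem is massively
underdetermined: many different gene signatures predict the phenotype
almost equally well, so the signature with the single highest accuracy is a
fragile and arbitrary summary of the biology. The useful object is instead
the *uncertainty set*

    M_tol = { g : Acc(g) >= 100 − E_tol }

of all signatures `g` whose predictive accuracy stays within a tolerance
`E_tol` of perfect. Genes that recur across `M_tol` — measured by their
**posterior sampling frequency** — are robust disease markers, and gene-set
over-representation of those recurrent genes points to the defective
pathways.

`pathsampler` implements two samplers of `M_tol`:

* **Fisher's-ratio sampler** — probes are ranked by Fisher's ratio
  `FR = (μ₁ − μ₂)² / (s₁² + s₂²)`, a two-class separability measure;
  random networks are drawn from the differentially-expressed pool with
  inclusion weight ∝ FR and network size up to a few times the length of
  the minimal signature; each network is scored by leave-one-out
  cross-validated (LOOCV) k-NN accuracy and accepted when it reaches the
  acceptance floor `Acc_min = 100 − E_tol`.
* **Holdout sampler** — repeated random 75/25 learn/validate bags; in each
  bag the minimal signature (shortest FR-ranked prefix with maximal
  training-fold LOOCV accuracy) is selected on the learning fold only and
  scored blind on the validation fold; bags passing the validation floor
  are kept.

Both samplers report posterior frequencies over their accepted sets; the
high-frequency genes, split into over-/under-expressed in the case class,
feed a local hypergeometric over-representation analysis (ORA) against GMT
gene-set collections with Benjamini–Hochberg FDR control.

A synthetic-data module generates two-class expression matrices with
planted informative probes of known effect size (population Fisher's ratio
`δ²/2σ²`), so the whole pipeline is testable without external data.

## Worked example

Simulate a cohort of 20 cases and 20 controls with 500 probes, 5 of them
planted with a moderate shift (δ = 2, σ = 1, i.e. population FR = 2), and
run the full pipeline:

```bash
pathsampler run-all --simulate --n-case 20 --n-control 20 \
    --n-probes 500 --n-informative 5 --effect-size 2 \
    --n-networks 2000 --n-bags 200 --seed 1 --out-dir results/demo
```

prints

```
minimal signature 3 probe(s) at 100.0% LOOCV; accepted 835 networks, 155 bags
```

i.e. the shortest FR-ranked prefix that classifies every sample correctly
under LOOCV has 3 probes; 835 of the 2000 FR-sampled networks and 155 of
the 200 holdout bags passed the 90% acceptance floor. The head of
`results/demo/posterior_fisher_ratio.tsv`:

```
probe_id   frequency  fisher_ratio  direction
P000303    0.806      3.232         over
P000110    0.756      2.587         over
P000075    0.497      1.831         over
P000213    0.413      1.585         over
P000256    0.327      1.141         over
```

The five top-frequency probes are exactly the five planted ones (recorded
in `ground_truth.json`), each flagged over-expressed in the case class, and
`agreement.json` shows the two samplers agree on the gene ranking
(top-10 Jaccard 0.67, Spearman ρ 0.85 on this run). With a `--gmt` file
the run also writes `enrichment_*.tsv` ORA tables per direction.

Each subcommand (`simulate`, `rank`, `min-signature`, `fr-sample`,
`holdout-sample`, `consensus`, `enrich`) is also available standalone;
all artifacts are tab-separated text plus a JSON run manifest, and every
run is byte-reproducible from its seed.

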