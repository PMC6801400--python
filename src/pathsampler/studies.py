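"""Standard validation studies: planted-probe recovery and null calibration.

These procedures define the synthetic study conditions under which the
samplers are expected to work, and are what the package's own acceptance
checks execute:

* the *recovery design* — 20 samples per class, 500 probes, 5 planted
  probes with a moderate shift (delta = 2, sigma = 1, population Fisher's
  ratio 2): a sampler passes a replicate when every planted probe lands in
  the top 10 posterior frequencies;
* the *null design* — the same cohort with nothing planted and permuted
  labels: the observed maximum posterior frequency is compared against the
  distribution of per-permutation maxima (a max-statistic permutation
  calibration), so a sampler is flagged only when it produces a hot gene
  that re-permutation cannot explain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fr_sampler import FrSamplerConfig, run_fr_sampler
from .holdout import HoldoutConfig, run_holdout_sampler
from .io import ExpressionDataset
from .posterior import PosteriorSummary
from .synthetic import SyntheticSpec, generate_two_class_dataset

__all__ = [
    "recovery_design",
    "null_design",
    "probes_in_top",
    "fr_recovery_replicate",
    "holdout_recovery_replicate",
    "permute_labels",
    "null_max_frequencies",
]


def recovery_design(seed: int) -> SyntheticSpec:
    """The standard planted-recovery study conditions."""
    return SyntheticSpec(
        n_samples_per_class=(20, 20), n_probes=500, n_informative=5,
        effect_size=2.0, noise_sd=1.0, seed=seed,
    )


def null_design(seed: int, n_probes: int = 200) -> SyntheticSpec:
    """The nothing-planted study conditions for null calibration."""
    return SyntheticSpec(
        n_samples_per_class=(20, 20), n_probes=n_probes, n_informative=0,
        effect_size=0.0, noise_sd=1.0, seed=seed,
    )


def probes_in_top(posterior: PosteriorSummary, probes, n: int = 10) -> bool:
    """True when every probe ranks within the top ``n`` frequencies.

    A probe counts as in the top n when fewer than n probes have a
    strictly greater frequency (frequency ties do not push it out).
    """
    freqs = posterior.frequencies
    values = list(freqs.values())
    for probe in probes:
        f = freqs.get(probe, 0.0)
        if f == 0.0 and probe not in freqs:
            return False
        if sum(1 for v in values if v > f) >= n:
            return False
    return True


def fr_recovery_replicate(
    seed: int,
    n_networks: int = 2000,
    accuracy_min_pct: float = 90.0,
) -> bool:
    """One Fisher's-ratio sampler replicate of the recovery design."""
    dataset, truth = generate_two_class_dataset(recovery_design(seed))
    cfg = FrSamplerConfig(n_networks=n_networks, accuracy_min_pct=accuracy_min_pct,
                          seed=seed + 10_000)
    _, posterior, _ = run_fr_sampler(dataset, cfg)
    return probes_in_top(posterior, truth.informative_probe_ids, n=10)


def holdout_recovery_replicate(
    seed: int,
    n_bags: int = 200,
    validation_min_pct: float = 90.0,
) -> bool:
    """One holdout-sampler replicate of the recovery design."""
    dataset, truth = generate_two_class_dataset(recovery_design(seed))
    cfg = HoldoutConfig(n_bags=n_bags, validation_min_pct=validation_min_pct,
                        seed=seed + 20_000)
    _, posterior = run_holdout_sampler(dataset, cfg)
    return probes_in_top(posterior, truth.informative_probe_ids, n=10)


def permute_labels(dataset: ExpressionDataset, rng: np.random.Generator) -> ExpressionDataset:
    """Randomly permute the class labels over samples (expression untouched)."""
    permuted = rng.permutation(dataset.labels.to_numpy())
    return ExpressionDataset(
        values=dataset.values.copy(),
        labels=pd.Series(permuted, index=dataset.sample_ids),
        case_label=dataset.case_label,
        control_label=dataset.control_label,
    )


def _null_sampler_max_freq(dataset: ExpressionDataset, sampler: str, seed: int) -> float:
    if sampler == "fisher_ratio":
        cfg = FrSamplerConfig(n_networks=300, accuracy_min_pct=50.0, seed=seed)
        _, posterior, _ = run_fr_sampler(dataset, cfg)
    elif sampler == "holdout":
        cfg = HoldoutConfig(n_bags=40, validation_min_pct=50.0, seed=seed)
        _, posterior = run_holdout_sampler(dataset, cfg)
    else:  # pragma: no cover - programming error
        raise ValueError(f"unknown sampler {sampler!r}")
    return max(posterior.frequencies.values())


def null_max_frequencies(
    sampler: str,
    seed: int,
    n_permutations: int = 50,
) -> tuple[float, np.ndarray]:
    """Observed null maximum frequency and its re-permutation distribution.

    Generates a nothing-planted dataset, permutes its labels once for the
    observed run, then re-permutes ``n_permutations`` more times; each run
    uses a low acceptance floor (50%) so the null posterior is populated.
    Returns ``(observed_max, per_permutation_maxima)``.
    """
    dataset, _ = generate_two_class_dataset(null_design(seed))
    rng = np.random.default_rng(seed + 1)
    observed = _null_sampler_max_freq(
        permute_labels(dataset, rng), sampler, seed + 2)
    maxima = np.array([
        _null_sampler_max_freq(permute_labels(dataset, rng), sampler, seed + 3 + b)
        for b in range(n_permutations)
    ])
    return observed, maxima
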