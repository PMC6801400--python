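"""The holdout sampler.

Random 75/25 learn/validate partitions ("bags") are drawn repeatedly.
Within each bag, probes are ranked and the minimal signature is selected
on the learning fold only (LOOCV within the fold), then scored blind on
the validation fold; bags whose validation accuracy reaches the threshold
are kept, and posterior sampling frequencies are tallied over the kept
signatures.  The spread of signatures across bags measures how stable the
gene selection is under resampling of the cohort.

Splits are stratified by class by default: with cohorts of a few dozen
samples an unstratified 25% fold can easily lose a class entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import math

import numpy as np

from .errors import EmptyAcceptanceError, ValidationError
from .fisher import rank_genes, select_differentially_expressed
from .io import ExpressionDataset
from .knn import holdout_accuracy
from .posterior import PosteriorSummary, posterior_frequencies
from .signature import Signature, minimal_signature

__all__ = ["HoldoutConfig", "HoldoutBag", "generate_bags", "run_holdout_sampler"]


@dataclass(frozen=True)
class HoldoutConfig:
    """Knobs of one holdout-sampler run.

    ``validation_min_pct`` plays the same role as the Fisher sampler's
    acceptance floor, applied to blind-validation accuracy.
    """

    n_bags: int = 1000
    train_fraction: float = 0.75
    validation_min_pct: float = 90.0
    k: int = 1
    seed: int = 0
    stratified: bool = True
    de_mode: str = "fr_threshold"
    de_cutoff: float | int | None = None
    max_depth: int | None = None

    def validate(self) -> None:
        if self.n_bags < 1:
            raise ValidationError("n_bags must be positive")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must lie in (0, 1)")
        if not (0.0 <= self.validation_min_pct <= 100.0):
            raise ValidationError("validation_min_pct must lie in [0, 100]")
        if self.k < 1 or self.k % 2 == 0:
            raise ValidationError("k must be a positive odd integer")


@dataclass(frozen=True)
class HoldoutBag:
    """One learn/validate partition with its per-bag signature and outcome."""

    bag_id: int
    train_sample_ids: tuple[str, ...]
    validation_sample_ids: tuple[str, ...]
    signature: Signature | None = None
    validation_accuracy_pct: float | None = None
    accepted: bool | None = None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _split_counts(class_sizes: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-class training counts: round(fraction * n_class), then adjust +/-1
    (largest-remainder first) so the total equals round(fraction * n)."""
    total = sum(class_sizes.values())
    target = _round_half_up(fraction * total)
    counts = {c: _round_half_up(fraction * n) for c, n in class_sizes.items()}
    remainders = {c: fraction * n - math.floor(fraction * n) for c, n in class_sizes.items()}
    diff = target - sum(counts.values())
    order = sorted(class_sizes, key=lambda c: (-remainders[c], c))
    i = 0
    while diff != 0 and i < 10 * len(order):
        c = order[i % len(order)]
        counts[c] += 1 if diff > 0 else -1
        diff = target - sum(counts.values())
        i += 1
    return counts


def generate_bags(
    dataset: ExpressionDataset,
    n_bags: int,
    train_fraction: float = 0.75,
    stratified: bool = True,
    seed: int = 0,
) -> list[HoldoutBag]:
    """Draw ``n_bags`` independent random partitions (splits only).

    Stratified splits fix per-class training counts by the rounding rule
    above; unstratified splits draw round(fraction * n) samples from the
    pooled cohort.  Every class must keep >= 2 training and >= 1
    validation samples.
    """
    if n_bags < 1:
        raise ValidationError("n_bags must be positive")
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    samples = dataset.sample_ids
    by_class = {
        cls: [s for s in samples if dataset.labels[s] == cls]
        for cls in (dataset.case_label, dataset.control_label)
    }
    class_sizes = {c: len(v) for c, v in by_class.items()}
    counts = _split_counts(class_sizes, train_fraction)
    for cls, n_cls in class_sizes.items():
        n_train = counts[cls]
        if n_train < 2 or n_cls - n_train < 1:
            raise ValidationError(
                f"class {cls!r} ({n_cls} samples) cannot supply >=2 training and "
                f">=1 validation samples at train_fraction={train_fraction}"
            )

    bags = []
    n_train_total = sum(counts.values())
    for bag_id in range(n_bags):
        if stratified:
            train: list[str] = []
            for cls in (dataset.case_label, dataset.control_label):
                members = by_class[cls]
                idx = rng.choice(len(members), size=counts[cls], replace=False)
                train.extend(members[i] for i in np.sort(idx))
        else:
            idx = rng.choice(len(samples), size=n_train_total, replace=False)
            train = [samples[i] for i in np.sort(idx)]
        train_set = set(train)
        validation = [s for s in samples if s not in train_set]
        bags.append(HoldoutBag(
            bag_id=bag_id,
            train_sample_ids=tuple(train),
            validation_sample_ids=tuple(validation),
        ))
    return bags


def run_holdout_sampler(
    dataset: ExpressionDataset,
    config: HoldoutConfig,
) -> tuple[list[HoldoutBag], PosteriorSummary]:
    """Full holdout-sampling pipeline on one dataset.

    Per bag: rank probes on the learning fold, preselect the candidate
    pool, find the minimal training-fold signature, score it blind on the
    validation fold, accept when accuracy >= ``validation_min_pct``.
    Raises :class:`EmptyAcceptanceError` when no bag is accepted.
    """
    config.validate()
    dataset.require_class_minimum(2)
    splits = generate_bags(
        dataset, config.n_bags, config.train_fraction,
        stratified=config.stratified, seed=config.seed,
    )
    bags: list[HoldoutBag] = []
    accepted_sets: list[frozenset[str]] = []
    for bag in splits:
        train = dataset.subset_samples(bag.train_sample_ids)
        validation = dataset.subset_samples(bag.validation_sample_ids)
        scores = rank_genes(train)
        pool = select_differentially_expressed(scores, config.de_mode, config.de_cutoff)
        max_depth = config.max_depth
        if max_depth is None:
            max_depth = min(len(pool), 100)
        sig, _ = minimal_signature(train, pool, max_depth=max_depth, k=config.k)
        result = holdout_accuracy(train, validation, sig.probe_ids, k=config.k)
        accepted = result.accuracy_pct >= config.validation_min_pct
        bags.append(replace(
            bag,
            signature=sig,
            validation_accuracy_pct=result.accuracy_pct,
            accepted=accepted,
        ))
        if accepted:
            accepted_sets.append(frozenset(sig.probe_ids))

    if not accepted_sets:
        raise EmptyAcceptanceError(
            f"none of the {config.n_bags} bags reached {config.validation_min_pct}% "
            "validation accuracy; lower the threshold or draw more bags"
        )
    posterior = posterior_frequencies(accepted_sets, sampler_tag="holdout")
    return bags, posterior
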