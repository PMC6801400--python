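"""Synthetic two-class expression datasets with planted discriminatory probes.

The generator emulates a normalized log2 expression matrix: a large
background of uninformative Gaussian probes plus a small block of
informative probes whose case-class mean is shifted upward by ``effect_size``
(log2 units).  Under this model the population Fisher's ratio of an
informative probe is ``effect_size**2 / (2 * noise_sd**2)``, which is
recorded in the returned ground truth so downstream recovery tests can
reason about separability.

Informative probes may share a latent factor (``correlation``) to mimic
co-regulated, redundant markers, and a fraction of class labels can be
flipped (``label_noise``) to mimic annotation errors.  Probe-level array
artifacts (batch effects, background correction) are deliberately not
modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionDataset

__all__ = ["SyntheticSpec", "GroundTruth", "generate_two_class_dataset", "write_ground_truth"]

#: baseline (control-class) probe means are drawn uniformly from this
#: log2-intensity range, typical of normalized microarray data
BASELINE_MEAN_RANGE = (4.0, 12.0)

CASE_LABEL = "case"
CONTROL_LABEL = "control"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``effect_size`` is the between-class mean shift delta in log2 units and
    ``noise_sd`` the within-class standard deviation sigma, so the
    population Fisher's ratio of an informative probe is
    ``delta**2 / (2 * sigma**2)``.
    """

    n_samples_per_class: tuple[int, int] = (20, 20)
    n_probes: int = 500
    n_informative: int = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    correlation: float = 0.0
    label_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        n_case, n_control = self.n_samples_per_class
        if n_case < 1 or n_control < 1:
            raise ValidationError("n_samples_per_class: both entries must be positive")
        if self.n_probes < 1:
            raise ValidationError("n_probes must be positive")
        if self.n_informative < 0:
            raise ValidationError("n_informative must be non-negative")
        if self.n_informative > self.n_probes:
            raise ValidationError("n_informative cannot exceed n_probes")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0.0 <= self.correlation < 1.0):
            raise ValidationError("correlation must lie in [0, 1)")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValidationError("label_noise must lie in [0, 0.5)")

    @property
    def theoretical_fisher_ratio(self) -> float:
        return self.effect_size**2 / (2.0 * self.noise_sd**2)


@dataclass
class GroundTruth:
    """What was planted: which probes are informative and how strongly."""

    informative_probe_ids: list[str]
    theoretical_fisher_ratio: float
    flipped_sample_ids: list[str] = field(default_factory=list)


def _probe_ids(n: int) -> list[str]:
    return [f"P{i:06d}" for i in range(1, n + 1)]


def generate_two_class_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset from ``spec``; byte-identical for identical seeds.

    The informative probes occupy random positions in the probe list (their
    identities are disclosed only through the ground truth, keeping
    downstream stages blind).  Case samples receive the +delta shift on
    informative probes; with ``correlation`` > 0 the informative block
    shares a per-sample latent factor so that any two informative probes
    have that pairwise correlation while keeping marginal variance at
    ``noise_sd**2``.
    """
    spec.validate()
    n_case, n_control = spec.n_samples_per_class
    n = n_case + n_control
    rng = np.random.default_rng(spec.seed)

    probes = _probe_ids(spec.n_probes)
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_case] = True

    baseline = rng.uniform(*BASELINE_MEAN_RANGE, size=spec.n_probes)
    informative_idx = np.sort(
        rng.choice(spec.n_probes, size=spec.n_informative, replace=False)
    )

    noise = rng.normal(0.0, 1.0, size=(spec.n_probes, n))
    if spec.correlation > 0 and spec.n_informative > 0:
        latent = rng.normal(0.0, 1.0, size=n)
        rho = spec.correlation
        noise[informative_idx, :] = (
            np.sqrt(rho) * latent[None, :]
            + np.sqrt(1.0 - rho) * noise[informative_idx, :]
        )
    values = baseline[:, None] + spec.noise_sd * noise
    if spec.n_informative > 0:
        shift = np.zeros((spec.n_informative, n))
        shift[:, is_case] = spec.effect_size
        values[informative_idx, :] += shift

    labels = np.where(is_case, CASE_LABEL, CONTROL_LABEL)
    flipped: list[str] = []
    if spec.label_noise > 0:
        n_flip = int(round(spec.label_noise * n))
        flip_idx = rng.choice(n, size=n_flip, replace=False)
        for i in flip_idx:
            labels[i] = CONTROL_LABEL if labels[i] == CASE_LABEL else CASE_LABEL
            flipped.append(samples[i])

    frame = pd.DataFrame(values, index=probes, columns=samples)
    dataset = ExpressionDataset(
        values=frame,
        labels=pd.Series(labels, index=samples),
        case_label=CASE_LABEL,
        control_label=CONTROL_LABEL,
    )
    truth = GroundTruth(
        informative_probe_ids=[probes[i] for i in informative_idx],
        theoretical_fisher_ratio=spec.theoretical_fisher_ratio,
        flipped_sample_ids=sorted(flipped),
    )
    return dataset, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """JSON sidecar next to the generated matrix/labels files."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "informative_probe_ids": truth.informative_probe_ids,
                "theoretical_fisher_ratio": truth.theoretical_fisher_ratio,
                "flipped_sample_ids": truth.flipped_sample_ids,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
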