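"""Minimal (small-scale) genetic signatures via FR-ranked prefix evaluation.

A signature is an FR-ranked prefix of the candidate probe list.  The
minimal signature is the shortest prefix attaining the maximum LOOCV
accuracy observed over prefixes of length 1..max_depth.  Restricting the
search to nested prefixes keeps the procedure deterministic and cheap;
arbitrary subsets are explored by the samplers instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .fisher import GeneScore
from .io import ExpressionDataset
from .knn import _check_k, _loocv_contrib, _loocv_predict_case

__all__ = ["Signature", "minimal_signature", "DEFAULT_MAX_DEPTH"]

#: prefixes longer than this are not scanned by default; published minimal
#: signatures in this family of methods are well below 100 genes
DEFAULT_MAX_DEPTH = 100


@dataclass(frozen=True)
class Signature:
    """An ordered probe list with the accuracy that selected it."""

    probe_ids: tuple[str, ...]
    accuracy_pct: float
    accuracy_kind: str = "loocv"

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValidationError("signature must contain at least one probe")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("signature probes must be unique")
        if not (0.0 <= self.accuracy_pct <= 100.0):
            raise ValidationError("accuracy_pct must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.probe_ids)


def loocv_prefix_profile(
    dataset: ExpressionDataset,
    ranked_probe_ids: Sequence[str],
    max_depth: int,
    k: int = 1,
) -> list[tuple[int, float]]:
    """LOOCV accuracy of every ranked prefix of length 1..max_depth.

    One shared precomputation (cumulative scaled squared differences over
    the ranked features) makes the scan linear in max_depth.
    """
    dataset.require_class_minimum(2)
    if max_depth < 1:
        raise ValidationError("max_depth must be >= 1")
    if max_depth > len(ranked_probe_ids):
        raise ValidationError(
            f"max_depth {max_depth} exceeds the {len(ranked_probe_ids)} ranked probes"
        )
    X = dataset.matrix_for(ranked_probe_ids[:max_depth])
    n = X.shape[0]
    _check_k(k, n - 1)
    y = dataset.is_case()
    cum = np.cumsum(_loocv_contrib(X), axis=2)
    profile = []
    for depth in range(1, max_depth + 1):
        pred = _loocv_predict_case(cum[:, :, depth - 1], y, k)
        n_mis = int((pred != y).sum())
        profile.append((depth, 100.0 * (1.0 - n_mis / n)))
    return profile


def minimal_signature(
    dataset: ExpressionDataset,
    ranked_scores: Sequence[GeneScore],
    max_depth: int | None = None,
    k: int = 1,
) -> tuple[Signature, list[tuple[int, float]]]:
    """Shortest FR-ranked prefix with maximal LOOCV accuracy.

    Returns the signature together with the full (length, accuracy)
    profile for diagnostics.  ``max_depth`` defaults to
    ``min(len(ranked_scores), 100)``.
    """
    if not ranked_scores:
        raise ValidationError("empty ranked score list")
    if max_depth is None:
        max_depth = min(len(ranked_scores), DEFAULT_MAX_DEPTH)
    probe_ids = [s.probe_id for s in ranked_scores]
    profile = loocv_prefix_profile(dataset, probe_ids, max_depth, k=k)
    accuracies = [acc for _, acc in profile]
    best = int(np.argmax(accuracies))  # first occurrence = shortest prefix
    signature = Signature(
        probe_ids=tuple(probe_ids[: best + 1]),
        accuracy_pct=accuracies[best],
        accuracy_kind="loocv",
    )
    return signature, profile
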