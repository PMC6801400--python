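"""Per-probe discriminatory statistics: Fisher's ratio, ranking, preselection.

The Fisher's ratio of a probe is the squared difference of class means over
the sum of (unbiased) class variances,

    FR = (mu_case - mu_control)**2 / (s2_case + s2_control),

a dimensionless two-class separability measure that is invariant under a
common affine rescaling of both groups.  Probes are ranked by FR, and a
"differentially expressed" candidate pool is carved out either as the top-n
probes or as all probes above an FR threshold (default: the 90th percentile
of the observed FR distribution; the choice of pool is a tuning knob, not a
statistical test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import ExpressionDataset

__all__ = [
    "GeneScore",
    "fisher_ratio",
    "rank_genes",
    "select_differentially_expressed",
    "expression_direction",
]

#: relative scale of the denominator guard used when ranking whole matrices
EPS_SCALE = 1e-12


@dataclass(frozen=True)
class GeneScore:
    """Class-wise summary statistics of one probe.

    ``direction`` is ``"over"`` when the case mean exceeds the control mean
    and ``"under"`` otherwise (ties count as under).
    """

    probe_id: str
    mean_case: float
    mean_control: float
    var_case: float
    var_control: float
    fisher_ratio: float
    direction: str


def fisher_ratio(
    values_case: Sequence[float],
    values_control: Sequence[float],
    eps: float = 0.0,
) -> float:
    """Fisher's ratio of two groups of observations.

    ``eps`` is an optional additive guard on the denominator for
    zero-variance groups (used by :func:`rank_genes`; the bare two-group
    form defaults to 0).  When both variances and the mean difference are
    zero the ratio is defined as 0; a zero denominator with distinct means
    yields ``inf`` — such a probe separates the classes perfectly.
    """
    x = np.asarray(values_case, dtype=float)
    y = np.asarray(values_control, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("fisher_ratio requires at least 2 values per group")
    num = (x.mean() - y.mean()) ** 2
    den = x.var(ddof=1) + y.var(ddof=1) + eps
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / den)


def _score_arrays(dataset: ExpressionDataset):
    """Vectorized class means/variances and guarded FR for every probe."""
    dataset.require_class_minimum(2)
    mat = dataset.values.to_numpy(dtype=float)
    case = dataset.is_case()
    xc = mat[:, case]
    xh = mat[:, ~case]
    mean_c = xc.mean(axis=1)
    mean_h = xh.mean(axis=1)
    var_c = xc.var(axis=1, ddof=1)
    var_h = xh.var(axis=1, ddof=1)
    # guard keeps constant probes finite and ranked last rather than crashing
    eps = EPS_SCALE * float(mat.var())
    num = (mean_c - mean_h) ** 2
    den = var_c + var_h + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        fr = np.where(den > 0, num / den, np.where(num == 0, 0.0, np.inf))
    return mean_c, mean_h, var_c, var_h, fr


def rank_genes(dataset: ExpressionDataset) -> list[GeneScore]:
    """Score every probe and sort by Fisher's ratio, highest first.

    Ties are broken by probe id (ascending) so the ranking is a
    deterministic function of the dataset.
    """
    mean_c, mean_h, var_c, var_h, fr = _score_arrays(dataset)
    probes = dataset.probe_ids
    order = sorted(range(len(probes)), key=lambda i: (-fr[i], probes[i]))
    return [
        GeneScore(
            probe_id=probes[i],
            mean_case=float(mean_c[i]),
            mean_control=float(mean_h[i]),
            var_case=float(var_c[i]),
            var_control=float(var_h[i]),
            fisher_ratio=float(fr[i]),
            direction="over" if mean_c[i] > mean_h[i] else "under",
        )
        for i in order
    ]


def select_differentially_expressed(
    scores: Sequence[GeneScore],
    mode: str = "fr_threshold",
    cutoff: float | int | None = None,
) -> list[GeneScore]:
    """Carve the candidate pool out of an FR-ranked score list.

    ``mode="top_n"`` keeps the first ``cutoff`` entries of the ranking;
    ``mode="fr_threshold"`` keeps every probe with FR >= ``cutoff``
    (default: the 90th percentile of the FR values), preserving order.
    """
    if not scores:
        raise ValidationError("empty score list")
    if mode == "top_n":
        if cutoff is None:
            raise ValidationError("top_n selection requires a cutoff (the n)")
        n = int(cutoff)
        if n < 1:
            raise ValidationError("top_n cutoff must be >= 1")
        if n > len(scores):
            raise ValidationError(
                f"top_n cutoff {n} exceeds the {len(scores)} ranked probes"
            )
        return list(scores[:n])
    if mode == "fr_threshold":
        if cutoff is None:
            cutoff = float(np.percentile([s.fisher_ratio for s in scores], 90))
        selected = [s for s in scores if s.fisher_ratio >= cutoff]
        if not selected:
            raise ValidationError(
                f"no probe reaches FR >= {cutoff}; relax the cutoff"
            )
        return selected
    raise ValidationError(f"unknown selection mode {mode!r}")


def expression_direction(score: GeneScore) -> str:
    """``"over"`` iff the case mean strictly exceeds the control mean."""
    return "over" if score.mean_case > score.mean_control else "under"
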