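"""Posterior sampling frequencies, consensus gene lists and sampler agreement.

The posterior sampling frequency of a probe is the fraction of accepted
networks/signatures that contain it — the gene-importance measure both
samplers report.  Consensus lists split the high-frequency probes by
expression direction (over/under in the case class, taken from the
full-data gene scores), ready for over-representation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sstats

from .errors import ValidationError
from .fisher import GeneScore

__all__ = [
    "PosteriorSummary",
    "posterior_frequencies",
    "consensus_gene_list",
    "compare_samplers",
    "top_probes",
]


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-probe posterior sampling frequency over accepted sets."""

    n_accepted: int
    frequencies: dict[str, float]
    sampler_tag: str

    def __post_init__(self) -> None:
        if self.n_accepted < 1:
            raise ValidationError("n_accepted must be positive")
        bad = {p: f for p, f in self.frequencies.items() if not (0.0 <= f <= 1.0)}
        if bad:
            raise ValidationError(f"frequencies outside [0, 1]: {bad}")


def posterior_frequencies(
    accepted_sets: Sequence[Iterable[str]],
    sampler_tag: str = "fisher_ratio",
) -> PosteriorSummary:
    """Exact counting of probe occurrences across accepted sets.

    Probes absent from every set are omitted (implicit frequency 0).
    """
    if len(accepted_sets) == 0:
        raise ValidationError("no accepted sets: cannot form a posterior")
    counts: dict[str, int] = {}
    for s in accepted_sets:
        for probe in set(s):
            counts[probe] = counts.get(probe, 0) + 1
    n = len(accepted_sets)
    freqs = {probe: c / n for probe, c in sorted(counts.items())}
    return PosteriorSummary(n_accepted=n, frequencies=freqs, sampler_tag=sampler_tag)


def top_probes(posterior: PosteriorSummary, n: int) -> list[str]:
    """The n highest-frequency probes (ties broken by probe id)."""
    ranked = sorted(posterior.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    return [probe for probe, _ in ranked[:n]]


def consensus_gene_list(
    posterior: PosteriorSummary,
    scores: Sequence[GeneScore],
    frequency_cutoff: float | None = None,
) -> tuple[list[str], list[str]]:
    """High-frequency probes split by expression direction.

    Probes with posterior frequency >= ``frequency_cutoff`` (default: the
    90th percentile of the nonzero frequencies) are partitioned into
    (over, under) lists by the full-data direction, each sorted by
    frequency, then Fisher's ratio, then probe id.  An empty consensus is
    reported with a warning, not an error.
    """
    if frequency_cutoff is None:
        nonzero = [f for f in posterior.frequencies.values() if f > 0]
        if not nonzero:
            warnings.warn("all posterior frequencies are zero; empty consensus")
            return [], []
        frequency_cutoff = float(np.percentile(nonzero, 90))
    if not (0.0 < frequency_cutoff <= 1.0):
        raise ValidationError("frequency_cutoff must lie in (0, 1]")
    by_probe = {s.probe_id: s for s in scores}
    chosen = [
        (probe, freq)
        for probe, freq in posterior.frequencies.items()
        if freq >= frequency_cutoff
    ]
    if not chosen:
        warnings.warn(
            f"no probe reaches posterior frequency {frequency_cutoff}; empty consensus"
        )
        return [], []
    missing = [p for p, _ in chosen if p not in by_probe]
    if missing:
        raise ValidationError(f"probes without scores: {missing[:5]}")

    def sort_key(item):
        probe, freq = item
        return (-freq, -by_probe[probe].fisher_ratio, probe)

    chosen.sort(key=sort_key)
    over = [p for p, _ in chosen if by_probe[p].direction == "over"]
    under = [p for p, _ in chosen if by_probe[p].direction == "under"]
    return over, under


def compare_samplers(
    posterior_a: PosteriorSummary,
    posterior_b: PosteriorSummary,
    top_n: int = 10,
) -> dict:
    """Agreement between two posteriors: top-n Jaccard plus rank correlation.

    The Spearman correlation is computed over the union of both top-n
    lists, treating a probe absent from one posterior as frequency 0.
    """
    if not posterior_a.frequencies or not posterior_b.frequencies:
        raise ValidationError("both posteriors must be non-empty")
    top_a = set(top_probes(posterior_a, top_n))
    top_b = set(top_probes(posterior_b, top_n))
    union = top_a | top_b
    inter = top_a & top_b
    jaccard = len(inter) / len(union) if union else 0.0
    probes = sorted(union)
    fa = [posterior_a.frequencies.get(p, 0.0) for p in probes]
    fb = [posterior_b.frequencies.get(p, 0.0) for p in probes]
    if len(probes) > 1 and np.std(fa) > 0 and np.std(fb) > 0:
        rho = float(_sstats.spearmanr(fa, fb).statistic)
    else:
        rho = float("nan")
    return {
        "top_n": top_n,
        "jaccard": jaccard,
        "n_common": len(inter),
        "spearman_rho": rho,
    }
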