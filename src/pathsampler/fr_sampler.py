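"""The Fisher's-ratio sampler.

Random gene networks are drawn from the differentially-expressed candidate
pool with per-gene inclusion probability proportional to Fisher's ratio,
scored by k-NN LOOCV, and accepted when their accuracy reaches
``accuracy_min_pct`` — i.e. when they belong to the uncertainty set of
signatures that predict the phenotype almost as well as the best one.
Posterior sampling frequencies over the accepted networks summarize which
genes the uncertainty set keeps reusing.

Network size is drawn uniformly from ``{1, ..., ceil(length_factor * l*)}``
where ``l*`` is the length of the minimal signature on the full data: the
sampler explores networks up to a few times the complexity of the best
small-scale signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyAcceptanceError, ValidationError
from .fisher import GeneScore, rank_genes, select_differentially_expressed
from .io import ExpressionDataset
from .knn import _check_k, _loocv_contrib, _loocv_predict_case
from .posterior import PosteriorSummary, posterior_frequencies
from .signature import Signature, minimal_signature

__all__ = ["FrSamplerConfig", "SampledNetwork", "draw_network", "run_fr_sampler"]


@dataclass(frozen=True)
class FrSamplerConfig:
    """Knobs of one Fisher's-ratio sampler run.

    ``accuracy_min_pct`` is the acceptance floor Accmin = 100 - Etol; the
    default of 90 (Etol = 10) and the default number of networks are
    package choices, exposed so a study can calibrate them.
    """

    n_networks: int = 1000
    accuracy_min_pct: float = 90.0
    length_factor: float = 3.0
    k: int = 1
    seed: int = 0
    de_mode: str = "fr_threshold"
    de_cutoff: float | int | None = None
    max_depth: int | None = None

    def validate(self) -> None:
        if self.n_networks < 1:
            raise ValidationError("n_networks must be positive")
        if not (0.0 < self.accuracy_min_pct <= 100.0):
            raise ValidationError("accuracy_min_pct must lie in (0, 100]")
        if self.length_factor < 1.0:
            raise ValidationError("length_factor must be >= 1")
        if self.k < 1 or self.k % 2 == 0:
            raise ValidationError("k must be a positive odd integer")


@dataclass(frozen=True)
class SampledNetwork:
    """One sampler draw: a probe set, its LOOCV accuracy and acceptance."""

    probe_ids: frozenset[str]
    accuracy_pct: float
    accepted: bool


def _weights(scores: Sequence[GeneScore]) -> np.ndarray:
    fr = np.array([s.fisher_ratio for s in scores], dtype=float)
    if np.any(fr < 0):
        raise ValidationError("negative Fisher's ratios in candidate pool")
    finite_max = fr[np.isfinite(fr)].max(initial=0.0)
    # perfectly separating probes (infinite FR) dominate but stay finite
    fr = np.where(np.isfinite(fr), fr, 10.0 * max(finite_max, 1.0))
    if fr.max() <= 0:
        raise ValidationError("all Fisher's ratios are zero; nothing to weight")
    # zero-FR probes keep a vanishing but nonzero inclusion weight
    return fr + 1e-12 * fr.max()


def _draw_indices(weights: np.ndarray, length: int, rng: np.random.Generator) -> np.ndarray:
    """Sequential weighted draws without replacement, renormalizing each step."""
    if length > weights.size:
        raise ValidationError(
            f"network length {length} exceeds the {weights.size} candidate probes"
        )
    avail = weights.astype(float).copy()
    out = np.empty(length, dtype=int)
    for t in range(length):
        p = avail / avail.sum()
        i = int(rng.choice(avail.size, p=p))
        out[t] = i
        avail[i] = 0.0
    return out


def draw_network(
    ranked_scores: Sequence[GeneScore],
    length: int,
    rng: np.random.Generator,
) -> list[str]:
    """Draw one network of ``length`` probes with inclusion weight ∝ FR."""
    if length < 1:
        raise ValidationError("network length must be >= 1")
    idx = _draw_indices(_weights(ranked_scores), length, rng)
    return [ranked_scores[i].probe_id for i in idx]


def run_fr_sampler(
    dataset: ExpressionDataset,
    config: FrSamplerConfig,
    scores: Sequence[GeneScore] | None = None,
) -> tuple[list[SampledNetwork], PosteriorSummary, Signature]:
    """Full Fisher's-ratio sampling pipeline on one dataset.

    Steps: rank probes by FR -> preselect the DE candidate pool -> find
    the minimal signature (length l*) -> draw ``n_networks`` networks of
    random size up to ``ceil(length_factor * l*)`` with FR-proportional
    weights -> score each by LOOCV -> accept those reaching
    ``accuracy_min_pct`` -> tally posterior frequencies.

    Returns the list of sampled networks (accepted and rejected), the
    posterior summary over the accepted ones, and the minimal signature.
    Raises :class:`EmptyAcceptanceError` when no network is accepted.
    """
    config.validate()
    if scores is None:
        scores = rank_genes(dataset)
    pool = select_differentially_expressed(scores, config.de_mode, config.de_cutoff)
    max_depth = config.max_depth
    if max_depth is None:
        max_depth = min(len(pool), 100)
    sig, _profile = minimal_signature(dataset, pool, max_depth=max_depth, k=config.k)

    length_max = min(int(math.ceil(config.length_factor * len(sig))), len(pool))
    length_max = max(length_max, 1)

    pool_probes = [s.probe_id for s in pool]
    weights = _weights(pool)
    X = dataset.matrix_for(pool_probes)
    n = X.shape[0]
    _check_k(config.k, n - 1)
    y = dataset.is_case()
    # shared precomputation: per-fold scaled squared differences for the
    # whole candidate pool; each network only sums its own feature slice
    contrib = _loocv_contrib(X)

    rng = np.random.default_rng(config.seed)
    networks: list[SampledNetwork] = []
    accepted_sets: list[frozenset[str]] = []
    for _ in range(config.n_networks):
        length = int(rng.integers(1, length_max + 1))
        cols = _draw_indices(weights, length, rng)
        d2 = contrib[:, :, cols].sum(axis=2)
        pred = _loocv_predict_case(d2, y, config.k)
        n_mis = int((pred != y).sum())
        acc = 100.0 * (1.0 - n_mis / n)
        accepted = acc >= config.accuracy_min_pct
        probe_set = frozenset(pool_probes[c] for c in cols)
        networks.append(SampledNetwork(probe_set, acc, accepted))
        if accepted:
            accepted_sets.append(probe_set)

    if not accepted_sets:
        raise EmptyAcceptanceError(
            f"empty Mtol sample: none of the {config.n_networks} networks reached "
            f"{config.accuracy_min_pct}% LOOCV accuracy; lower accuracy_min_pct "
            "or enlarge the candidate pool"
        )
    posterior = posterior_frequencies(accepted_sets, sampler_tag="fisher_ratio")
    return networks, posterior, sig
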