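"""Local over-representation analysis of consensus gene lists.

Given the over- and under-expressed consensus lists, each gene set in a
GMT collection is tested with the upper-tail hypergeometric probability
P(X >= overlap) against a user-supplied universe (by default: everything
the chip measured, i.e. all dataset probes after symbol mapping), and
p-values are adjusted per direction with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sstats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .fisher import GeneScore
from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeometric_ora",
    "bh_adjust",
    "enrich_directional",
    "collapse_probes_to_symbols",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation outcome for one query list."""

    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float
    significant: bool = False


def hypergeometric_ora(
    query: Iterable[str],
    target: Iterable[str],
    universe: Iterable[str],
) -> tuple[float, int, int, int, int]:
    """Upper-tail hypergeometric test of ``query`` against ``target``.

    Returns ``(p_value, overlap, set_size, query_size, universe_size)``
    where ``set_size`` counts target members inside the universe and
    ``p_value`` = P(X >= overlap) for X hypergeometric.  ``query`` must be
    a subset of the universe; target members outside it are ignored.
    """
    uni = set(universe)
    q = set(query)
    if not uni:
        raise ValidationError("empty universe")
    if not q:
        raise ValidationError("empty query")
    outside = q - uni
    if outside:
        raise ValidationError(f"query genes outside the universe: {sorted(outside)[:5]}")
    t = set(target) & uni
    k = len(q & t)
    # sf(k-1) = P(X >= k); overlap 0 gives p = 1
    p = float(_sstats.hypergeom.sf(k - 1, len(uni), len(t), len(q)))
    p = min(max(p, 0.0), 1.0)
    return p, k, len(t), len(q), len(uni)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _enrich_one_direction(
    query: Sequence[str],
    gmt: GeneSetCollection,
    universe: Iterable[str],
    q_cutoff: float,
) -> list[EnrichmentResult]:
    if not query:
        return []
    rows = []
    for name, members in gmt:
        p, k, set_size, query_size, uni_size = hypergeometric_ora(query, members, universe)
        rows.append((name, k, set_size, query_size, uni_size, p))
    qvals = bh_adjust([r[5] for r in rows])
    results = [
        EnrichmentResult(
            set_name=name, overlap=k, set_size=set_size, query_size=query_size,
            universe_size=uni_size, p_value=p, q_value=float(qv),
            significant=bool(qv <= q_cutoff),
        )
        for (name, k, set_size, query_size, uni_size, p), qv in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def enrich_directional(
    over_list: Sequence[str],
    under_list: Sequence[str],
    gmt: GeneSetCollection,
    universe: Iterable[str],
    q_cutoff: float = 0.05,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """ORA of the over- and under-expressed consensus lists, p-sorted.

    Each direction is adjusted separately; an empty query yields an empty
    table without error.
    """
    if len(gmt) == 0:
        raise ValidationError("empty gene-set collection")
    if not (0.0 < q_cutoff <= 1.0):
        raise ValidationError("q_cutoff must lie in (0, 1]")
    universe = set(universe)
    over = _enrich_one_direction(over_list, gmt, universe, q_cutoff)
    under = _enrich_one_direction(under_list, gmt, universe, q_cutoff)
    return over, under


def collapse_probes_to_symbols(
    probe_ids: Sequence[str],
    scores: Sequence[GeneScore],
    probe_to_symbol: Mapping[str, str],
) -> list[str]:
    """Map probes to gene symbols, keeping the max-FR probe per symbol.

    Probes without a mapping are dropped.  The returned symbol list keeps
    the order of the first (highest-priority) occurrence in ``probe_ids``.
    """
    fr = {s.probe_id: s.fisher_ratio for s in scores}
    best: dict[str, tuple[float, str]] = {}
    order: list[str] = []
    for probe in probe_ids:
        symbol = probe_to_symbol.get(probe)
        if symbol is None:
            continue
        score = fr.get(probe, 0.0)
        if symbol not in best:
            order.append(symbol)
            best[symbol] = (score, probe)
        elif score > best[symbol][0]:
            best[symbol] = (score, probe)
    return order
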