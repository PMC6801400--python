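"""Reading and writing of expression tables, gene sets and result artifacts.

All tabular formats are UTF-8 tab-separated text with ``.`` as the decimal
mark.  Expression matrices are stored probes-in-rows (first column holds the
probe identifier, the header row holds the sample identifiers), matching the
orientation of GEO series matrices.  Expression values are assumed to be
already normalized / log2-transformed; no preprocessing is performed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_results",
]


@dataclass
class ExpressionDataset:
    """A two-class expression study: matrix ``E`` plus observed class labels.

    Parameters
    ----------
    values
        probes x samples matrix of (log2) expression; the index holds probe
        identifiers, the columns hold sample identifiers.
    labels
        Mapping sample id -> class label, as a :class:`pandas.Series`
        indexed by sample id and aligned with ``values.columns``.
    case_label, control_label
        The two class names, with ``case_label`` designating the condition
        of interest (e.g. the disease class).
    """

    values: pd.DataFrame
    labels: pd.Series
    case_label: str
    control_label: str

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if self.case_label == self.control_label:
            raise ValidationError("case_label and control_label must differ")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        extra = [s for s in self.labels.index if s not in self.values.columns]
        if missing or extra:
            raise ValidationError(
                f"sample/label mismatch: missing labels for {missing[:5]}, "
                f"labels without samples {extra[:5]}"
            )
        self.labels = self.labels.reindex(self.values.columns)
        observed = set(self.labels.unique())
        expected = {self.case_label, self.control_label}
        # folds of a split may hold a single class; full studies are held to
        # >= 2 samples per class via require_class_minimum at the call sites
        if not observed <= expected:
            raise ValidationError(
                f"labels contain classes {sorted(observed)}, expected {sorted(expected)}"
            )
        if self.values.isna().to_numpy().any():
            n_bad = int(self.values.isna().to_numpy().sum())
            raise ValidationError(
                f"expression matrix contains {n_bad} missing value(s); imputation is out of scope"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == self.case_label]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == self.control_label]

    def is_case(self) -> np.ndarray:
        """Boolean array over samples (canonical order): True for case."""
        return (self.labels.to_numpy() == self.case_label)

    def require_class_minimum(self, n_min: int = 2) -> None:
        """Raise unless both classes have at least ``n_min`` samples."""
        for cls in (self.case_label, self.control_label):
            n = int((self.labels == cls).sum())
            if n < n_min:
                raise ValidationError(
                    f"class {cls!r} has {n} sample(s); at least {n_min} required"
                )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return ExpressionDataset(
            values=self.values.loc[:, list(sample_ids)].copy(),
            labels=self.labels.loc[list(sample_ids)].copy(),
            case_label=self.case_label,
            control_label=self.control_label,
        )

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionDataset":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise ValidationError(f"unknown probe ids: {missing[:5]}")
        return ExpressionDataset(
            values=self.values.loc[list(probe_ids), :].copy(),
            labels=self.labels.copy(),
            case_label=self.case_label,
            control_label=self.control_label,
        )

    def matrix_for(self, probe_ids: Sequence[str]) -> np.ndarray:
        """samples x probes numeric view, rows in canonical sample order."""
        return self.values.loc[list(probe_ids), :].to_numpy(dtype=float).T


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with one description per set."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_table(
    matrix_path: str | Path,
    labels_path: str | Path,
    case_label: str,
) -> ExpressionDataset:
    """Load a probes x samples TSV plus a two-column sample->class TSV.

    The sample order of the returned dataset follows the matrix header.
    Exactly two classes must be present and ``case_label`` must be one of
    them; the other becomes the control class.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    non_numeric = values.dtypes[~values.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric) > 0:
        raise ValidationError(
            "expression matrix contains non-numeric cells in columns "
            f"{list(non_numeric.index)[:5]} (no imputation in scope)"
        )
    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    if lab.shape[1] < 2:
        raise ValidationError("labels table needs two columns: sample id, class")
    lab_series = pd.Series(lab.iloc[:, 1].values, index=lab.iloc[:, 0].values)
    missing = [s for s in values.columns if s not in lab_series.index]
    if missing:
        raise ValidationError(f"samples missing from labels table: {missing}")
    lab_series = lab_series.loc[list(values.columns)]
    classes = sorted(set(lab_series))
    if len(classes) != 2:
        raise ValidationError(f"expected exactly 2 classes, found {classes}")
    if case_label not in classes:
        raise ValidationError(f"case label {case_label!r} not among classes {classes}")
    control = classes[0] if classes[1] == case_label else classes[1]
    ds = ExpressionDataset(values=values, labels=lab_series,
                           case_label=case_label, control_label=control)
    ds.require_class_minimum(2)
    return ds


def write_expression_table(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Write the matrix and labels in the dialect :func:`read_expression_table` reads."""
    out = dataset.values.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t")
    lab = pd.DataFrame({"sample_id": dataset.sample_ids,
                        "class": [dataset.labels[s] for s in dataset.sample_ids]})
    lab.to_csv(labels_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are collapsed; blank lines are skipped.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r} at line {lineno}")
            if not members:
                raise ValidationError(f"{path}: line {lineno} defines an empty set")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

RANKED_SCORE_COLUMNS = [
    "probe_id", "mean_case", "mean_control", "var_case", "var_control",
    "fisher_ratio", "direction",
]
SIGNATURE_COLUMNS = ["signature_id", "accuracy_kind", "accuracy_pct", "n_probes", "probe_ids"]
POSTERIOR_COLUMNS = ["probe_id", "frequency", "fisher_ratio", "direction"]
ENRICHMENT_COLUMNS = [
    "set", "overlap", "set_size", "query_size", "universe", "p", "q",
    "direction", "significant",
]


def scores_frame(scores) -> pd.DataFrame:
    """Ranked per-probe statistics as a DataFrame with fixed column order."""
    rows = [
        (s.probe_id, s.mean_case, s.mean_control, s.var_case, s.var_control,
         s.fisher_ratio, s.direction)
        for s in scores
    ]
    return pd.DataFrame(rows, columns=RANKED_SCORE_COLUMNS)


def posterior_frame(posterior, scores=None) -> pd.DataFrame:
    """Posterior sampling frequencies, highest first, annotated with FR/direction."""
    by_probe = {s.probe_id: s for s in scores} if scores is not None else {}
    items = sorted(posterior.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = []
    for probe, freq in items:
        sc = by_probe.get(probe)
        rows.append((probe, freq,
                     sc.fisher_ratio if sc is not None else np.nan,
                     sc.direction if sc is not None else ""))
    return pd.DataFrame(rows, columns=POSTERIOR_COLUMNS)


def enrichment_frame(over_results, under_results) -> pd.DataFrame:
    rows = []
    for direction, results in (("over", over_results), ("under", under_results)):
        for r in results:
            rows.append((r.set_name, r.overlap, r.set_size, r.query_size,
                         r.universe_size, r.p_value, r.q_value, direction,
                         int(r.significant)))
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


def write_results(
    run_dir: str | Path,
    ranked_scores=None,
    signatures: Mapping[str, object] | None = None,
    posteriors: Iterable[tuple[object, object]] | None = None,
    enrichment_tables: Mapping[str, tuple[list, list]] | None = None,
    manifest: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write the standard TSV artifacts plus a JSON run manifest.

    ``signatures`` maps a signature id to a Signature; ``posteriors`` yields
    ``(PosteriorSummary, ranked_scores_for_annotation)`` pairs;
    ``enrichment_tables`` maps a tag to ``(over_results, under_results)``.
    Returns the paths written, keyed by artifact name.
    """
    run_dir = Path(run_dir)
    try:
        run_dir.mkdir(parents=True, exist_ok=True)
        probe = run_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"run directory {run_dir} is not writable: {exc}") from exc

    paths: dict[str, Path] = {}
    if ranked_scores is not None:
        p = run_dir / "ranked_scores.tsv"
        scores_frame(ranked_scores).to_csv(p, sep="\t", index=False)
        paths["ranked_scores"] = p
    if signatures:
        rows = [
            (sig_id, sig.accuracy_kind, sig.accuracy_pct, len(sig.probe_ids),
             ",".join(sig.probe_ids))
            for sig_id, sig in signatures.items()
        ]
        p = run_dir / "signatures.tsv"
        pd.DataFrame(rows, columns=SIGNATURE_COLUMNS).to_csv(p, sep="\t", index=False)
        paths["signatures"] = p
    if posteriors:
        for posterior, scores in posteriors:
            p = run_dir / f"posterior_{posterior.sampler_tag}.tsv"
            posterior_frame(posterior, scores).to_csv(p, sep="\t", index=False)
            paths[f"posterior_{posterior.sampler_tag}"] = p
    if enrichment_tables:
        for tag, (over_results, under_results) in enrichment_tables.items():
            p = run_dir / f"enrichment_{tag}.tsv"
            enrichment_frame(over_results, under_results).to_csv(p, sep="\t", index=False)
            paths[f"enrichment_{tag}"] = p
    if manifest is not None:
        p = run_dir / "run_manifest.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = p
    return paths
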