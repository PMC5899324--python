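"""Core data model and plain-text table I/O.

Everything downstream operates on four validated containers:

``CqTable``
    quantification-cycle (Cq) matrix, genes x samples.  Cq values are
    dimensionless cycle numbers; a lower Cq means a more abundant
    transcript.  Values must be finite and inside the open interval
    (0, 45) -- the usual cycling range of a qPCR run.
``SampleSheet``
    assignment of each sample to a treatment group and replicate index.
``EfficiencyTable``
    per-gene amplification efficiency E (fold amplification per cycle;
    E = 2 is perfect doubling).  Genes without an entry default to 2.0.
``ExpressionTable``
    gene x condition expression matrix on an FPKM-like scale, optionally
    carrying per-gene annotation flags and precomputed screening
    statistics (mean expression, CV, DPM).

All files are delimited text with a header row.  The delimiter is
auto-detected between tab and comma unless given explicitly.  Malformed
input raises :class:`ValidationError` with the offending coordinates;
no partially constructed table ever escapes a reader.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CQ_LOW, CQ_HIGH = 0.0, 45.0
EFFICIENCY_LOW, EFFICIENCY_HIGH = 1.5, 2.2
DEFAULT_EFFICIENCY = 2.0

#: columns of an expression file that are gene metadata, not conditions
_EXPR_META_COLUMNS = {
    "annotation": "annotated",
    "annotated": "annotated",
    "mean_expression": "mean_expression",
    "mean_fpkm": "mean_expression",
    "mv_fpkm": "mean_expression",
    "cv": "cv",
    "dpm": "dpm",
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_identifiers(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i).strip() for i in ids)
    if any(i == "" or i.lower() == "nan" for i in ids):
        raise ValidationError(f"empty {what} identifier found")
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass(frozen=True)
class CqTable:
    """Complete matrix of quantification-cycle values, genes x samples."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        genes = _check_identifiers(self.genes, "gene")
        samples = _check_identifiers(self.samples, "sample")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"Cq matrix shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        bad = ~np.isfinite(values)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"missing or non-numeric Cq for gene {genes[g]!r}, sample {samples[s]!r}"
            )
        out = (values <= CQ_LOW) | (values >= CQ_HIGH)
        if out.any():
            g, s = np.argwhere(out)[0]
            raise ValidationError(
                f"Cq {values[g, s]} for gene {genes[g]!r}, sample {samples[s]!r} "
                f"outside the open interval ({CQ_LOW:g}, {CQ_HIGH:g})"
            )
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def subset_genes(self, genes: Sequence[str]) -> "CqTable":
        idx = [self.genes.index(g) for g in genes]
        return CqTable(tuple(genes), self.samples, self.values[idx])

    def subset_samples(self, samples: Sequence[str]) -> "CqTable":
        idx = [self.samples.index(s) for s in samples]
        return CqTable(self.genes, tuple(samples), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.samples))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CqTable":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)),
                   frame.to_numpy(dtype=float, na_value=np.nan))


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-group assignment with replicate indices."""

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        sample_ids = _check_identifiers(self.sample_ids, "sample")
        groups = tuple(str(g).strip() for g in self.groups)
        if len(groups) != len(sample_ids) or len(self.replicates) != len(sample_ids):
            raise ValidationError("sample sheet columns have unequal lengths")
        if any(g == "" or g.lower() == "nan" for g in groups):
            raise ValidationError("empty group label in sample sheet")
        replicates = tuple(int(r) for r in self.replicates)
        if any(r < 1 for r in replicates):
            raise ValidationError("replicate indices must be positive integers")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "replicates", replicates)

    @property
    def group_names(self) -> tuple[str, ...]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return tuple(seen)

    def group_of(self, sample: str) -> str:
        try:
            return self.groups[self.sample_ids.index(sample)]
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def samples_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in zip(self.sample_ids, self.groups) if g == group)

    def require_min_group_size(self, n: int) -> None:
        for g in self.group_names:
            if len(self.samples_in_group(g)) < n:
                raise ValidationError(
                    f"group {g!r} has fewer than {n} samples; "
                    "grouped analyses need at least 2 per group "
                    "(use single-group mode otherwise)"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.groups, "replicate": self.replicates}
        )


@dataclass(frozen=True)
class EfficiencyTable:
    """Per-gene amplification efficiencies; genes not listed default to 2.0."""

    efficiencies: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        eff = {str(g): float(e) for g, e in dict(self.efficiencies).items()}
        for gene, e in eff.items():
            if not (EFFICIENCY_LOW <= e <= EFFICIENCY_HIGH):
                raise ValidationError(
                    f"efficiency {e} for gene {gene!r} outside "
                    f"[{EFFICIENCY_LOW}, {EFFICIENCY_HIGH}]"
                )
        object.__setattr__(self, "efficiencies", eff)

    def of(self, gene: str) -> float:
        return self.efficiencies.get(gene, DEFAULT_EFFICIENCY)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.efficiencies), "efficiency": list(self.efficiencies.values())}
        )


@dataclass(frozen=True)
class ExpressionTable:
    """Gene x condition expression matrix (FPKM-like scale).

    ``annotated`` marks genes with a credible functional annotation.
    ``mean_expression`` / ``cv`` / ``dpm`` hold precomputed screening
    statistics when the source table carried them; screening uses these
    verbatim instead of recomputing from the condition values.  A DPM
    reported only as exceeding a bound (e.g. "> 0.3") is stored as
    ``inf`` so threshold filters still behave correctly.
    """

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    values: np.ndarray
    annotated: tuple[bool, ...] | None = None
    mean_expression: tuple[float, ...] | None = None
    cv: tuple[float, ...] | None = None
    dpm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        genes = _check_identifiers(self.genes, "gene")
        conditions = _check_identifiers(self.conditions, "condition") if self.conditions else ()
        values = np.asarray(self.values, dtype=float).reshape(len(genes), len(conditions))
        if np.isnan(values).any():
            g, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing expression value for gene {genes[g]!r}, condition {conditions[c]!r}"
            )
        if (values < 0).any():
            g, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression {values[g, c]} for gene {genes[g]!r}, "
                f"condition {conditions[c]!r}"
            )
        values = values.copy()
        values.setflags(write=False)
        for name in ("annotated", "mean_expression", "cv", "dpm"):
            col = getattr(self, name)
            if col is not None and len(col) != len(genes):
                raise ValidationError(f"{name} column length does not match gene count")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "conditions", conditions)
        object.__setattr__(self, "values", values)
        if self.annotated is not None:
            object.__setattr__(self, "annotated", tuple(bool(a) for a in self.annotated))

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def value(self, gene: str, condition: str) -> float:
        try:
            c = self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}") from None
        return float(self.row(gene)[c])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=list(self.genes), columns=list(self.conditions))
        for name in ("mean_expression", "cv", "dpm"):
            col = getattr(self, name)
            if col is not None:
                frame[name] = list(col)
        if self.annotated is not None:
            frame["annotation"] = ["yes" if a else "no" for a in self.annotated]
        return frame


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and conventions shared across the pipeline.

    Defaults follow standard practice for reference-gene studies:
    candidates need mean expression above ``min_fpkm`` and dispersion at
    most ``max_dpm``; a geNorm M below 0.5 denotes stable expression; a
    pairwise variation V(n/n+1) below 0.15 means the (n+1)-th reference
    gene adds nothing; a BestKeeper SD above 1 cycle is unacceptable.
    """

    min_fpkm: float = 10.0
    max_dpm: float = 0.3
    genorm_m_cutoff: float = 0.5
    pairwise_variation_cutoff: float = 0.15
    bestkeeper_sd_cutoff: float = 1.0
    tie_rule: str = "min-rank"
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_fpkm", "max_dpm", "genorm_m_cutoff",
                     "pairwise_variation_cutoff", "bestkeeper_sd_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.tie_rule not in ("min-rank", "mid-rank"):
            raise ValidationError(f"unknown tie rule {self.tie_rule!r}")


# ---------------------------------------------------------------------------
# readers


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if head.count("\t") >= head.count(",") else ","


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = delimiter or _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep, dtype=str, index_col=None)


def read_cq_table(
    path: str | Path,
    delimiter: str | None = None,
    drop_incomplete_samples: bool = False,
) -> CqTable:
    """Read a genes x samples Cq matrix.

    First column holds gene identifiers, header row sample identifiers.
    ``drop_incomplete_samples`` removes any sample column containing a
    missing or non-numeric cell before validation (never imputes).
    """
    raw = _read_delimited(path, delimiter)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: expected gene column plus at least one sample column")
    genes = _check_identifiers(raw.iloc[:, 0].tolist(), "gene")
    samples = list(raw.columns[1:])
    values = raw.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if drop_incomplete_samples:
        keep = ~np.isnan(values).any(axis=0)
        values = values[:, keep]
        samples = [s for s, k in zip(samples, keep) if k]
        if not samples:
            raise ValidationError(f"{path}: every sample column has a missing cell")
    bad = np.argwhere(np.isnan(values))
    if len(bad):
        g, s = bad[0]
        raise ValidationError(
            f"{path}: missing or non-numeric Cq at gene {genes[g]!r}, sample {samples[s]!r}"
        )
    return CqTable(tuple(genes), tuple(samples), values)


def read_sample_sheet(path: str | Path, delimiter: str | None = None) -> SampleSheet:
    """Read a sample sheet with columns sample_id, group, replicate."""
    raw = _read_delimited(path, delimiter)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = {"sample_id", "group", "replicate"} - set(raw.columns)
    if missing:
        raise ValidationError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    try:
        reps = [int(r) for r in raw["replicate"]]
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-integer replicate index ({exc})") from None
    return SampleSheet(tuple(raw["sample_id"]), tuple(raw["group"]), tuple(reps))


def read_efficiency_table(path: str | Path, delimiter: str | None = None) -> EfficiencyTable:
    """Read per-gene amplification efficiencies (columns gene, efficiency)."""
    raw = _read_delimited(path, delimiter)
    raw.columns = [c.strip().lower() for c in raw.columns]
    if "gene" not in raw.columns or "efficiency" not in raw.columns:
        raise ValidationError(f"{path}: efficiency table needs columns gene, efficiency")
    genes = _check_identifiers(raw["gene"].tolist(), "gene")
    try:
        eff = [float(e) for e in raw["efficiency"]]
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric efficiency ({exc})") from None
    return EfficiencyTable(dict(zip(genes, eff)))


_CENSORED_RE = re.compile(r"^\s*>\s*([0-9.eE+-]+)\s*$")


def _parse_stat_cell(cell: str, what: str, gene: str) -> float:
    """Parse a numeric screening statistic; '> x' censored entries become inf."""
    if _CENSORED_RE.match(cell):
        return math.inf
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(f"non-numeric {what} value {cell!r} for gene {gene!r}") from None


def read_expression_table(path: str | Path, delimiter: str | None = None) -> ExpressionTable:
    """Read a gene x condition expression matrix.

    Columns named annotation/annotated, mean_expression (or mean_fpkm /
    mv_fpkm), cv and dpm (case-insensitive) are treated as per-gene
    metadata; all remaining columns after the gene column are conditions.
    """
    raw = _read_delimited(path, delimiter)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: expected gene column plus data columns")
    genes = _check_identifiers(raw.iloc[:, 0].tolist(), "gene")
    meta: dict[str, list] = {}
    cond_cols: list[str] = []
    for col in raw.columns[1:]:
        key = _EXPR_META_COLUMNS.get(col.strip().lower())
        if key == "annotated":
            meta["annotated"] = [
                str(v).strip().lower() in ("1", "true", "yes", "y") for v in raw[col]
            ]
        elif key is not None:
            meta[key] = [
                _parse_stat_cell(str(v), key, genes[i]) for i, v in enumerate(raw[col])
            ]
        else:
            cond_cols.append(col)
    values = raw[cond_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return ExpressionTable(
        genes=tuple(genes),
        conditions=tuple(cond_cols),
        values=values.reshape(len(genes), len(cond_cols)),
        annotated=tuple(meta["annotated"]) if "annotated" in meta else None,
        mean_expression=tuple(meta["mean_expression"]) if "mean_expression" in meta else None,
        cv=tuple(meta["cv"]) if "cv" in meta else None,
        dpm=tuple(meta["dpm"]) if "dpm" in meta else None,
    )


# ---------------------------------------------------------------------------
# writers


def write_cq_table(table: CqTable, path: str | Path, delimiter: str = "\t") -> None:
    frame = table.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep=delimiter)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, delimiter: str = "\t") -> None:
    sheet.to_frame().to_csv(path, sep=delimiter, index=False)


def write_efficiency_table(eff: EfficiencyTable, path: str | Path, delimiter: str = "\t") -> None:
    eff.to_frame().to_csv(path, sep=delimiter, index=False)


def write_expression_table(expr: ExpressionTable, path: str | Path, delimiter: str = "\t") -> None:
    frame = expr.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep=delimiter)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj, key=str) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in seq]
    return obj


def write_report(results, path: str | Path, format: str = "tabular") -> None:
    """Serialize a pipeline result deterministically.

    ``tabular`` writes a tab-delimited table via the result's
    ``to_frame`` method; ``structured`` writes JSON.  Numeric fields are
    written with full (shortest round-tripping) precision, so re-reading
    reproduces them exactly; writing the same result twice yields
    byte-identical files.
    """
    path = Path(path)
    if format == "tabular":
        if not hasattr(results, "to_frame"):
            raise ValidationError(
                f"{type(results).__name__} has no tabular form; use format='structured'"
            )
        frame = results.to_frame()
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif format == "structured":
        payload = _jsonable(results)
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")
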