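"""Transcriptome screen for candidate reference genes.

Candidates are mined from a gene x condition expression matrix by three
filters: a credible functional annotation, a mean expression above a
floor (default FPKM > 10, so the gene is reliably detectable by qPCR),
and a low dispersion across conditions (default DPM <= 0.3, inclusive).

Two dispersion statistics are reported per gene.  ``cv`` is the ordinary
sample coefficient of variation (standard deviation with the n-1
denominator over the mean).  ``dpm`` is the dispersion measure used for
the filter: here the population-denominator (n) coefficient of
variation over the per-condition values.  Both are scale-invariant and
zero for a constant profile.  Input tables may carry precomputed
mean/cv/dpm columns (e.g. transcribed from a published screen); those
are used verbatim instead of being recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from refstab.quant_io import AnalysisConfig, ExpressionTable, ValidationError


@dataclass(frozen=True)
class ScreenRecord:
    """Per-gene screening statistics and filter verdicts."""

    gene: str
    mean_expression: float
    cv: float
    dpm: float
    annotated: bool
    passes_expression: bool
    passes_dpm: bool
    passes: bool


@dataclass(frozen=True)
class ScreenResult:
    """Screen output: records sorted by dpm ascending plus filter counts."""

    records: tuple[ScreenRecord, ...]
    n_pass: int
    n_fail: int
    n_fail_expression: int
    n_fail_dpm: int
    n_fail_annotation: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "mean_expression": r.mean_expression,
                    "cv": r.cv,
                    "dpm": r.dpm,
                    "annotated": r.annotated,
                    "passes": r.passes,
                }
                for r in self.records
            ]
        )


def summarize_expression(values) -> tuple[float, float, float]:
    """Mean expression, sample CV and dispersion (DPM) of one gene.

    ``values`` holds the per-condition abundances (length >= 2, all
    non-negative, not all zero).  Returns ``(mean, cv, dpm)`` where cv
    uses the n-1 denominator and dpm the population (n) denominator.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("need a 1-D vector of at least two condition values")
    if (x < 0).any() or not np.isfinite(x).all():
        raise ValidationError("expression values must be finite and non-negative")
    mean = float(x.mean())
    if mean == 0.0:
        raise ValidationError("all-zero expression vector: CV and DPM are undefined")
    cv = float(x.std(ddof=1)) / mean
    dpm = float(x.std(ddof=0)) / mean
    return mean, cv, dpm


def screen_candidates(expr: ExpressionTable, config: AnalysisConfig | None = None) -> ScreenResult:
    """Apply the annotation / expression-level / dispersion screen.

    Genes lacking annotation are retained with ``passes = False``, never
    dropped.  The expression filter is strict (mean > ``min_fpkm``), the
    dispersion filter inclusive (dpm <= ``max_dpm``).  Records come back
    sorted by dpm ascending, ties broken by gene identifier.
    """
    config = config or AnalysisConfig()
    has_precomputed = expr.mean_expression is not None and expr.dpm is not None
    if not has_precomputed and len(expr.conditions) < 2:
        raise ValidationError(
            "expression table has neither condition values nor precomputed statistics"
        )
    records = []
    for i, gene in enumerate(expr.genes):
        if has_precomputed:
            mean = float(expr.mean_expression[i])
            dpm = float(expr.dpm[i])
            cv = float(expr.cv[i]) if expr.cv is not None else math.nan
        else:
            mean, cv, dpm = summarize_expression(expr.values[i])
        annotated = True if expr.annotated is None else expr.annotated[i]
        p_expr = mean > config.min_fpkm
        p_dpm = dpm <= config.max_dpm
        records.append(
            ScreenRecord(
                gene=gene,
                mean_expression=mean,
                cv=cv,
                dpm=dpm,
                annotated=annotated,
                passes_expression=p_expr,
                passes_dpm=p_dpm,
                passes=annotated and p_expr and p_dpm,
            )
        )
    records.sort(key=lambda r: (r.dpm, r.gene))
    n_pass = sum(r.passes for r in records)
    return ScreenResult(
        records=tuple(records),
        n_pass=n_pass,
        n_fail=len(records) - n_pass,
        n_fail_expression=sum(not r.passes_expression for r in records),
        n_fail_dpm=sum(not r.passes_dpm for r in records),
        n_fail_annotation=sum(not r.annotated for r in records),
    )
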