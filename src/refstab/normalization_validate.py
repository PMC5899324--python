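"""Efficiency-corrected relative quantification and validation.

A normalization factor (NF) for a sample is the geometric mean of the
chosen reference genes' relative quantities; a target gene's normalized
expression is its own relative quantity divided by the NF.  With a
single reference gene and perfect doubling efficiency this reduces to
the textbook 2^(-ddCq) calculation.  Fold changes versus a control
group are ratios of group means of the normalized (linear-scale)
quantities, with a two-sided Welch t-test on log2 values for
significance.  qPCR profiles can be cross-checked against RNA-seq
(FPKM) fold changes for the same conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from refstab.quant_io import ExpressionTable, SampleSheet, ValidationError
from refstab.stability_suite import RelativeQuantityTable


@dataclass(frozen=True)
class NormalizationFactor:
    """Per-sample geometric mean of the reference genes' quantities."""

    sample: str
    nf: float
    references: tuple[str, ...]


@dataclass(frozen=True)
class FoldChangeProfile:
    """Fold change of one target in one condition versus control."""

    target: str
    condition: str
    fold_change: float
    direction: str  # "up" | "down" | "none"
    p_value: float
    source: str  # "qpcr" | "rnaseq"

    @property
    def stars(self) -> str:
        if math.isnan(self.p_value):
            return ""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


@dataclass(frozen=True)
class ConcordanceSummary:
    """Agreement between two fold-change profiles (e.g. qPCR vs RNA-seq)."""

    log2_differences: dict[str, float]
    mean_abs_log2_difference: float
    direction_agreement: float


def _direction(fold_change: float) -> str:
    if fold_change > 1:
        return "up"
    if fold_change < 1:
        return "down"
    return "none"


def normalization_factor(
    q: RelativeQuantityTable, references: Sequence[str]
) -> list[NormalizationFactor]:
    """Geometric mean of the reference genes' quantities, per sample."""
    if not references:
        raise ValidationError("reference gene list is empty")
    unknown = [g for g in references if g not in q.genes]
    if unknown:
        raise ValidationError(f"unknown reference gene(s): {unknown}")
    rows = np.stack([q.row(g) for g in references])
    nf = np.exp(np.log(rows).mean(axis=0))
    refs = tuple(references)
    return [NormalizationFactor(sample=s, nf=float(v), references=refs)
            for s, v in zip(q.samples, nf)]


def relative_expression(
    q: RelativeQuantityTable,
    target: str,
    nfs: Sequence[NormalizationFactor],
) -> dict[str, float]:
    """Per-sample normalized expression: Q(target, s) / NF(s)."""
    if target not in q.genes:
        raise ValidationError(f"unknown target gene {target!r}")
    by_sample = {nf.sample: nf.nf for nf in nfs}
    missing = [s for s in q.samples if s not in by_sample]
    if missing:
        raise ValidationError(f"no normalization factor for sample(s): {missing}")
    row = q.row(target)
    return {s: float(v / by_sample[s]) for s, v in zip(q.samples, row)}


def fold_change_vs_control(
    values: Mapping[str, float],
    sheet: SampleSheet,
    control: str,
    target: str = "target",
) -> list[FoldChangeProfile]:
    """Group fold changes of normalized expression versus a control group.

    Fold change is the ratio of arithmetic group means on the linear
    scale; the p-value comes from a two-sided Welch t-test on log2
    values (NaN when a group has no spread to test against).  The
    control group itself is reported with fold change 1.
    """
    if control not in sheet.group_names:
        raise ValidationError(f"control group {control!r} not in sample sheet")
    control_samples = sheet.samples_in_group(control)
    if len(control_samples) < 2:
        raise ValidationError("control group needs at least 2 samples")
    missing = [s for s in sheet.sample_ids if s not in values]
    if missing:
        raise ValidationError(f"no expression value for sample(s): {missing}")
    ctrl = np.array([values[s] for s in control_samples], dtype=float)
    profiles = [
        FoldChangeProfile(target=target, condition=control, fold_change=1.0,
                          direction="none", p_value=math.nan, source="qpcr")
    ]
    for group in sheet.group_names:
        if group == control:
            continue
        x = np.array([values[s] for s in sheet.samples_in_group(group)], dtype=float)
        fc = float(x.mean() / ctrl.mean())
        if len(x) >= 2 and (np.ptp(np.log2(x)) > 0 or np.ptp(np.log2(ctrl)) > 0):
            _, p = stats.ttest_ind(np.log2(x), np.log2(ctrl), equal_var=False)
            p = float(p)
        else:
            p = math.nan
        profiles.append(
            FoldChangeProfile(target=target, condition=group, fold_change=fc,
                              direction=_direction(fc), p_value=p, source="qpcr")
        )
    return profiles


def rnaseq_fold_change(
    expr: ExpressionTable, target: str, control: str
) -> list[FoldChangeProfile]:
    """Condition-level FPKM ratios versus a control condition."""
    if target not in expr.genes:
        raise ValidationError(f"unknown target gene {target!r}")
    if control not in expr.conditions:
        raise ValidationError(f"unknown control condition {control!r}")
    base = expr.value(target, control)
    if base == 0:
        raise ValidationError(f"control FPKM for {target!r} is zero; fold change undefined")
    profiles = []
    for condition in expr.conditions:
        fc = expr.value(target, condition) / base
        profiles.append(
            FoldChangeProfile(
                target=target, condition=condition, fold_change=float(fc),
                direction="none" if condition == control else _direction(fc),
                p_value=math.nan, source="rnaseq",
            )
        )
    return profiles


def compare_profiles(
    a: Sequence[FoldChangeProfile], b: Sequence[FoldChangeProfile]
) -> ConcordanceSummary:
    """Condition-wise concordance of two fold-change profiles.

    Conditions where both profiles have fold change 1 by construction
    (the shared control) contribute a zero difference.  Direction
    agreement counts conditions where both profiles move the same way.
    """
    a_by = {p.condition: p for p in a}
    b_by = {p.condition: p for p in b}
    if set(a_by) != set(b_by):
        raise ValidationError(
            f"condition mismatch: {sorted(set(a_by) ^ set(b_by))}"
        )
    diffs: dict[str, float] = {}
    agree = 0
    compared = 0
    for cond in a_by:
        fa, fb = a_by[cond].fold_change, b_by[cond].fold_change
        diffs[cond] = math.log2(fa) - math.log2(fb)
        da, db = _direction(fa), _direction(fb)
        if da == "none" and db == "none":
            continue
        compared += 1
        if da == db:
            agree += 1
    return ConcordanceSummary(
        log2_differences=diffs,
        mean_abs_log2_difference=float(np.mean([abs(d) for d in diffs.values()])),
        direction_agreement=(agree / compared) if compared else 1.0,
    )


def fold_change_table(profiles: Sequence[FoldChangeProfile]) -> pd.DataFrame:
    """Tabular form of a list of fold-change profiles."""
    return pd.DataFrame(
        [
            {
                "target": p.target,
                "condition": p.condition,
                "fold_change": p.fold_change,
                "direction": p.direction,
                "p_value": p.p_value,
                "significance": p.stars,
                "source": p.source,
            }
            for p in profiles
        ]
    )
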