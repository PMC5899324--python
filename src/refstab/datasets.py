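"""Bundled example dataset: nine candidate reference genes of the red
alga *Pyropia yezoensis* assayed under abiotic stress.

The data cover a transcriptome-derived screening summary (per-gene mean
FPKM, CV and dispersion measure), per-gene qPCR amplification
efficiencies, and the per-method stability scores and rank orders
obtained on three sample panels: ``all`` (every stress treatment),
``dehydration`` (control plus three water-loss levels and rehydration)
and ``temperature`` (control plus heat, chilling and freezing).  The
underlying raw Cq matrix is not distributed; the scores and rank orders
are inputs for the consensus and screening stages and for worked
examples.

Three DPM entries are known only to exceed 0.3 and are stored as
``inf`` (see :mod:`refstab.quant_io`).
"""

from __future__ import annotations

import math

from refstab.consensus_rank import MethodRanking, ranking_from_order
from refstab.quant_io import EfficiencyTable, ExpressionTable

PANELS = ("all", "dehydration", "temperature")

#: gene -> (mean FPKM, CV, DPM); inf marks "exceeds 0.3"
_SCREEN = {
    "MAP": (104.792, 0.130, 0.129),
    "ATPase": (36.383, 0.136, 0.134),
    "CGS1": (175.309, 0.166, 0.164),
    "PPK": (24.197, 0.166, 0.164),
    "DPE2": (76.424, 0.167, 0.165),
    "FHP": (83.279, 0.170, 0.168),
    "UBC": (374.296, 0.649, math.inf),
    "EF1-a": (1079.455, 0.475, math.inf),
    "eif4A": (1149.390, 0.779, math.inf),
}

_EFFICIENCIES = {
    "MAP": 1.946,
    "ATPase": 2.014,
    "CGS1": 1.947,
    "PPK": 1.98,
    "DPE2": 1.992,
    "FHP": 1.973,
    "UBC": 1.99,
    "EF1-a": 1.96,
    "eif4A": 1.951,
}

#: per-panel geNorm M at exclusion (ordered most to least stable)
_GENORM_M = {
    "all": {"MAP": 0.478, "UBC": 0.478, "FHP": 0.592, "EF1-a": 0.646, "CGS1": 0.744,
            "PPK": 0.904, "ATPase": 1.0, "eif4A": 1.111, "DPE2": 1.376},
    "dehydration": {"CGS1": 0.219, "FHP": 0.219, "PPK": 0.314, "UBC": 0.357,
                    "MAP": 0.466, "EF1-a": 0.566, "eif4A": 0.67, "DPE2": 0.79,
                    "ATPase": 0.895},
    "temperature": {"MAP": 0.485, "ATPase": 0.485, "EF1-a": 0.544, "UBC": 0.583,
                    "CGS1": 0.628, "FHP": 0.657, "PPK": 0.868, "DPE2": 1.045,
                    "eif4A": 1.188},
}

_NORMFINDER_SV = {
    "all": {"UBC": 0.254, "MAP": 0.373, "EF1-a": 0.406, "FHP": 0.408, "CGS1": 0.491,
            "PPK": 0.708, "eif4A": 0.761, "ATPase": 0.783, "DPE2": 1.246},
    "dehydration": {"UBC": 0.209, "CGS1": 0.257, "FHP": 0.315, "MAP": 0.342,
                    "EF1-a": 0.365, "PPK": 0.370, "eif4A": 0.527, "DPE2": 0.589,
                    "ATPase": 0.646},
    "temperature": {"UBC": 0.173, "MAP": 0.293, "CGS1": 0.402, "EF1-a": 0.424,
                    "ATPase": 0.476, "FHP": 0.505, "DPE2": 0.718, "PPK": 0.847,
                    "eif4A": 0.972},
}

#: gene -> (SD in cycles, CV percent), listed in the published rank order
_BESTKEEPER = {
    "all": {"MAP": (0.43, 1.68), "UBC": (0.41, 2.08), "FHP": (0.49, 2.04),
            "PPK": (0.67, 2.55), "CGS1": (0.69, 2.74), "EF1-a": (0.70, 3.34),
            "ATPase": (0.81, 3.60), "eif4A": (1.17, 5.07), "DPE2": (1.68, 6.34)},
    "dehydration": {"CGS1": (0.16, 0.63), "FHP": (0.16, 0.67), "PPK": (0.27, 1.00),
                    "UBC": (0.27, 1.39), "MAP": (0.50, 1.94), "EF1-a": (0.68, 3.28),
                    "DPE2": (0.97, 3.86), "ATPase": (0.98, 4.28), "eif4A": (0.99, 4.27)},
    "temperature": {"MAP": (0.29, 1.16), "ATPase": (0.47, 2.19), "UBC": (0.52, 2.68),
                    "CGS1": (0.74, 2.86), "PPK": (0.75, 2.93), "EF1-a": (0.69, 3.28),
                    "FHP": (0.88, 3.71), "DPE2": (1.30, 4.57), "eif4A": (1.53, 6.69)},
}

_DELTACT_MEAN_SD = {
    "all": {"UBC": 0.948, "MAP": 1.009, "FHP": 1.048, "EF1-a": 1.079, "CGS1": 1.190,
            "ATPase": 1.347, "eif4A": 1.435, "PPK": 1.495, "DPE2": 2.338},
    "dehydration": {"UBC": 0.573, "CGS1": 0.596, "FHP": 0.666, "MAP": 0.680,
                    "PPK": 0.739, "EF1-a": 0.799, "eif4A": 0.852, "ATPase": 1.050,
                    "DPE2": 1.073},
    "temperature": {"UBC": 0.885, "MAP": 0.886, "ATPase": 0.920, "EF1-a": 0.935,
                    "CGS1": 0.945, "FHP": 1.019, "DPE2": 1.636, "PPK": 1.681,
                    "eif4A": 1.702},
}

#: per-panel published rank orders; "A/B" marks a tied pair
_RANK_ORDERS = {
    "all": {
        "genorm": ["MAP/UBC", "FHP", "EF1-a", "CGS1", "PPK", "ATPase", "eif4A", "DPE2"],
        "normfinder": ["UBC", "MAP", "EF1-a", "FHP", "CGS1", "PPK", "eif4A", "ATPase", "DPE2"],
        "bestkeeper": ["MAP", "UBC", "FHP", "PPK", "CGS1", "EF1-a", "ATPase", "eif4A", "DPE2"],
        "deltact": ["UBC", "MAP", "FHP", "EF1-a", "CGS1", "ATPase", "eif4A", "PPK", "DPE2"],
    },
    "dehydration": {
        "genorm": ["CGS1/FHP", "PPK", "UBC", "MAP", "EF1-a", "eif4A", "DPE2", "ATPase"],
        "normfinder": ["UBC", "CGS1", "FHP", "MAP", "EF1-a", "PPK", "eif4A", "DPE2", "ATPase"],
        "bestkeeper": ["CGS1", "FHP", "PPK", "UBC", "MAP", "EF1-a", "DPE2", "ATPase", "eif4A"],
        "deltact": ["UBC", "CGS1", "FHP", "MAP", "PPK", "EF1-a", "eif4A", "ATPase", "DPE2"],
    },
    "temperature": {
        "genorm": ["MAP/ATPase", "EF1-a", "UBC", "CGS1", "FHP", "PPK", "DPE2", "eif4A"],
        "normfinder": ["UBC", "MAP", "CGS1", "EF1-a", "ATPase", "FHP", "DPE2", "PPK", "eif4A"],
        "bestkeeper": ["MAP", "ATPase", "UBC", "CGS1", "PPK", "EF1-a", "FHP", "DPE2", "eif4A"],
        "deltact": ["UBC", "MAP", "ATPase", "EF1-a", "CGS1", "FHP", "DPE2", "PPK", "eif4A"],
    },
}

#: published comprehensive (consensus) orders per panel
_COMPREHENSIVE = {
    "all": ("UBC", "MAP", "FHP", "EF1-a", "CGS1", "PPK", "ATPase", "eif4A", "DPE2"),
    "dehydration": ("CGS1", "UBC", "FHP", "PPK", "MAP", "EF1-a", "eif4A", "DPE2", "ATPase"),
    "temperature": ("MAP", "UBC", "CGS1", "ATPase", "EF1-a", "FHP", "PPK", "DPE2", "eif4A"),
}

#: fold-change series of the two stress-responsive validation targets.
#: conditions are ordered mild -> severe; values are condition / control
#: ratios under the best and worst reference-gene sets, plus RNA-seq.
FOLD_CHANGES = {
    "PyOLE-1": {
        "conditions": ("24C", "0C", "-8C"),
        "qpcr_best": (1.50, 4.05, 10.28),
        "qpcr_worst": (5.97, 18.78, 39.76),
        "rnaseq": (1.03, 4.19, 6.50),
    },
    "PyOEE-1": {
        "conditions": ("loss20", "loss50", "loss70"),
        "qpcr_best": (0.81, 0.96, 0.82),
        "qpcr_worst": (3.80, 7.72, 7.63),
        "rnaseq": (0.63, 0.60, 0.67),
    },
}

GENES = tuple(_SCREEN)


def _check_panel(panel: str) -> None:
    if panel not in PANELS:
        raise KeyError(f"unknown panel {panel!r}; choose from {PANELS}")


def example_screen_table() -> ExpressionTable:
    """Screening summary of the nine candidates (precomputed statistics)."""
    return ExpressionTable(
        genes=GENES,
        conditions=(),
        values=[[] for _ in GENES],
        annotated=tuple([True] * len(GENES)),
        mean_expression=tuple(_SCREEN[g][0] for g in GENES),
        cv=tuple(_SCREEN[g][1] for g in GENES),
        dpm=tuple(_SCREEN[g][2] for g in GENES),
    )


def example_efficiencies() -> EfficiencyTable:
    """Assay amplification efficiencies of the nine candidates."""
    return EfficiencyTable(dict(_EFFICIENCIES))


def example_method_scores(panel: str) -> dict[str, dict]:
    """Per-method stability scores for one panel.

    geNorm (M value), NormFinder (SV) and delta-Ct (mean pair SD) map
    gene -> score; BestKeeper maps gene -> (SD, CV percent).
    """
    _check_panel(panel)
    return {
        "genorm": dict(_GENORM_M[panel]),
        "normfinder": dict(_NORMFINDER_SV[panel]),
        "bestkeeper": dict(_BESTKEEPER[panel]),
        "deltact": dict(_DELTACT_MEAN_SD[panel]),
    }


def example_method_rankings(panel: str, tie_rule: str = "min-rank") -> list[MethodRanking]:
    """The four published per-method rank orders for one panel."""
    _check_panel(panel)
    return [
        ranking_from_order(method, order, tie_rule=tie_rule)
        for method, order in _RANK_ORDERS[panel].items()
    ]


def example_comprehensive_order(panel: str) -> tuple[str, ...]:
    """The published consensus (comprehensive) order for one panel."""
    _check_panel(panel)
    return _COMPREHENSIVE[panel]
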