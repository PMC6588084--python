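"""Aggregation of per-analysis calls and performance metrics.

Aggregation follows the conservative published rule: a single DDI call from
any analysis in the scheme makes the overall verdict DDI; otherwise a single
non-DDI call makes it non-DDI; only if every analysis is inconclusive is the
overall verdict inconclusive.

Performance counts an inconclusive overall verdict as an incorrect call for
the chemical's true class (a false negative for true DDI, a false positive
slot for true non-DDI), so TP+FN always equals the number of true DDI
chemicals and TN+FP the number of true non-DDI chemicals. Percentages are
reported rounded half-up to integers, with balanced accuracy computed from
the unrounded sensitivity and specificity before rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .profiles import CLASSES, DDI, INCONCLUSIVE, NON_DDI, ClassCall

#: analysis labels in canonical order
ANALYSES = ("PA", "PCA", "2-DC", "RF")

#: combination schemes -> required analyses
SCHEMES: dict[str, tuple[str, ...]] = {
    "three_pronged": ("PA", "PCA", "2-DC"),
    "rf_only": ("RF",),
    "three_pronged_plus_rf": ("PA", "PCA", "2-DC", "RF"),
    "pa_rf": ("PA", "RF"),
    "pca_rf": ("PCA", "RF"),
    "twodc_rf": ("2-DC", "RF"),
}


def _verdict(call: ClassCall | str) -> str:
    return call.verdict if isinstance(call, ClassCall) else str(call)


def aggregate_calls(
    calls: Mapping[str, ClassCall | str], scheme: str = "three_pronged"
) -> ClassCall:
    """Combine per-analysis verdicts under a scheme's one-DDI-call-wins rule.

    The returned score is the fraction of the scheme's analyses calling DDI.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}")
    required = SCHEMES[scheme]
    missing = [a for a in required if a not in calls]
    if missing:
        raise KeyError(f"scheme {scheme!r} requires analysis {missing[0]!r}")
    verdicts = [_verdict(calls[a]) for a in required]
    if DDI in verdicts:
        overall = DDI
    elif NON_DDI in verdicts:
        overall = NON_DDI
    else:
        overall = INCONCLUSIVE
    return ClassCall(
        verdict=overall,
        score=verdicts.count(DDI) / len(verdicts),
        analysis=scheme,
    )


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (87.5 -> 88)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion counts and the derived rates (percent, unrounded floats)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float

    def rounded(self) -> dict[str, int]:
        """Integer-percent report (half-up rounding, balanced accuracy from
        the unrounded components)."""
        return {
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
            "accuracy": round_half_up(self.accuracy),
            "balanced_accuracy": round_half_up(self.balanced_accuracy),
        }


def performance(
    verdicts: Mapping[str, ClassCall | str],
    truth: Mapping[str, str],
) -> PerformanceReport:
    """Score overall verdicts against known classes.

    ``verdicts`` maps chemical to an overall verdict (possibly inconclusive);
    ``truth`` maps every chemical to DDI or non-DDI.
    """
    tp = fp = tn = fn = 0
    for chem, call in verdicts.items():
        if chem not in truth:
            raise KeyError(f"no true class known for chemical {chem!r}")
        t = truth[chem]
        if t not in CLASSES:
            raise ValueError(f"invalid true class {t!r} for chemical {chem!r}")
        v = _verdict(call)
        if t == DDI:
            if v == DDI:
                tp += 1
            else:  # non-DDI or inconclusive: missed DDI
                fn += 1
        else:
            if v == NON_DDI:
                tn += 1
            else:  # DDI or inconclusive: not a correct non-DDI call
                fp += 1
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("performance needs chemicals of both true classes")
    sens = 100.0 * tp / n_pos
    spec = 100.0 * tn / n_neg
    acc = 100.0 * (tp + tn) / (n_pos + n_neg)
    return PerformanceReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=(sens + spec) / 2.0,
    )


def build_call_matrix(
    per_analysis: Mapping[str, Mapping[str, ClassCall | str]],
    truth: Mapping[str, str] | None = None,
    schemes: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Tabulate per-analysis verdicts plus aggregated verdicts per scheme.

    ``per_analysis`` maps analysis label -> {chemical -> call}. Only schemes
    whose required analyses are all present are aggregated.
    """
    analyses = [a for a in ANALYSES if a in per_analysis]
    if not analyses:
        raise ValueError("no analyses provided")
    chemicals = sorted(per_analysis[analyses[0]])
    for a in analyses:
        if sorted(per_analysis[a]) != chemicals:
            raise ValueError(f"analysis {a!r} covers a different chemical set")
    table = pd.DataFrame(
        {a: [_verdict(per_analysis[a][c]) for c in chemicals] for a in analyses},
        index=pd.Index(chemicals, name="chemical"),
    )
    for scheme, required in (schemes or SCHEMES).items():
        if all(a in per_analysis for a in required):
            table[scheme] = [
                aggregate_calls({a: per_analysis[a][c] for a in required}, scheme).verdict
                for c in chemicals
            ]
    if truth is not None:
        table["true_class"] = [truth.get(c) for c in chemicals]
    return table
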