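"""Statistical pipeline for questionnaire and time-in-sync comparisons.

The analysis follows the study design it serves: within-participant
comparisons across the three conditions (*human*, *no coupling*,
*coupling*).  Normality of each sample (or of difference scores) is
gated with Shapiro-Wilk at alpha = 0.05; normal data get a paired
Student t-test, non-normal data a Wilcoxon signed-rank test.  Effect
sizes are Cliff's delta — the normalised difference between the counts
of greater and lesser cross-sample pairs — with qualitative labels.

Because participants differ wildly in their overall tendency to hold
the synchrony button, raw time-in-sync comparisons are noisy; the
*human* condition serves as a per-participant baseline, and conditions
are compared through the difference scores ``coupling - human`` and
``no_coupling - human``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError, MirrorGameError

__all__ = [
    "StatResult",
    "PairedSample",
    "cliffs_delta",
    "effect_label",
    "compare_paired",
    "baseline_correct",
    "analyze_questionnaire",
    "analyze_sync_times",
    "EFFECT_THRESHOLDS",
    "ALPHA",
]

ALPHA = 0.05

#: |delta| thresholds for negligible / small / medium / large.
EFFECT_THRESHOLDS = (0.15, 0.33, 0.66)


@dataclass(frozen=True)
class StatResult:
    """Outcome of one statistical test."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    effect_size: Optional[float] = None
    effect_label: Optional[str] = None
    extra: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")
        if self.effect_size is not None and abs(self.effect_size) > 1:
            raise ValueError("Cliff's delta must lie in [-1, 1]")


@dataclass(frozen=True)
class PairedSample:
    """Per-participant values for two conditions, aligned by participant."""

    a: np.ndarray
    b: np.ndarray
    name_a: str = "a"
    name_b: str = "b"

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired samples must be equal-length vectors")
        if np.any(np.isnan(self.a)) or np.any(np.isnan(self.b)):
            raise ValueError("paired samples must have no missing values")

    @property
    def n(self) -> int:
        return len(self.a)

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


def cliffs_delta(a: Sequence[float], b: Sequence[float]) -> float:
    """Cliff's delta: P(a > b) - P(a < b) over all cross-sample pairs.

    Ranges over [-1, 1]; 0 means full overlap, +/-1 complete separation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    diff = a[:, None] - b[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (a.size * b.size))


def effect_label(
    delta: float, thresholds: Tuple[float, float, float] = EFFECT_THRESHOLDS
) -> str:
    """Qualitative label for a Cliff's delta magnitude.

    Default cuts 0.15 / 0.33 / 0.66 map |delta| to negligible, small,
    medium or large.  (The conventional 0.474 medium/large cut would put
    |delta| = 0.5 in "large"; these cuts keep 0.4-0.5 "medium",
    consistent with how this effect scale is used for 7-point
    questionnaire items.)
    """
    if abs(delta) > 1:
        raise ValueError("delta must lie in [-1, 1]")
    mag = abs(delta)
    t1, t2, t3 = thresholds
    if mag < t1:
        return "negligible"
    if mag < t2:
        return "small"
    if mag < t3:
        return "medium"
    return "large"


def _wilcoxon(d: np.ndarray) -> Tuple[float, float]:
    """Signed-rank test on differences: zeros dropped, normal approximation
    with continuity correction for n > 25, exact otherwise."""
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateTestError(
            "all paired differences are zero; signed-rank test undefined"
        )
    method = "approx" if nz.size > 25 else "exact"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       method=method)
    return float(res.statistic), float(res.pvalue)


def compare_paired(
    sample: PairedSample,
    force_test: Optional[str] = None,
    normality_on: str = "margins",
    alpha: float = ALPHA,
) -> StatResult:
    """Compare two paired conditions with the appropriate test.

    Shapiro-Wilk gates the choice: if normality is rejected (on either
    margin for raw condition scores, or on the paired differences for
    derived difference scores, per ``normality_on``), a Wilcoxon
    signed-rank test is used; otherwise a paired Student t-test.
    ``force_test`` ("wilcoxon" or "ttest") bypasses the gate.  Cliff's
    delta and its label are always attached.
    """
    if sample.n < 5:
        raise ValueError("need at least 5 pairs")
    d = sample.differences
    if force_test is None:
        if normality_on == "margins":
            ps = [sps.shapiro(sample.a).pvalue, sps.shapiro(sample.b).pvalue]
        elif normality_on == "differences":
            if np.ptp(d) == 0:
                raise DegenerateTestError(
                    "constant differences; normality test undefined"
                )
            ps = [sps.shapiro(d).pvalue]
        else:
            raise ValueError("normality_on must be 'margins' or 'differences'")
        test = "wilcoxon" if min(ps) < alpha else "ttest"
    else:
        test = force_test
    if test == "wilcoxon":
        stat, p = _wilcoxon(d)
        name = "wilcoxon_signed_rank"
    elif test == "ttest":
        if np.ptp(d) == 0:
            raise DegenerateTestError(
                "zero-variance differences; paired t-test undefined"
            )
        res = sps.ttest_rel(sample.a, sample.b)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "paired_t"
    else:
        raise ValueError(f"unknown test: {test!r}")
    delta = cliffs_delta(sample.a, sample.b)
    return StatResult(
        test_name=name,
        statistic=stat,
        p_value=p,
        n=sample.n,
        effect_size=delta,
        effect_label=effect_label(delta),
    )


def baseline_correct(
    sync_times: Mapping[str, Mapping[str, float]]
    | pd.DataFrame,
) -> PairedSample:
    """Subtract each participant's *human*-condition time from the others.

    ``sync_times`` maps participant -> {condition -> time} (or an
    equivalent tidy DataFrame with columns participant, condition,
    time_pressed_s).  Returns the paired difference scores
    (coupling - human, no_coupling - human).
    """
    if isinstance(sync_times, pd.DataFrame):
        wide = sync_times.pivot(
            index="participant", columns="condition", values="time_pressed_s"
        )
        sync_times = {p: row.to_dict() for p, row in wide.iterrows()}
    coupling, no_coupling = [], []
    for participant, times in sync_times.items():
        missing = {"human", "no_coupling", "coupling"} - set(times)
        if missing or any(
            v is None or (isinstance(v, float) and math.isnan(v))
            for v in times.values()
        ):
            raise MirrorGameError(
                f"participant {participant!r} lacks conditions {missing or 'values'}"
            )
        coupling.append(times["coupling"] - times["human"])
        no_coupling.append(times["no_coupling"] - times["human"])
    return PairedSample(
        np.asarray(coupling), np.asarray(no_coupling),
        name_a="coupling-human", name_b="no_coupling-human",
    )


def analyze_questionnaire(
    table: pd.DataFrame,
    cond_a: str = "coupling",
    cond_b: str = "no_coupling",
) -> List[StatResult]:
    """Per-question Wilcoxon comparison of two conditions.

    ``table`` is tidy: participant, condition, question, response.
    Ordinal 7-point responses get the signed-rank test regardless of
    normality.  No multiple-testing correction is applied (each question
    is reported with its raw p-value); apply one downstream if desired.
    Results are ordered by question index and carry the per-condition
    medians in ``extra``.
    """
    results = []
    for q in sorted(table["question"].unique()):
        sub = table[table["question"] == q]
        wide = sub.pivot(index="participant", columns="condition",
                         values="response")
        if cond_a not in wide or cond_b not in wide or wide[
            [cond_a, cond_b]
        ].isna().any().any():
            raise MirrorGameError(
                f"question {q}: incomplete pairing for "
                f"{cond_a!r} vs {cond_b!r}"
            )
        a = wide[cond_a].to_numpy(float)
        b = wide[cond_b].to_numpy(float)
        d = a - b
        if np.all(d == 0):
            raise DegenerateTestError(
                f"question {q}: identical responses in both conditions"
            )
        stat, p = _wilcoxon(d)
        delta = cliffs_delta(a, b)
        results.append(
            StatResult(
                test_name="wilcoxon_signed_rank",
                statistic=stat,
                p_value=p,
                n=len(a),
                effect_size=delta,
                effect_label=effect_label(delta),
                extra={
                    "question": float(q),
                    f"median_{cond_a}": float(np.median(a)),
                    f"median_{cond_b}": float(np.median(b)),
                },
            )
        )
    return results


def analyze_sync_times(
    sync_times: Mapping[str, Mapping[str, float]] | pd.DataFrame,
) -> List[StatResult]:
    """Two-stage analysis of per-participant time-in-sync.

    Stage 1 works on raw times: Shapiro-Wilk per condition, then a
    Wilcoxon signed-rank test of *coupling* vs *no coupling* (the raw
    distributions are typically non-normal because some participants
    hold the button constantly).  Stage 2 removes that participant bias
    by baseline correction against the *human* condition: Shapiro-Wilk
    on each difference sample, then a paired t-test of
    (coupling - human) vs (no_coupling - human) with Cliff's delta.

    Returns, in order: three stage-1 Shapiro results (human,
    no_coupling, coupling), the stage-1 Wilcoxon, two stage-2 Shapiro
    results, and the stage-2 paired t.
    """
    if isinstance(sync_times, pd.DataFrame):
        wide = sync_times.pivot(
            index="participant", columns="condition", values="time_pressed_s"
        )
        sync_times = {p: row.to_dict() for p, row in wide.iterrows()}
    conditions = ("human", "no_coupling", "coupling")
    raw = {c: [] for c in conditions}
    for participant, times in sync_times.items():
        missing = set(conditions) - set(times)
        if missing:
            raise MirrorGameError(
                f"participant {participant!r} lacks conditions {missing}"
            )
        for c in conditions:
            raw[c].append(times[c])
    raw = {c: np.asarray(v, dtype=float) for c, v in raw.items()}
    n = len(raw["human"])

    results: List[StatResult] = []
    for c in conditions:
        results.append(_shapiro_result(f"shapiro_{c}", raw[c], n))
    results.append(
        _paired_or_degenerate(
            PairedSample(raw["coupling"], raw["no_coupling"],
                         "coupling", "no_coupling"),
            "wilcoxon",
        )
    )

    diffs = baseline_correct(sync_times)
    for label, values in (
        ("coupling_minus_human", diffs.a),
        ("no_coupling_minus_human", diffs.b),
    ):
        results.append(_shapiro_result(f"shapiro_{label}", values, n))
    results.append(_paired_or_degenerate(diffs, "ttest"))
    return results


def _shapiro_result(name: str, values: np.ndarray, n: int) -> StatResult:
    """Shapiro-Wilk wrapped as a StatResult; constant data are flagged."""
    if np.ptp(values) == 0:
        return StatResult(f"{name}_degenerate", math.nan, 1.0, n)
    res = sps.shapiro(values)
    return StatResult(name, float(res.statistic), float(res.pvalue), n)


def _paired_or_degenerate(sample: PairedSample, test: str) -> StatResult:
    """Run the paired test; degenerate data become a flagged null result."""
    try:
        return compare_paired(sample, force_test=test)
    except DegenerateTestError:
        name = ("wilcoxon_signed_rank" if test == "wilcoxon"
                else "paired_t")
        return StatResult(
            test_name=f"{name}_degenerate",
            statistic=math.nan,
            p_value=1.0,
            n=sample.n,
            effect_size=0.0,
            effect_label="negligible",
        )
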