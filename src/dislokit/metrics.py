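"""Diagnostic accuracy: confusion tables, exact binomial CIs, incidence,
review burden, and reconstruction of integer confusion counts from a
published percentage table.

All percentages are reported on the 0-100 scale, rounded half-up to one
decimal, matching the presentation of registry validation studies.
Confidence intervals are exact Clopper-Pearson (beta) intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from statsmodels.stats.proportion import proportion_confint

from .classifier import StepClassification
from .model import DislocationEvent, DislokitError, ValidationError


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero to ``ndigits`` decimals (table convention;
    Python's built-in ``round`` is half-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def clopper_pearson(count: int, nobs: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact two-sided binomial CI as proportions in [0, 1]."""
    if nobs <= 0:
        raise ValidationError("Clopper-Pearson interval needs nobs > 0")
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="beta")
    return float(lo), float(hi)


@dataclass(frozen=True)
class MetricValue:
    """A proportion in %, with its exact 95% CI, all rounded to 1 decimal."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    @classmethod
    def from_counts(cls, numerator: int, denominator: int) -> "MetricValue":
        lo, hi = clopper_pearson(numerator, denominator)
        return cls(
            value=round_half_up(100.0 * numerator / denominator),
            ci_low=round_half_up(100.0 * lo),
            ci_high=round_half_up(100.0 * hi),
            numerator=numerator,
            denominator=denominator,
        )

    def __str__(self):
        return f"{self.value:.1f} ({self.ci_low:.1f}-{self.ci_high:.1f})"


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives


@dataclass(frozen=True)
class AccuracyResult:
    sensitivity: Optional[MetricValue]
    specificity: Optional[MetricValue]
    ppv: Optional[MetricValue]
    npv: Optional[MetricValue]


def accuracy(ct: ConfusionTable) -> AccuracyResult:
    """Sensitivity, specificity, PPV and NPV with exact 95% CIs.

    PPV/NPV are ``None`` when no patient tests positive/negative; an
    all-zero table is an error.
    """
    if ct.total == 0:
        raise ValidationError("empty confusion table")
    return AccuracyResult(
        sensitivity=MetricValue.from_counts(ct.tp, ct.positives) if ct.positives else None,
        specificity=MetricValue.from_counts(ct.tn, ct.negatives) if ct.negatives else None,
        ppv=MetricValue.from_counts(ct.tp, ct.tp + ct.fp) if ct.tp + ct.fp else None,
        npv=MetricValue.from_counts(ct.tn, ct.tn + ct.fn) if ct.tn + ct.fn else None,
    )


def confusion(
    classifications: Sequence[StepClassification],
    truth: Iterable[DislocationEvent],
    step,
) -> ConfusionTable:
    """Patient-level 2x2 table at one step against the gold standard.

    ``truth`` is the verified event list; a patient is a true case iff they
    have at least one event. Every truth patient must be classified.
    """
    positives = {e.patient_id for e in truth}
    classified = {c.patient_id for c in classifications}
    missing = positives - classified
    if missing:
        raise ValidationError(
            f"{len(missing)} truth patients missing from classifications, "
            f"e.g. {sorted(missing)[:3]}"
        )
    tp = fp = tn = fn = 0
    for c in classifications:
        flagged = c.detected_at_step[step]
        if c.patient_id in positives:
            tp += flagged
            fn += not flagged
        else:
            fp += flagged
            tn += not flagged
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# implied-count reconstruction from a printed accuracy table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpliedCounts:
    """Integer confusion counts implied by printed sensitivity and PPV."""

    step: str
    tp: int
    fp: int
    fp_candidates: tuple
    ambiguous: bool
    exact: bool  # False when no fp reproduces the printed PPV exactly
    P: int
    N: int

    @property
    def table(self) -> ConfusionTable:
        return ConfusionTable(tp=self.tp, fp=self.fp, tn=self.N - self.fp, fn=self.P - self.tp)


class ReconstructionError(DislokitError):
    """No integer counts reproduce a printed row."""


def _fp_candidates(tp: int, ppv: float, n_max: int) -> List[int]:
    # 100*tp/(tp+fp) rounds to ppv  <=>  tp+fp in [100*tp/(ppv+0.05), 100*tp/(ppv-0.05))
    if tp == 0:
        # PPV is 0/fp = 0 for every fp >= 1 (fp = 0 leaves it undefined)
        return list(range(1, n_max + 1)) if ppv == 0.0 else []
    lo_total = 100.0 * tp / (ppv + 0.05)
    hi_total = 100.0 * tp / (ppv - 0.05) if ppv > 0.05 else float("inf")
    out = []
    start = max(tp, int(math.floor(lo_total)) - 2)
    stop = tp + n_max
    if math.isfinite(hi_total):
        stop = min(stop, int(math.ceil(hi_total)) + 2)
    for total in range(start, stop + 1):
        fp = total - tp
        if 0 <= fp <= n_max and round_half_up(100.0 * tp / total) == ppv:
            out.append(fp)
    return out


def reconstruct_step(
    step: str,
    sensitivity: float,
    ppv: float,
    P: int,
    N: int,
    on_inexact: str = "error",
) -> ImpliedCounts:
    """Invert one printed (sensitivity, PPV) pair to integer (tp, fp).

    ``tp`` must be unique among 0..P; several ``fp`` may round to the same
    PPV (flagged ambiguous, smallest reported). ``on_inexact`` controls what
    happens when no integer fp reproduces the printed PPV: ``"error"``
    raises; ``"nearest"`` returns the fp whose unrounded PPV is closest and
    marks the row inexact.
    """
    tps = [tp for tp in range(P + 1) if round_half_up(100.0 * tp / P) == sensitivity]
    if not tps:
        raise ReconstructionError(
            f"step {step}: no tp in 0..{P} gives sensitivity {sensitivity}"
        )
    if len(tps) > 1:
        raise ReconstructionError(
            f"step {step}: tp not unique for sensitivity {sensitivity}: {tps}"
        )
    tp = tps[0]
    fps = _fp_candidates(tp, ppv, N)
    exact = True
    if not fps:
        if on_inexact != "nearest":
            raise ReconstructionError(
                f"step {step}: no integer fp reproduces PPV {ppv} at tp={tp} "
                "(inconsistent printed row)"
            )
        exact = False
        fps = [
            min(
                range(N + 1),
                key=lambda fp: (abs(100.0 * tp / (tp + fp) - ppv), fp),
            )
        ]
    return ImpliedCounts(
        step=step,
        tp=tp,
        fp=fps[0],
        fp_candidates=tuple(fps),
        ambiguous=len(fps) > 1,
        exact=exact,
        P=P,
        N=N,
    )


def reconstruct_implied_counts(
    printed: Mapping[str, Mapping[str, float]],
    P: int,
    N: int,
    on_inexact: str = "error",
) -> Dict[str, ImpliedCounts]:
    """Invert a printed per-step accuracy table to confusion counts.

    ``printed`` maps step label to a mapping with at least ``sensitivity``
    and ``ppv`` (percent, one decimal).
    """
    return {
        step: reconstruct_step(
            step, row["sensitivity"], row["ppv"], P, N, on_inexact=on_inexact
        )
        for step, row in printed.items()
    }


# ---------------------------------------------------------------------------
# incidence and review burden
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Incidence:
    percent: float
    numerator: int
    denominator: int
    ci_low: float
    ci_high: float


def incidence(cohort, truth: Iterable[DislocationEvent]) -> Incidence:
    """Crude cumulative incidence: % of cohort patients with >= 1 event."""
    n = len(cohort.records) if hasattr(cohort, "records") else len(cohort)
    if n == 0:
        raise ValidationError("empty cohort")
    ids = (
        cohort.patient_ids
        if hasattr(cohort, "patient_ids")
        else {r.patient_id for r in cohort}
    )
    k = len({e.patient_id for e in truth} & ids)
    lo, hi = clopper_pearson(k, n)
    return Incidence(
        percent=round_half_up(100.0 * k / n),
        numerator=k,
        denominator=n,
        ci_low=round_half_up(100.0 * lo),
        ci_high=round_half_up(100.0 * hi),
    )


@dataclass(frozen=True)
class ReviewBurden:
    patients: int
    contacts: int


def review_burden(
    classifications: Sequence[StepClassification], step: str
) -> ReviewBurden:
    """How many patient files (and qualifying contacts) must be reviewed.

    4A reviews the patients first flagged at step 4 (group-4 contacts only);
    5A additionally reviews those first flagged at step 5 (cumulative).
    """
    if step not in ("4A", "5A"):
        raise DislokitError("review burden is defined for steps 4A and 5A")
    patients = 0
    contacts = 0
    for c in classifications:
        if c.detected_at_step[4] and not c.detected_at_step[3]:
            patients += 1
            contacts += sum(1 for g in c.contact_groups.values() if g == 4)
        if step == "5A" and c.detected_at_step[5] and not c.detected_at_step[4]:
            patients += 1
            contacts += sum(1 for g in c.contact_groups.values() if g == 5)
    return ReviewBurden(patients=patients, contacts=contacts)
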