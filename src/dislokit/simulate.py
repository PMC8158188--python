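"""Synthetic registry generator calibrated to the published accuracy table.

Generates linked ``cohort`` / ``contacts`` / ``truth`` tables whose
coding-error structure reproduces the validation study's per-step accuracy
profile, so the whole pipeline (cohort builder → classifier → metrics) can
be exercised end to end without access to the restricted national registers.

Two modes:

- ``quota``: category counts are hit exactly — deterministic reproduction of
  the published table at full cohort size;
- ``sampling``: every patient draws a category multinomially with the quota
  probabilities — a stochastic registry for power-style experiments whose
  estimates converge to the quota values as the cohort grows.

Each truly dislocating patient carries one verified event per episode and a
same-day hospital contact per event, coded so the patient's best (lowest
group) qualifying contact equals the calibrated detection category. False
positives at each step are negative patients with a single contact of the
corresponding group. The remaining negatives receive 0-2 nuisance contacts
whose codes never collide with the algorithm's code sets.

Episodes per dislocating patient follow a shifted geometric distribution
truncated at 10, with the rate chosen so the mean matches the calibrated
total event count; this is a modelling stand-in for an unpublished quantity
(only the totals are known) and lands the re-dislocation fraction in the
40-68% range reported in the literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import published
from .metrics import reconstruct_implied_counts, round_half_up
from .model import FOLLOW_UP_DAYS, CodeSet, ValidationError, code_matches
from . import io as dio

BASE_DATE = np.datetime64("2010-01-01")
#: Index operations are spread uniformly over 2010-01-01 .. 2014-12-31.
INDEX_SPAN_DAYS = 1826

CATEGORY_KEYS = ("step1", "step2", "step3", "step4", "step5", "never")
FP_KEYS = ("step1", "step2", "step3", "step4", "step5")

#: Non-qualifying diagnoses paired with qualifying procedures ("any random
#: diagnosis") and pure-nuisance codes. Checked against the active CodeSet
#: at generation time: they must never prefix-match a qualifying code.
RANDOM_DX_POOL = ("DS320", "DM2416", "DZ470", "DT933", "DM796")
NUISANCE_DX_POOL = ("DM160", "DM161", "DZ966", "DI109", "DE119", "DM545")
NUISANCE_PROC_POOL = ("KNGA21", "KQBE05", "KZZX00")


@dataclass
class CalibrationProfile:
    """Everything the generator needs to emulate the study's registry.

    ``detection_category_counts`` says how many truly dislocating patients
    are first detectable at each step (or never); ``fp_increment_counts``
    how many false-positive patients first appear at each step. Optional
    ``event_detection_counts`` (cumulative per step) switches calibration to
    the event level: per-episode detection categories are then quota'd and
    the patient-level profile becomes emergent.
    """

    cohort_size: int
    positives: int
    total_events: int
    detection_category_counts: Dict[str, int]
    fp_increment_counts: Dict[str, int]
    event_detection_counts: Optional[Dict[str, int]] = None
    multiplicity_max: int = 10
    unknown_side_fraction: float = 0.08
    acute_fraction: float = 0.55
    censor_fraction: float = 0.05

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not 0 < self.positives <= self.cohort_size:
            raise ValidationError("positives must be in 1..cohort_size")
        if sum(self.detection_category_counts.get(k, 0) for k in CATEGORY_KEYS) != self.positives:
            raise ValidationError("detection_category_counts must sum to positives")
        if set(self.detection_category_counts) - set(CATEGORY_KEYS):
            raise ValidationError(f"unknown detection categories: {set(self.detection_category_counts) - set(CATEGORY_KEYS)}")
        if any(v < 0 for v in self.detection_category_counts.values()):
            raise ValidationError("detection_category_counts must be non-negative")
        n_fp = sum(self.fp_increment_counts.get(k, 0) for k in FP_KEYS)
        if any(v < 0 for v in self.fp_increment_counts.values()):
            raise ValidationError("fp_increment_counts must be non-negative")
        if n_fp > self.cohort_size - self.positives:
            raise ValidationError("more false-positive patients than negatives available")
        mean = self.total_events / self.positives
        if not 1.0 <= mean <= self.multiplicity_max:
            raise ValidationError(
                f"mean episodes per dislocator {mean:.3f} outside [1, {self.multiplicity_max}]"
            )
        if self.event_detection_counts is not None:
            vals = [self.event_detection_counts[k] for k in FP_KEYS]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValidationError("event_detection_counts must be non-decreasing over steps")
            if vals[-1] > self.total_events:
                raise ValidationError("event_detection_counts exceed total_events")
        for name in ("unknown_side_fraction", "acute_fraction", "censor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a proportion in [0, 1]")

    # -- event multiplicity model -------------------------------------------

    @property
    def multiplicity_mean(self) -> float:
        return self.total_events / self.positives

    def multiplicity_pmf(self) -> np.ndarray:
        """Shifted geometric on 1..multiplicity_max with the calibrated mean."""
        K = self.multiplicity_max
        ks = np.arange(1, K + 1)

        def trunc_mean(p):
            q = 1.0 - p
            w = p * q ** (ks - 1)
            w /= w.sum()
            return float((ks * w).sum())

        target = self.multiplicity_mean
        if target <= 1.0 + 1e-12:
            pmf = np.zeros(K)
            pmf[0] = 1.0
            return pmf
        p = brentq(lambda p: trunc_mean(p) - target, 1e-9, 1 - 1e-9)
        q = 1.0 - p
        pmf = p * q ** (ks - 1)
        return pmf / pmf.sum()

    def multiplicity_quota(self) -> Dict[int, int]:
        """Deterministic per-multiplicity patient counts hitting both the
        number of dislocators and the total episode count exactly."""
        K = self.multiplicity_max
        pmf = self.multiplicity_pmf()
        exact = pmf * self.positives
        counts = {k: int(math.floor(exact[k - 1])) for k in range(1, K + 1)}
        short = self.positives - sum(counts.values())
        order = sorted(range(1, K + 1), key=lambda k: (-(exact[k - 1] - counts[k]), k))
        for k in order[:short]:
            counts[k] += 1
        total = sum(k * v for k, v in counts.items())
        while total < self.total_events:
            k = min(k for k in range(1, K) if counts[k] > 0)
            counts[k] -= 1
            counts[k + 1] += 1
            total += 1
        while total > self.total_events:
            k = max(k for k in range(2, K + 1) if counts[k] > 0)
            counts[k] -= 1
            counts[k - 1] += 1
            total -= 1
        return counts

    # -- (de)serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "cohort_size": self.cohort_size,
            "positives": self.positives,
            "total_events": self.total_events,
            "detection_category_counts": dict(self.detection_category_counts),
            "fp_increment_counts": dict(self.fp_increment_counts),
            "multiplicity_max": self.multiplicity_max,
            "unknown_side_fraction": self.unknown_side_fraction,
            "acute_fraction": self.acute_fraction,
            "censor_fraction": self.censor_fraction,
        }
        if self.event_detection_counts is not None:
            d["event_detection_counts"] = dict(self.event_detection_counts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationProfile":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CalibrationProfile":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_profile() -> CalibrationProfile:
    """Patient-level profile implied by the published accuracy table.

    Per-step true/false positive counts are reconstructed from the printed
    sensitivity/PPV pairs by integer inversion; detection categories and
    false-positive increments are their successive differences. The step-5
    false-positive ambiguity resolves to the smallest candidate, and the
    step-2 row (whose printed PPV admits no exact integer solution) uses the
    nearest-PPV count.
    """
    steps = ("1", "2", "3", "4", "5")
    printed = {s: published.PATIENT_LEVEL_ACCURACY[s] for s in steps}
    implied = reconstruct_implied_counts(
        printed,
        published.DISLOCATION_PATIENTS,
        published.TRUE_NEGATIVE_PATIENTS,
        on_inexact="nearest",
    )
    tps = [implied[s].tp for s in steps]
    fps = [implied[s].fp for s in steps]
    cats = {
        f"step{i + 1}": tps[i] - (tps[i - 1] if i else 0) for i in range(5)
    }
    cats["never"] = published.DISLOCATION_PATIENTS - tps[-1]
    fp_inc = {
        f"step{i + 1}": fps[i] - (fps[i - 1] if i else 0) for i in range(5)
    }
    return CalibrationProfile(
        cohort_size=published.COHORT_SIZE,
        positives=published.DISLOCATION_PATIENTS,
        total_events=published.DISLOCATION_EVENTS,
        detection_category_counts=cats,
        fp_increment_counts=fp_inc,
    )


def event_profile() -> CalibrationProfile:
    """Event-level calibration for the "count every episode" use case.

    Only the step-4 and step-5 event sensitivities were published (whole
    percents); cumulative detection counts for steps 1-3 are interpolated
    from the patient-level sensitivities. Patient-level accuracy is emergent
    under this profile, not calibrated.
    """
    base = default_profile()
    total = base.total_events
    d = {}
    for i, s in enumerate(("1", "2", "3")):
        d[f"step{i + 1}"] = int(
            round_half_up(published.PATIENT_LEVEL_ACCURACY[s]["sensitivity"] / 100.0 * total, 0)
        )
    d["step4"] = int(round_half_up(published.EVENT_LEVEL_ACCURACY["4"]["sensitivity"] / 100.0 * total, 0))
    d["step5"] = int(round_half_up(published.EVENT_LEVEL_ACCURACY["5"]["sensitivity"] / 100.0 * total, 0))
    return replace(base, event_detection_counts=d)


def scaled_profile(profile: CalibrationProfile, factor: float) -> CalibrationProfile:
    """Shrink or grow a profile, preserving count-sum invariants.

    Used for desk-scale experiments; category proportions are kept by
    largest-remainder apportionment.
    """
    positives = max(1, int(round(profile.positives * factor)))
    cohort = max(positives, int(round(profile.cohort_size * factor)))
    cats = _apportion(profile.detection_category_counts, positives)
    n_fp = int(round(sum(profile.fp_increment_counts.values()) * factor))
    n_fp = min(n_fp, cohort - positives)
    fp_inc = _apportion(profile.fp_increment_counts, n_fp)
    mean = profile.multiplicity_mean
    total_events = min(
        profile.multiplicity_max * positives, max(positives, int(round(mean * positives)))
    )
    events = None
    if profile.event_detection_counts is not None:
        fracs = {
            k: profile.event_detection_counts[k] / profile.total_events for k in FP_KEYS
        }
        events = {}
        prev = 0
        for k in FP_KEYS:
            events[k] = max(prev, min(total_events, int(round(fracs[k] * total_events))))
            prev = events[k]
    return replace(
        profile,
        cohort_size=cohort,
        positives=positives,
        total_events=total_events,
        detection_category_counts=cats,
        fp_increment_counts=fp_inc,
        event_detection_counts=events,
    )


def _apportion(counts: Dict[str, int], target: int) -> Dict[str, int]:
    keys = list(counts)
    tot = sum(counts.values())
    if tot == 0:
        return {k: 0 for k in keys}
    exact = {k: counts[k] * target / tot for k in keys}
    out = {k: int(math.floor(exact[k])) for k in keys}
    short = target - sum(out.values())
    order = sorted(keys, key=lambda k: (-(exact[k] - out[k]), keys.index(k)))
    for k in order[:short]:
        out[k] += 1
    return out


# ---------------------------------------------------------------------------
# contact recipes
# ---------------------------------------------------------------------------

def _check_pools(codes: CodeSet) -> None:
    for dx in RANDOM_DX_POOL + NUISANCE_DX_POOL:
        if any(code_matches(dx, p) for p in codes.correct_dx | codes.alt_dx):
            raise ValidationError(f"nuisance diagnosis {dx} collides with the code set")
    for pr in NUISANCE_PROC_POOL:
        if pr in codes.correct_proc | codes.alt_proc:
            raise ValidationError(f"nuisance procedure {pr} collides with the code set")


def _pick(rng, seq):
    return seq[int(rng.integers(len(seq)))]


def _recipe(rng, codes: CodeSet, category: str, tha_side: str, profile) -> dict:
    """Coding recipe for one contact of the given detection category."""
    correct_dx = _pick(rng, sorted(codes.correct_dx))
    if rng.random() < 0.3:
        correct_dx += "A"  # subcode variant; still prefix-matches
    correct_proc = _pick(rng, sorted(codes.correct_proc))

    if category == "step1":
        return dict(dx=[(correct_dx, "primary")], procs=[correct_proc],
                    side=tha_side, admission_type="acute", setting="inpatient",
                    specialty="orthopedic")
    if category == "step2":
        return dict(dx=[(_pick(rng, RANDOM_DX_POOL), "primary")], procs=[correct_proc],
                    side=tha_side, admission_type="acute", setting="inpatient",
                    specialty="orthopedic")
    if category == "step3":
        if rng.random() < 0.5:
            dx, procs = [(_pick(rng, sorted(codes.alt_dx)), "primary")], []
        else:
            dx = [(_pick(rng, RANDOM_DX_POOL), "primary")]
            procs = [_pick(rng, sorted(codes.alt_proc))]
        return dict(dx=dx, procs=procs, side=tha_side, admission_type="acute",
                    setting=_pick(rng, ("inpatient", "outpatient_er")),
                    specialty="orthopedic")
    if category == "step4":
        base = _recipe(rng, codes, _pick(rng, ("step1", "step2", "step3")), tha_side, profile)
        base["side"] = "unknown"
        return base
    if category == "step5":
        procs = [_pick(rng, NUISANCE_PROC_POOL)] if rng.random() < 0.3 else []
        return dict(dx=[(correct_dx, _pick(rng, ("primary", "secondary")))], procs=procs,
                    side=tha_side, admission_type="acute",
                    setting=_pick(rng, ("inpatient", "outpatient_er")),
                    specialty="orthopedic")
    # nuisance: must never qualify at any step
    side = tha_side
    u = rng.random()
    if u < profile.unknown_side_fraction:
        side = "unknown"
    elif u < profile.unknown_side_fraction + 0.25:
        side = "left" if tha_side == "right" else "right"
    acute = rng.random() < profile.acute_fraction
    setting = _pick(rng, ("inpatient", "outpatient_er")) if acute else _pick(
        rng, ("inpatient", "outpatient_clinic"))
    procs = [_pick(rng, NUISANCE_PROC_POOL)] if rng.random() < 0.2 else []
    return dict(dx=[(_pick(rng, NUISANCE_DX_POOL), _pick(rng, ("primary", "secondary")))],
                procs=procs, side=side,
                admission_type="acute" if acute else "elective", setting=setting,
                specialty=_pick(rng, ("orthopedic", "other", "other")))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(
    profile: CalibrationProfile,
    seed: int,
    mode: str = "quota",
    codes: Optional[CodeSet] = None,
    out_dir=None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (cohort, contacts, truth) DataFrames; optionally write CSVs.

    Deterministic: identical (profile, seed, mode) give byte-identical CSV
    output.
    """
    if mode not in ("quota", "sampling"):
        raise ValidationError(f"mode must be quota or sampling: {mode!r}")
    profile.validate()
    codes = codes or CodeSet()
    _check_pools(codes)
    rng = np.random.default_rng(seed)
    n = profile.cohort_size

    index_day = rng.integers(0, INDEX_SPAN_DAYS, size=n)
    sides = np.where(rng.random(n) < 0.5, "left", "right")
    ages = np.clip(np.rint(rng.normal(69.0, 10.0, size=n)), 40, 95).astype(int)
    censored = rng.random(n) < profile.censor_fraction
    censor_days = rng.integers(30, FOLLOW_UP_DAYS, size=n)
    censor_reasons = rng.choice(["death", "revision", "emigration"], size=n)

    roles = _assign_roles(profile, rng, n, mode)

    # episodes per dislocating patient
    pos_idx = [i for i in range(n) if roles[i][0] == "pos"]
    mult = _assign_multiplicities(profile, rng, len(pos_idx), mode)

    # verified events: (patient index, day offset)
    events: List[Tuple[int, int]] = []
    for i, m in zip(pos_idx, mult):
        w = int(censor_days[i]) if censored[i] else FOLLOW_UP_DAYS - 1
        days = np.sort(rng.choice(np.arange(1, w + 1), size=m, replace=False))
        events.extend((i, int(d)) for d in days)

    event_cats = _event_categories(profile, rng, roles, events, mode)

    contact_rows: List[dict] = []

    def add_contact(pidx: int, day: int, category: str):
        r = _recipe(rng, codes, category, str(sides[pidx]), profile)
        admit = int(index_day[pidx]) + day
        stay = int(rng.integers(0, 4)) if r["setting"] == "inpatient" else 0
        contact_rows.append(
            dict(
                pidx=pidx,
                admit=admit,
                discharge=admit + stay,
                specialty=r["specialty"],
                admission_type=r["admission_type"],
                setting=r["setting"],
                side=r["side"],
                dx_codes=";".join(code for code, _ in r["dx"]),
                dx_positions=";".join(pos for _, pos in r["dx"]),
                proc_codes=";".join(r["procs"]),
                proc_dates=";".join([_day_to_iso(admit)] * len(r["procs"])),
            )
        )

    for (pidx, day), cat in zip(events, event_cats):
        add_contact(pidx, day, "nuisance" if cat == "never" else cat)

    for i in range(n):
        kind, key = roles[i]
        w = int(censor_days[i]) if censored[i] else FOLLOW_UP_DAYS - 1
        if kind == "fp":
            add_contact(i, int(rng.integers(1, w + 1)), key)
        elif kind == "neg":
            k = int(rng.choice([0, 1, 2], p=[0.5, 0.35, 0.15]))
            for _ in range(k):
                add_contact(i, int(rng.integers(1, w + 1)), "nuisance")

    pids = np.array([f"P{i:06d}" for i in range(n)])

    cohort_df = pd.DataFrame(
        {
            "patient_id": pids,
            "index_date": _days_to_iso(index_day),
            "side": sides,
            "age_at_surgery": ages,
            "indication": "primary_OA",
            "censor_date": np.where(
                censored, _days_to_iso(index_day + censor_days), ""
            ),
            "censor_reason": np.where(censored, censor_reasons, "none"),
        },
        columns=dio.COHORT_COLUMNS,
    )

    contact_rows.sort(key=lambda r: (r["pidx"], r["admit"]))
    contacts_df = pd.DataFrame(
        {
            "patient_id": [pids[r["pidx"]] for r in contact_rows],
            "contact_id": [f"C{i:07d}" for i in range(len(contact_rows))],
            "admit_date": _days_to_iso(np.array([r["admit"] for r in contact_rows], dtype=int)),
            "discharge_date": _days_to_iso(np.array([r["discharge"] for r in contact_rows], dtype=int)),
            "specialty": [r["specialty"] for r in contact_rows],
            "admission_type": [r["admission_type"] for r in contact_rows],
            "setting": [r["setting"] for r in contact_rows],
            "side": [r["side"] for r in contact_rows],
            "dx_codes": [r["dx_codes"] for r in contact_rows],
            "dx_positions": [r["dx_positions"] for r in contact_rows],
            "proc_codes": [r["proc_codes"] for r in contact_rows],
            "proc_dates": [r["proc_dates"] for r in contact_rows],
        },
        columns=dio.CONTACT_COLUMNS,
    )

    events_sorted = sorted(events)
    truth_df = pd.DataFrame(
        {
            "patient_id": [pids[i] for i, _ in events_sorted],
            "event_id": [f"E{i:06d}" for i in range(len(events_sorted))],
            "event_date": _days_to_iso(
                np.array([int(index_day[i]) + d for i, d in events_sorted], dtype=int)
            ),
        },
        columns=dio.TRUTH_COLUMNS,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_csv(cohort_df, out / "cohort.csv")
        dio.write_csv(contacts_df, out / "contacts.csv")
        dio.write_csv(truth_df, out / "truth.csv")
    return cohort_df, contacts_df, truth_df


def _assign_roles(profile, rng, n, mode) -> List[Tuple[str, str]]:
    labels: List[Tuple[str, str]] = [("pos", k) for k in CATEGORY_KEYS]
    labels += [("fp", k) for k in FP_KEYS]
    labels.append(("neg", ""))
    counts = [profile.detection_category_counts.get(k, 0) for k in CATEGORY_KEYS]
    counts += [profile.fp_increment_counts.get(k, 0) for k in FP_KEYS]
    counts.append(n - sum(counts))
    if mode == "quota":
        seq = np.repeat(np.arange(len(labels)), counts)
        rng.shuffle(seq)
    else:
        probs = np.asarray(counts, dtype=float) / n
        seq = rng.choice(len(labels), size=n, p=probs)
    return [labels[j] for j in seq]


def _assign_multiplicities(profile, rng, n_pos, mode) -> List[int]:
    if mode == "quota" and n_pos == profile.positives:
        quota = profile.multiplicity_quota()
        mult = np.repeat(
            [k for k in sorted(quota)], [quota[k] for k in sorted(quota)]
        )
        rng.shuffle(mult)
        return [int(m) for m in mult]
    pmf = profile.multiplicity_pmf()
    ks = np.arange(1, profile.multiplicity_max + 1)
    return [int(m) for m in rng.choice(ks, size=n_pos, p=pmf)]


def _event_categories(profile, rng, roles, events, mode) -> List[str]:
    """Detection category per event.

    Patient-level calibration: each event inherits its patient's category.
    Event-level calibration: categories are quota'd (or sampled) over
    episodes from the cumulative event_detection_counts.
    """
    if profile.event_detection_counts is None:
        return [roles[i][1] for i, _ in events]
    d = [profile.event_detection_counts[k] for k in FP_KEYS]
    inc = [d[0]] + [d[j] - d[j - 1] for j in range(1, 5)]
    counts = inc + [profile.total_events - d[-1]]
    labels = list(FP_KEYS) + ["never"]
    if mode == "quota" and len(events) == profile.total_events:
        seq = np.repeat(np.arange(len(labels)), counts)
        rng.shuffle(seq)
    else:
        probs = np.asarray(counts, dtype=float) / profile.total_events
        seq = rng.choice(len(labels), size=len(events), p=probs)
    return [labels[j] for j in seq]


def _day_to_iso(day: int) -> str:
    return str(BASE_DATE + np.timedelta64(int(day), "D"))


def _days_to_iso(days: np.ndarray) -> np.ndarray:
    return (BASE_DATE + days.astype("timedelta64[D]")).astype("datetime64[D]").astype(str)
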