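# Methods

## Problem and setting

Dislocation after primary total hip arthroplasty (THA) is usually treated
with closed reduction and therefore rarely reaches arthroplasty registers,
which are revision-driven. Administrative hospital-contact registers do see
these episodes, but under heterogeneous coding: the correct pair — ICD-10
diagnosis `DT84.0(A)` (mechanical complication of an internal joint
prosthesis, Danish dialect with a leading `D`) plus NCSP procedure `KNFH20`
(closed reduction of a prosthetic hip) — identifies only about 63% of truly
dislocating patients. `dislokit` implements a stepwise case-finding
algorithm over coded hospital contacts, evaluates it against a gold-standard
event table, and ships a synthetic registry generator calibrated so the full
pipeline reproduces the published nationwide validation (31,762 THAs,
2010–2014, two-year follow-up; 1,094 dislocators with 1,890 episodes).

## The algorithm

Each hospital contact within a THA's follow-up window is assigned to at most
one code group (lowest applicable group wins; a contact coded for the
opposite hip never qualifies):

| group | definition |
|---|---|
| 1 | diagnosis `DT840*` **and** procedure `KNFH20`, contact laterality = operated side |
| 2 | `KNFH20` with any other diagnosis, laterality matching |
| 3 | alternative codes (`DS730*` traumatic hip dislocation, or `KNFH00/02/21/22`), laterality matching |
| 4 | any group 1–3 code criterion but contact laterality unknown |
| 5 | `DT840*` alone (no `KNFH20`), laterality matching, acute admission or emergency-room contact only |

Diagnosis codes match by prefix (`DT840A` qualifies under `DT840`);
procedure codes are fixed-length NCSP codes and match exactly. Both primary
and secondary diagnosis positions qualify. Detection step *k* flags a
patient whose best contact has group ≤ *k*, so the steps are cumulative and
patient-level sensitivity is non-decreasing while specificity and PPV fall.
Steps 4A and 5A model a manual chart review of the group-4 (respectively
group-4/5) contacts in which false positives are discarded; review never
removes true positives, so it raises PPV without touching sensitivity.

Patient-level classification answers "who had at least one dislocation"
(risk of dislocation). Event-level classification instead asks which of the
verified episodes are captured: each qualifying contact is matched to at
most one episode of the same patient within ±1 day of the admission date
(nearest date, earlier episode on ties). The register never documents how
contacts map to episodes; the generator emits same-day contacts, so the
calibration results are insensitive to the width of this window.

## Cohort rules

Primary-osteoarthritis THAs in patients aged ≥ 40; one THA per patient
(earliest kept, the contralateral logged as excluded); follow-up is the
closed–open 730-day window from the index date, truncated by revision,
death or emigration, with the censoring day itself still observed (a
revision on day *d* may carry the codes of the dislocation that caused it).
Day-0 contacts are retained: in-admission dislocations exist and the
classifier, not the windowing, should decide about them.

## Accuracy metrics

Sensitivity, specificity, PPV and NPV from the patient-level 2×2 table, as
percentages rounded half-up to one decimal, each with an exact
Clopper–Pearson 95% CI (`statsmodels` beta method). PPV/NPV are reported as
absent — not 0 or 100 — when nobody tests positive/negative. The crude
cumulative incidence is the proportion of cohort patients with ≥ 1 verified
event; the published incidence CI (3.3–3.6) likely comes from a
censoring-aware estimator, so only the point estimate is asserted.

## Implied-count reconstruction

The validation paper prints percentages, not counts. Because sensitivity =
tp/1094 and PPV = tp/(tp+fp) are printed at one decimal and the counts are
integers, the per-step (tp, fp) can be recovered by exact inversion: scan tp
∈ 0..1094 for the printed sensitivity (it must be unique), then scan fp for
the printed PPV. `reconstruct_implied_counts` returns the full candidate
set, flags ambiguity, and in strict mode raises when a row admits no integer
solution; `on_inexact="nearest"` substitutes the fp with the closest
unrounded PPV instead.

Applied to the published table this yields step-wise (tp, fp) = (686, 15),
(842, 31), (931, 36), (999, 72), (1044, 232), with four print quirks the
package reports rather than hides:

- step-5 fp is ambiguous between 232 and 233 (both round to PPV 81.8 and
  specificity 99.2); the smallest is used;
- the step-2 printed PPV 96.5 admits **no** integer fp at the forced
  tp = 842 (fp = 31 gives 96.4, fp = 30 gives 96.6); the nearest (31) is used;
- step-1 specificity recomputes to 100.0 (30653/30668 = 99.95%) though
  printed as 99.9;
- the 5A row is inconsistent with the forced review counts: discarding the
  group-4/5 false positives leaves fp = 36, giving PPV 96.7 and specificity
  99.9 versus the printed 96.6 and 99.8. (Row-local inversion would give
  fp = 37 — still specificity 99.9.)

The printed step-5 sensitivity CI (93.9–96.5) is likewise one rounding notch
away from every standard binomial interval at 1044/1094 (exact: 94.0–96.6);
all other sensitivity CIs reproduce exactly with Clopper–Pearson.

## Synthetic registry generator

The generator's default profile **is** the study condition set: cohort
31,762; 1,094 dislocators; 1,890 episodes; per-step detection categories and
false-positive increments equal to the successive differences of the
implied counts (686/156/89/68/45 dislocators first detectable at steps 1–5,
50 never; 15/16/5/36/160 false-positive patients first appearing at steps
1–5).

- **quota mode** hits every category count exactly, so the full pipeline
  reproduces the published table deterministically for any seed (the seed
  only moves nuisance structure: dates, sides, which patient gets which
  category).
- **sampling mode** draws each patient's category multinomially with the
  quota probabilities; estimates converge to the quota values as the cohort
  grows (tested at 10× scale within three binomial standard errors).

Each dislocator receives one verified event per episode and a same-day
hospital contact per event, coded by its detection category (a step-4
patient's contacts carry group 1–3 codes with unknown laterality, a step-5
patient's carry `DT840` alone on an acute/ER contact, a "never" patient's
carry non-qualifying codes). False-positive patients get a single contact of
their step's group and no event. Remaining negatives get 0–2 nuisance
contacts from a small code pool that is checked, at generation time, never
to collide with the active code set.

Episodes per dislocator follow a shifted geometric distribution truncated at
10, the rate solved so the mean is 1890/1094 ≈ 1.73. Only the totals are
published; the family is a modelling choice, and its implied re-dislocation
fraction (≈ 42% of dislocators have > 1 episode) falls inside the 40–68%
range reported in the joint-replacement literature. In quota mode the
per-multiplicity patient counts are apportioned deterministically
(largest-remainder, then single-step moves) so both totals are hit exactly.

Other nuisance defaults, chosen once as plausible for a national inpatient
register and not revisited: index dates uniform over 2010–2014; ages
N(69, 10²) clipped to 40–95; ~5% of patients censored (death/revision/
emigration, uniform day 30–729, with a dislocator's censoring never placed
before their last event so calibration is unaffected); 8% of nuisance
contacts with unknown laterality; 55% of nuisance contacts acute; 0–2
nuisance contacts per clean negative (expected ≈ 0.65). These shape realism
only — quota calibration is independent of all of them.

The **event-calibrated profile** quotas detection categories per episode
instead: cumulative detected-episode counts (1185, 1455, 1608, 1663, 1796 of
1890) reproduce the published whole-percent event sensitivities at steps 4
(88%) and 5 (95%); steps 1–3 were not published and are interpolated from
the patient-level sensitivities. Patient-level accuracy and event-level PPV
are emergent, not calibrated, under this profile — jointly matching the
patient-level table and the event-level figures is over-constrained and is
not attempted.

## What the synthetic data does and does not show

Passing the end-to-end tests shows the algorithm, the review adjustment and
the metrics are internally consistent with the published confusion
structure, and that the pipeline's plumbing (windowing, laterality, code
matching, event linkage) behaves correctly. It does **not** validate the
algorithm on real registries: the generator reproduces the marginal
confusion counts, not the real joint distribution of codes, departments,
transfer chains, or contact volumes (it makes no attempt to match the
study's 16,437 extracted contacts or 5,096 reviewed files), and real
contact-to-episode linkage may be messier than same-day coding.

## Numerical choices and degenerate inputs

Half-up rounding to one decimal on the percent scale (the table's
convention; Python's built-in `round` is half-even and would differ at
exact .05 boundaries). Ties in event matching break to the earlier episode;
ties in cohort deduplication break to the earliest index date. Duplicate
(patient, date, side) arthroplasty rows, non-disjoint code sets, empty code
strings, censoring before the index date, and profiles whose counts do not
sum are rejected with validation errors before any output is written.
Reported problem sizes: unit and property tests run on cohorts of up to a
few thousand patients; the calibration tests run the full 31,762-patient
registry (seconds), and the sampling-convergence check runs a 317,620-patient
registry once.

## Known limitations

- The multiplicity family and all nuisance distributions are stand-ins for
  unpublished quantities.
- Group-4 contacts are attributed to the single index THA; safe here because
  contralateral THAs are excluded, but wrong for registries with bilateral
  cases.
- The extraction code list of the original study's appendix is not
  reproduced; the default `CodeSet` contains the codes the algorithm itself
  names, and the filter is configurable for wider extractions.
- Event-level NPV/specificity are not defined (no denominator of "true
  negative episodes"); only event sensitivity and PPV are reported.
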