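#!/usr/bin/env python
"""Event-level evaluation: how many of the 1,890 episodes does each step find?

Runs the pipeline on the event-calibrated profile and writes
results/event_metrics.csv. The headline: step 5 captures 95% of episodes,
step 4 88% — lower than the patient-level sensitivities because later
episodes of an already-detected patient can still be miscoded.
"""

from pathlib import Path

from dislokit import event_profile, run_event_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main():
    res = run_event_pipeline(profile=event_profile(), seed=42)
    (ROOT / "results").mkdir(exist_ok=True)
    res.metrics.to_csv(ROOT / "results" / "event_metrics.csv", index=False)
    print(res.metrics.to_string(index=False))
    print(f"\nstep-5 event sensitivity: "
          f"{res.metric(5, 'sensitivity_whole'):.0f}% of {res.total_events} episodes")


if __name__ == "__main__":
    main()
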