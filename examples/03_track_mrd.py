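"""Track an MRD course: molecular response, negativity, recurrence.

Simulates a patient whose ctDNA clears under therapy and reappears at the
last timepoint (a molecular recurrence), runs the full quantification on
every timepoint and prints the per-timepoint status calls.
"""

import datetime as dt

import breaktracer as bt

course = bt.simulate_patient_course("recurrence", seed=3, patient_id="P1")
print(f"profile: {course.truth.profile}; "
      f"truth copies/mL: {list(course.truth.copies_per_ml)}")

timepoints = []
for wells, ctrl, date in zip(course.timepoint_wells, course.controls, course.dates):
    result = bt.quantify_sample(list(wells), run_controls=list(ctrl))
    timepoints.append(
        bt.TimePoint("P1", dt.date.fromisoformat(date), result)
    )

series = bt.build_series(timepoints)
for tp, calls in zip(series.timepoints, series.statuses):
    print(f"{tp.date}  {tp.result.copies_per_mL_plasma:8.1f} copies/mL  "
          f"{tp.result.detectability:12s}  {', '.join(calls) or '-'}")

print("called transitions:", bt.transition_indices(series))
print("truth transitions :", course.truth.transitions)
# The recurrence at the final timepoint is the molecular correlate of
# clinical relapse: positivity after documented negativity.
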