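"""A miniature synthetic wayfinding study, measured and modelled end to end.

Generates 16 synthetic participants across both buildings, computes the four
behavioural measures per between-floor trial, segments trials into
visible/non-visible conditions, compares the three response forms, and fits
the study's mixed-effects model for Time to Escalator.
"""

import wayvis as wv
from wayvis.synthetic import SyntheticDesign, generate_synthetic_trials

envs = [wv.build_building(a) for a in ("centralized", "distributed")]
design = SyntheticDesign(n_participants=16, seed=7)
trials = generate_synthetic_trials(design, envs)
print(f"generated {len(trials)} trials "
      f"({design.n_analyzed} between-floor trials analysed)")

df = wv.measures_table(trials, envs[0], fov=wv.HUMAN_FOV,
                       n_rays=25, visibility_stride=4)
seg = wv.segment_visibility_condition(df)
print(f"visibility conditions: {seg.attrs['n_nv']} NV, {seg.attrs['n_v']} V")

fits = wv.fit_visibility_response_models(
    seg["avg_destination_visibility"], seg["time_to_escalator"])
print("\nresponse forms ranked by AIC (time vs destination visibility):")
for f in fits:
    print(f"  {f.form:12s} a={f.a:8.3f} b={f.b:8.3f} AIC={f.aic:9.1f}")

res = wv.fit_study_model(seg, "time_to_escalator")
print("\nmixed model: TimeToEscalator ~ AtriaType + Block + "
      "VisibilityCondition + Session + (1 | Participant)")
print(res.table.round(3).to_string())
print(f"participant variance: {res.group_var:.2f}")
print("\nThe negative visibility coefficient is the injected effect: trials "
      "with a visible destination reach the escalator several seconds sooner.")
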