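"""Generate a synthetic ward and inspect its cohort funnel and red flags.

Builds 200 hospital encounters with irregularly sampled vitals, applies the
acute-care / length-of-stay / data-availability cohort filters, and detects
red-flag events under the default track-and-trigger thresholds.  Printed
numbers: the funnel counts at each filter stage, the number of red-flag
events, and the fraction of prediction points followed by a red flag within
each lookahead horizon (the class prevalence the models must cope with).
"""

import wardflag as wf
from wardflag import synthetic

params = wf.GeneratorParams(n_encounters=200, random_seed=42, hazard_scale=8.0)
encounters, observations, truth = wf.generate(params)
print(f"{len(encounters)} encounters, {len(observations)} observations")
print("phenotypes:", truth["phenotype"].value_counts().to_dict())
print("episodes fired:", int(truth["onset_time"].notna().sum()))

kept, report = wf.filter_cohort(encounters, observations)
print("\ncohort funnel (encounters retained per stage):")
for stage, n in report.stages():
    print(f"  {stage:>18}: {n}")

obs = observations[observations["encounter_id"].isin(kept)]
flags = wf.detect_red_flags(obs)
print(f"\n{len(flags)} red-flag events; by vital:",
      flags["vital"].value_counts().to_dict())

print("\nlabelled event prevalence per prediction window:")
for w in (2, 4, 6, 8):
    prev = synthetic.window_prevalence(encounters, observations, w)
    print(f"  {w} h ahead: {prev:.1%} of prediction points")
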