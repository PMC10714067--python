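"""Approach behavior around reactive prey: strokes and head turns.

For every capture attempt with a reacting prey, the window from 10 s
before to 5 s after the event is characterized: did the prey react
before/during/after the PrCA, was the seal stroking in the 5 s before the
reaction and during the event, and did it turn its head left or right
within 1 s of the reaction.
"""

from sealforage import SimulationConfig
from sealforage.pipeline import run_pipeline
from sealforage.simulate import simulate_deployment

# study-scale event counts (331 PrCAs -> ~70 reactive prey) so the
# percentages are comparable to the scheduled rates; takes ~half a minute
cfg = SimulationConfig.study_scale(seed=4)
bundles, truth = simulate_deployment(cfg)
res = run_pipeline(bundles, truth=truth, config=cfg, cluster=False)

print(f"{len(res.approach)} reactive-prey approach windows analyzed\n")
cols = ["group", "n_prcas", "pct_before", "pct_during", "pct_after",
        "pct_strokes_before", "pct_strokes_during",
        "pct_turn_left", "pct_turn_right"]
tot = res.approach_summary[res.approach_summary.group.str.startswith("total")]
print(tot[cols].round(1).to_string(index=False))

print("\nScheduled rates: 34/59/7 % before/during/after, 74 % strokes "
      "before, 79 % continuing, 43 % left vs 27 % right turns.")
print("Percentages within a few points of the schedule show the heading/"
      "stroke estimators recover the scripted behavior.")
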