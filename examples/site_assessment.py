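"""Assessing a synthetic multicenter trial, whole-trial and per window.

Generates an example-like trial (50 sites, a discontinuation KRI at ~25%
overall with a few sites planted at 55%), derives risk levels from the
overall rate with absolute percentage-point offsets, classifies each site
and prints the traffic-light summary, then repeats per 60-day study-day
window for one flagged site.
"""

import rbmon as rb
from rbmon.fixtures import make_fixture

fx = make_fixture("example_like", seed=7)
disc = fx.records[fx.records.kri_id == "discontinuation"]

# Specified rule: high risk = overall + 30 pp, medium = overall + 15 pp.
overall = (disc["event_times"].str.len() > 0).mean()
high, medium = rb.levels_from_overall(overall, [0.30, 0.15])
print(f"overall discontinuation {100 * overall:.1f}% -> levels "
      f"high {100 * high:.1f}%, medium {100 * medium:.1f}%")

spec = [rb.RiskLevelSpec("discontinuation", "binomial", (high, medium),
                         reference_time=12.0)]
calls = rb.assess_trial(disc, spec, monitoring_time=24.0)
reds = [a.site_id for a in calls if a.color == "red"]
print(f"{len(calls)} sites assessed; red: {reds}")
truth_high = set(fx.truth[fx.truth.disc_class == "high"].site_id)
print(f"planted high-risk sites            : {sorted(truth_high)}")

# Windowed view of the first flagged site (60-day study-day windows).
site = reds[0]
wspec = rb.WindowSpec("study_day", duration_days=60)
windows = rb.window_assess(disc[disc.site_id == site], wspec, spec)
for a in windows:
    print(f"{site} window {a.window[0]:4.1f}-{a.window[1]:4.1f} mo: "
          f"{a.color:5s} (statistic {a.statistic:.3f})")
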