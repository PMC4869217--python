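"""Draw a synthetic review-platform extract and look at its shape.

The ny-like preset emulates a state-wide venue category whose openings
accelerate after 2009, on a platform launched in October 2004 whose
adoption follows a logistic curve — so early venues wait many months for
a first review while 2014 venues are reviewed almost immediately.
"""

from venuescope import generate_dataset, ny_like_config

cfg = ny_like_config(seed=42)
venues, reviews, truth, sim_truth = generate_dataset(cfg)

target = [t for t in sim_truth if t.category == cfg.category]
closed = sum(t.closed for t in target)
verified = sum(
    1 for g in truth if g.verified_opening_date is not None and g.venue_id.startswith("h")
)
print(f"{len(target)} target venues ({closed} truly closed by {cfg.snapshot}), "
      f"{len(venues) - len(target)} control venues, {len(reviews)} reviews total")
print(f"{verified} target venues carry a verified opening date "
      f"(the calibration cohort for the correction table)")
flagged = sum(v.platform_closed_flag for v in venues)
print(f"{flagged} venues carry the platform closed-flag — all of them truly closed, "
      f"because the flag never fires on open venues by construction")
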