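"""Calibrate the correction table and predict opening dates.

The model: per opening year, the mean calendar-month lag between verified
opening and first review; a venue's opening is predicted as its first
review minus the applicable year's (rounded) mean lag.
"""

from venuescope import (
    fit_correction_table,
    generate_dataset,
    ny_like_config,
    predict_openings,
    share_opened_since,
    yearly_opening_histogram,
)

cfg = ny_like_config(seed=42)
venues, reviews, truth, sim_truth = generate_dataset(cfg)

table = fit_correction_table(truth, reviews)
print("year  n   mean lag (months)")
for year, (n, mean) in sorted(table.rows.items()):
    print(f"{year}  {n:2d}   {'-' if mean is None else f'{mean:.2f}'}")
print("-> the lag shrinks as platform adoption grows: recent first reviews"
      " are near-immediate proxies for opening dates\n")

estimates = predict_openings(reviews, table)
hist = yearly_opening_histogram(estimates, min_year=2006)
share = share_opened_since(hist, 2009, ndigits=1)
print(f"{len(estimates)} venues got an opening estimate; histogram: {hist}")
print(f"{share}% are predicted to have opened in 2009 or later")

true_year = {t.venue_id: t.true_opening_date.year for t in sim_truth}
hits = sum(e.predicted_opening_year == true_year[e.venue_id] for e in estimates)
print(f"{hits}/{len(estimates)} predicted opening years exactly match the "
      f"simulator's truth (errors concentrate in the low-adoption early years)")
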