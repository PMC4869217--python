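# Table formats

All tables are UTF-8 CSV with a header row; JSON-lines (one object per
line, same keys) is accepted wherever a format argument says so.  Dates
are ISO-8601 (`YYYY-MM-DD`), day precision, timezone-naive.  Booleans are
`true`/`false` (also accepted: `1/0`, `yes/no`); an empty cell means
"absent", which is distinct from `false` for attribute columns.

## Venue table (`venues.csv`)

| column | type | notes |
| --- | --- | --- |
| `venue_id` | string | required, unique within the dataset |
| `name` | string | required |
| `address` | string | free text; last standalone 5-digit token used as zip fallback |
| `city`, `state` | string | optional |
| `zip` | string | 5 digits; malformed values demote to absent with a warning |
| `categories` | string | `\|`-separated tags, e.g. `hookah bars\|lounges` |
| `platform_closed_flag` | bool | the platform's crowd-sourced "closed" marker |
| *(any other column)* | bool | preserved as a named attribute (e.g. `credit_cards`, `wifi`); empty = absent |

## Review table (`reviews.csv`)

| column | type | notes |
| --- | --- | --- |
| `venue_id` | string | required; unknown ids retained, counted in a warning |
| `review_date` | date | unparseable dates are a hard error naming the row |

Rows are sorted by (`venue_id`, `review_date`) on read and write.

## Ground-truth table (`ground_truth.csv`)

| column | type | notes |
| --- | --- | --- |
| `venue_id` | string | required |
| `verified_opening_date` | date | optional |
| `verified_status` | `open`/`closed` | optional; status at the snapshot date |
| `source_note` | string | provenance free text |

At least one of `verified_opening_date` / `verified_status` must be
present per row.

## Derived outputs

* `correction_table.csv`: `year, n_venues, mean_lag_months` (empty mean
  for years with no calibration venues).
* `opening_estimates.csv`: `venue_id, first_review_date,
  predicted_opening_date, predicted_opening_year, confidence`.
* `closure_calls.csv`: `venue_id, months_since_last_review,
  predicted_status, rule` (empty recency for reviewless venues).
* `contingency_model.csv` / `contingency_flag.csv`: 2×2 with rows =
  truth, columns = prediction.
* `trend_target.csv` / `trend_control.csv`: `year, month, count,
  cumulative`.
* `zip_density.csv`: `zip, count`, zip ascending; `zip_density.geojson`:
  RFC 7946 FeatureCollection, one feature per zip with `zip` and `count`
  properties (null geometry unless supplied).
* `region_rollup.csv`: `region, count, share_pct`.
* Region map input: `region, zip`, one row per (region, zip) pair.
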