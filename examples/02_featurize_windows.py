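"""From cleaned bookings to labeled 52-week windows.

Shows the featurization chain: weekly count matrices, provision clustering,
facility ranking/regrouping, sliding-window extraction, phi scaling and
labeling.  Prints the dataset dimensions and the label frequencies before
and after rebalancing.
"""

import numpy as np

from attendcast.features import WeekCalendar, build_window_dataset, \
    rebalance_windows, scale_phi
from attendcast.records import clean_records
from attendcast.synth import GeneratorConfig, generate_dataset

cfg = GeneratorConfig(n_patients=60, seed=3)
bookings, _, facilities = generate_dataset(cfg)
cleaned, _ = clean_records(bookings)

calendar = WeekCalendar(cfg.period_start, cfg.period_end)
print(f"calendar: {calendar.n_weeks} weeks")
print("phi scaling of counts 0..5:", scale_phi(np.arange(6)).round(4))

result = build_window_dataset(
    cleaned, calendar, dict(zip(facilities["facility_id"],
                                facilities["district_id"])), seed=1)
ds = result.dataset
print(f"\n{len(ds)} windows; P {ds.P.shape[1:]}, F {ds.F.shape[1:]}, "
      f"labels {ds.y.shape[1]}")
print("top-10 facilities:", result.catalog.top_facilities)

before = ds.y.mean(axis=0)
keep = rebalance_windows(ds.y, seed=1)
after = ds.y[keep].mean(axis=0)
print("\nlabel frequencies before rebalance:", before.round(3))
print("label frequencies after rebalance:  ", after.round(3))
# Down-sampling the windows that only visit non-top facilities (last label)
# raises the relative frequency of every top-facility label.
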