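"""Generate a synthetic booking population and summarize its entities.

Builds a small seeded population (300 patients, 3 years), prints the
unique-entity counts, the most frequent health-service provisions, and the
cumulative frequency of the top provisions — the descriptive statistics a
booking database is usually profiled with before modeling.
"""

from attendcast.records import clean_records, summarize_entities
from attendcast.synth import GeneratorConfig, generate_dataset

cfg = GeneratorConfig(n_patients=300, seed=7, invalid_fraction=0.03,
                      negative_wait_fraction=0.01)
bookings, patients, facilities = generate_dataset(cfg)
cleaned, report = clean_records(bookings)

print(f"generated {report.records_in} bookings; "
      f"{report.records_out} survive cleaning")
print("removed per rule:", report.counts_removed_per_rule)

summary = summarize_entities(cleaned, top_n=(10, 50))
print("\nunique entities:", summary.unique_counts)
print("\ntop-5 provisions by frequency:")
print(summary.provision_frequencies.head(5).round(4).to_string())
print("\ncumulative frequency of top-n provisions:",
      {n: round(v, 3) for n, v in summary.cumulative_top_n.items()})
# A heavy-tailed provision distribution means a few provisions dominate
# bookings while most are rare — the sparsity the featurization collapses.
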