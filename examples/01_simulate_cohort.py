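"""Generate a synthetic panel-sequenced cohort and look at its structure.

The generator emulates an NSCLC-like cohort: per-gene mutation
prevalences, known-oncogenic vs VUS annotations with a latent
driver/passenger truth behind every VUS, class-conditional VEP scores,
confounded survival, binding-residue enrichment and within-pathway
mutual exclusivity.
"""
import collections

import vepbench as vb

cohort = vb.generate_cohort(vb.default_config(n_patients=1000, seed=7))

print(f"patients: {len(cohort.patients)}")
print(f"mutation occurrences: {len(cohort.mutations)}")
print(f"unique scored variants: {len(cohort.scores)}")

by_class = collections.Counter(m.oncokb_class for m in cohort.mutations)
print("occurrences by annotation:", dict(by_class))

latent = cohort.truth.variant_class["latent_class"].value_counts()
print("latent truth over unique variants:")
print(latent.to_string())

events = sum(p.event for p in cohort.patients)
print(f"deaths observed: {events}/{len(cohort.patients)}")
# Most mutations are VUSs (as in real tumor panels); the latent classes
# behind them are what the benchmarks try to recover from scores alone.
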