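"""Benchmark 2 — are reclassified-pathogenic VUSs enriched at binding sites?

OR_binding pools, across all genes with structural data, the odds that a
VUS called pathogenic (vs benign) by a method sits on a ligand-binding
residue or protein-protein-interaction hotspot.
"""
import vepbench as vb
from vepbench.binding import enrichment_battery
from vepbench.pipeline import calibrate_methods
from vepbench.types import ONCOGENIC_CLASSES

cohort = vb.generate_cohort(vb.default_config(n_patients=1000, seed=7))
classifications, _ = calibrate_methods(cohort)

vus_muts = [
    m
    for m in cohort.mutations
    if m.oncokb_class not in ONCOGENIC_CLASSES and m.is_missense
]
where = vb.partition_binding(vus_muts, cohort.binding_map)

results = []
for name in classifications:
    results.append(vb.or_binding(classifications[name], where, group=name))
enrichment_battery(results)

print("OR_binding per method (designed enrichment in the generator: 5.0):")
for r in sorted(results, key=lambda r: -r.or_point):
    print(
        f"  {r.group:8s} OR {r.or_point:5.2f}  [{r.ci_low:.2f}, {r.ci_high:.2f}]"
        f"  q {r.q:.2e}  (table {r.a}/{r.b}/{r.c}/{r.d})"
    )
# An OR well above 1 means the method's 'pathogenic' calls concentrate on
# functionally critical residues — indirect structural validation of the
# reclassification.  Better discriminators approach the designed OR.
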