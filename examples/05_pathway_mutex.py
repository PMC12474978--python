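"""Benchmark 4 — pathway mutual exclusivity of reclassified mutations.

For each gene in a pathway: do patients with a reclassified-pathogenic
VUS in the gene tend NOT to carry known oncogenic mutations elsewhere in
the pathway?  Exclusivity (negative log-OR, BH q <= 0.1) is the pattern
expected of true drivers, since one driver per pathway usually suffices.
"""
import vepbench as vb
from vepbench.mutex import mutex_battery
from vepbench.pipeline import calibrate_methods
from vepbench.types import filter_panel

cohort = vb.generate_cohort(vb.default_config(n_patients=2000, seed=7))
classifications, _ = calibrate_methods(cohort)
calls = classifications["am"]

results = []
for pw in cohort.pathways:
    for gene in pw.genes:
        pats = filter_panel(cohort.patients, cohort.coverage, gene)
        table = vb.build_mutex_table(gene, pw, calls, pats, cohort.mutations)
        res = vb.mutex_fisher(table, gene=gene, pathway=pw.name)
        if res is not None:
            results.append(res)
mutex_battery(results)

print("one-vs-all exclusivity tests ('am' reclassified-pathogenic calls):")
for r in results:
    flag = "  * mutually exclusive" if r.significant else ""
    print(
        f"  {r.pathway:8s} {r.gene:8s} logOR {r.log_or:+.2f}  q {r.q:.3f}{flag}"
    )
for pw in cohort.pathways:
    rate = vb.pathway_rate([r for r in results if r.pathway == pw.name], pw)
    print(f"pathway rate {pw.name}: {rate:.2f}")
# The generator couples NRF2- and RTK/RAS-pathway drivers with odds
# ratios < 1, so focal genes there should test mutually exclusive.
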