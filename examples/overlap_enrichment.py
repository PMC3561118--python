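"""Venn partitioning, overlap significance and term enrichment.

Uses the classified sets from a simulated run, asks whether ED overlaps HD
more than chance (cumulative hypergeometric), and runs a toy
over-representation analysis.
"""

from hypoxdep import (
    SimulationConfig,
    enrich_terms,
    generate_expression,
    hypergeometric_overlap,
    run_full_scheme,
    venn_partition,
)

config = SimulationConfig(
    n_probes=4000,
    seed=4,
    class_fractions={"HD": 0.05, "HI": 0.05, "ED": 0.05},
    effect_log2=(1.5, 3.0),
)
matrix, truth = generate_expression(config)
result = run_full_scheme(matrix)
universe_n = matrix.n_probes

regions = venn_partition({k: result.sets[k] for k in ("HI", "HD", "ED")})
print("Venn regions (disjoint, summing to the union):")
for names, count in sorted(regions.items()):
    print(f"  {'&'.join(names):10s} {count}")

ov = hypergeometric_overlap(result.sets["HD"], result.sets["DM"], universe_n)
print(
    f"\nHD vs DM: {ov.overlap_k} shared of {ov.set_a_size}/{ov.set_b_size} "
    f"(universe {universe_n}), p = {ov.p_value:.3g}"
)
# A tiny p means the sets share far more members than two random sets of
# these sizes would — here guaranteed, since every HD probe is also
# double-mutant-dependent by construction.

glycolysis = set(truth.index[truth["dependency_class"] == "HI"][:20])
annotation = {
    "glycolysis": glycolysis,
    "random_term": set(truth.index[2000:2050]),
}
enr = enrich_terms(result.sets["HI"], annotation, universe_n)
print("\nterm enrichment in the HI set (sorted by p):")
print(enr.round(6).to_string(index=False))
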