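"""Generate a small factorial expression dataset with planted truth.

Builds a 1,000-probe matrix over four genotypes x two oxygen levels with
5% each of HIF-dependent, HIF-independent and ERR-dependent responders,
then shows how the planted effects are realised per genotype.
"""

from hypoxdep import SimulationConfig, generate_expression

config = SimulationConfig(
    n_probes=1000,
    noise_sd=0.25,
    seed=1,
    class_fractions={"HD": 0.05, "HI": 0.05, "ED": 0.05},
    effect_log2=(1.5, 3.0),
)
matrix, truth = generate_expression(config)

print(f"matrix: {matrix.values.shape[0]} probes x {matrix.values.shape[1]} samples")
print(truth["dependency_class"].value_counts().to_string())

hd = truth[truth["dependency_class"] == "HD"].iloc[0]
print(f"\nexample HD probe {hd.name}: planted log2 effect {hd['effect_log2']:+.2f}")
print(
    "realised per genotype (hypoxia - normoxia shift):",
    {g: round(float(hd[f"effect_{g}"]), 2) for g in config.genotypes},
)
# An HD probe responds only where HIF is functional (control, err_mutant):
# its hypoxic induction vanishes in the hif_mutant and double_mutant columns.
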