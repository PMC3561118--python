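"""End-to-end pipeline run writing a reproducible result bundle.

Simulates data, runs every comparison and scheme, and writes DE tables,
GMT gene sets, dependency flags, Venn regions, overlap statistics and a
manifest with per-file checksums into ./pipeline_demo/.
"""

from hypoxdep.pipeline import PipelineConfig, run_pipeline
from hypoxdep.simulate import SimulationConfig

config = PipelineConfig(
    simulate=SimulationConfig(
        n_probes=2000,
        class_fractions={"HD": 0.05, "HI": 0.05, "ED": 0.05},
        effect_log2=(1.5, 3.0),
    ),
    out_dir="pipeline_demo",
    seed=11,
)
manifest = run_pipeline(config)

print("named set sizes:", {k: manifest["set_sizes"][k] for k in ("HI", "HD", "ED", "DM")})
print("gates used (comparison -> max q):")
for name, gate in manifest["gates"].items():
    print(f"  {name:32s} {gate['max_q']}")
print(f"{len(manifest['files'])} files written; rerunning with the same seed")
print("reproduces every checksum in the manifest byte-for-byte.")
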