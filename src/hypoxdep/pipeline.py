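"""End-to-end orchestration: expression matrix in, classified sets out.

``run_pipeline`` runs every required differential comparison, applies the
dual-evidence schemes, computes Venn regions and pairwise overlap
significance for the named sets (and term enrichment when an annotation is
supplied), writes everything as TSV/GMT, and records a manifest (seeds,
gates, universe size, file checksums) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix
from .diffexpr import DEConfig, ThresholdPolicy
from .io import read_annotation, read_expression, write_expression, write_gene_sets
from .overlap import enrich_terms, hypergeometric_overlap, venn_partition
from .setlogic import DEFAULT_POLICIES, SchemeResult, run_full_scheme
from .simulate import SimulationConfig, generate_expression

logger = logging.getLogger("hypoxdep")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either ``matrix_path``+``sheet_path`` (load data) or ``simulate``
    (generate it) must be given. ``gates`` overrides per-comparison q
    gates (fractions); ``universe_n`` defaults to the number of probes in
    the matrix.
    """

    matrix_path: str | None = None
    sheet_path: str | None = None
    simulate: SimulationConfig | None = None
    annotation_path: str | None = None
    schemes: tuple[str, ...] = ("hif", "err", "double")
    direction_mode: str = "ignore"
    gates: dict[str, float] = field(default_factory=dict)
    min_abs_fold: float = 1.5
    de: DEConfig = field(default_factory=DEConfig)
    universe_n: int | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            for key in ("class_fractions", "ct_effects"):
                if key in sim and sim[key] is not None:
                    sim[key] = dict(sim[key])
            for key in ("effect_log2", "baseline_log2", "genotypes"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = SimulationConfig(**sim)
        if "de" in raw and raw["de"] is not None:
            raw["de"] = DEConfig(**raw["de"])
        if "schemes" in raw and raw["schemes"] is not None:
            raw["schemes"] = tuple(raw["schemes"])
        return cls(**raw)

    def policies(self) -> dict[str, ThresholdPolicy]:
        policies = dict(DEFAULT_POLICIES)
        for cmp_name, max_q in self.gates.items():
            if cmp_name not in policies:
                raise ValueError(f"gate for unknown comparison {cmp_name!r}")
            policies[cmp_name] = ThresholdPolicy(self.min_abs_fold, max_q)
        if self.min_abs_fold != 1.5:
            policies = {
                name: ThresholdPolicy(self.min_abs_fold, pol.max_q)
                for name, pol in policies.items()
            }
        return policies


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_matrix(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate
        if sim.seed != config.seed:
            sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
        logger.info("[simulate] %d probes, genotypes=%s", sim.n_probes, sim.genotypes)
        return generate_expression(sim)
    if not (config.matrix_path and config.sheet_path):
        raise ValueError("either simulate or matrix_path+sheet_path required")
    logger.info("[load] %s", config.matrix_path)
    return read_expression(config.matrix_path, config.sheet_path), None


_NAMED_SETS = ("HI", "HD", "ED", "DM")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the result bundle.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    matrix, truth = _load_matrix(config)
    de_config = config.de
    if de_config.seed != config.seed:
        de_config = DEConfig(**{**de_config.__dict__, "seed": config.seed})
    policies = config.policies()
    universe_n = config.universe_n or matrix.n_probes

    logger.info("[classify] schemes=%s on %d probes", config.schemes, matrix.n_probes)
    result: SchemeResult = run_full_scheme(
        matrix, de_config, policies, config.schemes, config.direction_mode
    )

    written: list[Path] = []

    def _emit(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", **kwargs)
        written.append(path)

    if truth is not None:
        _emit(truth, "sim_truth.tsv")
        write_expression(matrix, out_dir / "expression.tsv", out_dir / "samples.csv")
        written += [out_dir / "expression.tsv", out_dir / "samples.csv"]

    for cmp_name, df in result.de.items():
        _emit(df.round(6), f"de_{cmp_name}.tsv")

    gmt_path = out_dir / "gene_sets.gmt"
    write_gene_sets(
        {k: result.sets[k] for k in sorted(result.sets)},
        gmt_path,
    )
    written.append(gmt_path)

    flags = []
    for scheme, calls in result.calls.items():
        f = calls.flags.copy()
        f.insert(0, "scheme", scheme)
        flags.append(f)
    if flags:
        _emit(pd.concat(flags), "dependency_flags.tsv")

    named_present = [n for n in _NAMED_SETS if n in result.sets]
    overlap_rows = []
    for i, name_a in enumerate(named_present):
        for name_b in named_present[i + 1 :]:
            ov = hypergeometric_overlap(
                result.sets[name_a], result.sets[name_b], universe_n
            )
            overlap_rows.append(
                {
                    "set_a": name_a,
                    "set_b": name_b,
                    "size_a": ov.set_a_size,
                    "size_b": ov.set_b_size,
                    "overlap_k": ov.overlap_k,
                    "universe_n": ov.universe_n,
                    "p_value": ov.p_value,
                }
            )
    if overlap_rows:
        _emit(pd.DataFrame(overlap_rows), "overlaps.tsv", index=False)

    venn_names = [n for n in ("HI", "HD", "ED") if n in result.sets][:3]
    if len(venn_names) >= 2:
        regions = venn_partition({n: result.sets[n] for n in venn_names})
        venn_df = pd.DataFrame(
            [{"region": "&".join(k), "count": v} for k, v in sorted(regions.items())]
        )
        _emit(venn_df, "venn_regions.tsv", index=False)

    if config.annotation_path:
        annotation = read_annotation(config.annotation_path)
        for name in named_present:
            enr = enrich_terms(result.sets[name], annotation, universe_n)
            _emit(enr, f"enrichment_{name}.tsv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "universe_n": universe_n,
        "direction_mode": config.direction_mode,
        "schemes": list(config.schemes),
        "gates": {
            name: {"min_abs_fold": pol.min_abs_fold, "max_q": pol.max_q}
            for name, pol in result.policies.items()
        },
        "de_config": {
            "s0_mode": de_config.s0_mode,
            "s0_fixed": de_config.s0_fixed,
            "n_permutations": de_config.n_permutations,
            "exhaustive_limit": de_config.exhaustive_limit,
            "tie_rule": de_config.tie_rule,
        },
        "set_sizes": {name: len(result.sets[name]) for name in sorted(result.sets)},
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("[done] %d files in %s", len(written) + 1, out_dir)
    return manifest
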