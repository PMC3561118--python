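"""Dual-evidence set logic classifying hypoxia-responsive transcripts.

For each factor (HIF, ERR, or both together via the double mutant) the
scheme combines three differential comparisons drawn from the same probe
universe:

* ``total_h``            — control normoxia vs control hypoxia (the Total
  H-genes set);
* ``factor_independent`` — mutant normoxia vs mutant hypoxia (transcripts
  still hypoxia-responsive without the factor);
* ``cross_h``            — control hypoxia vs mutant hypoxia (direct
  evidence that the hypoxic level differs when the factor is removed).

The factor-independent responders are ``total_h ∩ factor_independent``;
subtracting them from the total gives candidate "set 2"; intersecting the
candidates with the cross-comparison set ("set 1") yields the
factor-dependent responders. Independent and dependent sets are therefore
mutually exclusive by construction, and together with the gating rules
(fold >= 1.5, per-comparison q gates) this reproduces the
HI / HD / ED / DM classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import ExpressionMatrix, GeneSet
from .diffexpr import DEConfig, ThresholdPolicy, call_differential, differential_expression

__all__ = [
    "SchemeInputs",
    "DependencyCalls",
    "SchemeResult",
    "DEFAULT_POLICIES",
    "COMPARISONS",
    "SCHEMES",
    "classify_factor",
    "run_full_scheme",
    "concordance_calls",
]

#: the seven comparisons of the reference design, as (group_a, group_b)
COMPARISONS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "control_N_vs_H": (("control", "normoxia"), ("control", "hypoxia")),
    "hif_mutant_N_vs_H": (("hif_mutant", "normoxia"), ("hif_mutant", "hypoxia")),
    "control_H_vs_hif_mutant_H": (("control", "hypoxia"), ("hif_mutant", "hypoxia")),
    "err_mutant_N_vs_H": (("err_mutant", "normoxia"), ("err_mutant", "hypoxia")),
    "control_H_vs_err_mutant_H": (("control", "hypoxia"), ("err_mutant", "hypoxia")),
    "double_mutant_N_vs_H": (("double_mutant", "normoxia"), ("double_mutant", "hypoxia")),
    "control_H_vs_double_mutant_H": (
        ("control", "hypoxia"),
        ("double_mutant", "hypoxia"),
    ),
}

#: per-comparison FDR gates of the reference analysis (fractions, not %)
DEFAULT_POLICIES: dict[str, ThresholdPolicy] = {
    "control_N_vs_H": ThresholdPolicy(1.5, 0.00733),
    "hif_mutant_N_vs_H": ThresholdPolicy(1.5, 0.00414),
    "control_H_vs_hif_mutant_H": ThresholdPolicy(1.5, 0.00721),
    "err_mutant_N_vs_H": ThresholdPolicy(1.5, 0.0784),
    "control_H_vs_err_mutant_H": ThresholdPolicy(1.5, 0.00619),
    "double_mutant_N_vs_H": ThresholdPolicy(1.5, 0.00662),
    "control_H_vs_double_mutant_H": ThresholdPolicy(1.5, 0.00703),
}

#: scheme name -> (dependent-set label, mutant genotype,
#:                 independent comparison, cross comparison)
SCHEMES = {
    "hif": ("HD", "hif_mutant", "hif_mutant_N_vs_H", "control_H_vs_hif_mutant_H"),
    "err": ("ED", "err_mutant", "err_mutant_N_vs_H", "control_H_vs_err_mutant_H"),
    "double": (
        "DM",
        "double_mutant",
        "double_mutant_N_vs_H",
        "control_H_vs_double_mutant_H",
    ),
}


@dataclass
class SchemeInputs:
    """The three gene sets feeding one factor's classification scheme."""

    total_h: GeneSet
    factor_independent: GeneSet
    cross_h: GeneSet
    factor_name: str = "factor"


@dataclass
class DependencyCalls:
    """Per-probe flags produced by one scheme run.

    ``flags`` is a DataFrame indexed by probe with boolean columns
    in_total, independent_H, candidate_set2, dependent_H plus the direction
    of the hypoxic response in the control background. The named sets are
    also exposed directly.
    """

    factor_name: str
    flags: pd.DataFrame
    independent_set: GeneSet
    candidate_set2: GeneSet
    dependent_set: GeneSet

    def __post_init__(self) -> None:
        f = self.flags
        if (f["independent_H"] & f["dependent_H"]).any():
            raise ValueError("independent and dependent calls must be exclusive")


def _directions_compatible(total_dir: str, other_dir: str, kind: str) -> bool:
    """Direction concordance for intersections.

    For the factor-independent intersection the mutant must respond the
    same way as the control ("same"). For the cross comparison
    (control-H vs mutant-H, oriented mutant-relative-to-control) a
    hypoxia-up transcript that needs the factor must be *lower* in the
    mutant, i.e. the cross direction is opposite ("opposite").
    """
    if kind == "same":
        return total_dir == other_dir
    return total_dir != other_dir


def classify_factor(
    inputs: SchemeInputs,
    direction_mode: str = "ignore",
    universe=None,
) -> DependencyCalls:
    """Run the dual-evidence scheme for one factor.

    independent_H = total_h ∩ factor_independent;
    candidate_set2 = total_h − independent_H;
    dependent_H = cross_h ∩ candidate_set2.

    ``direction_mode`` — "ignore" intersects on membership alone;
    "concordant" additionally requires compatible directions (same
    direction for the independent intersection, opposite for the cross
    intersection, the cross comparison being oriented mutant relative to
    control).
    """
    if direction_mode not in ("ignore", "concordant"):
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    total = inputs.total_h
    indep = inputs.factor_independent
    cross = inputs.cross_h
    if universe is not None:
        universe = set(universe)
        for gs in (total, indep, cross):
            stray = gs.ids - universe
            if stray:
                raise ValueError(
                    f"set {gs.name!r} has probes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def _indep_ok(p: str) -> bool:
        if p not in indep:
            return False
        if direction_mode == "concordant":
            return _directions_compatible(total.direction(p), indep.direction(p), "same")
        return True

    def _cross_ok(p: str) -> bool:
        if p not in cross:
            return False
        if direction_mode == "concordant":
            return _directions_compatible(
                total.direction(p), cross.direction(p), "opposite"
            )
        return True

    independent_ids = {p for p in total.members if _indep_ok(p)}
    set2_ids = set(total.members) - independent_ids
    dependent_ids = {p for p in set2_ids if _cross_ok(p)}

    name = inputs.factor_name
    independent_set = total.subset(independent_ids, f"{name}_independent_H")
    candidate_set2 = total.subset(set2_ids, f"{name}_dependent_set2")
    dependent_set = total.subset(dependent_ids, f"{name}_dependent_H")

    probes = sorted(total.members)
    flags = pd.DataFrame(
        {
            "in_total": True,
            "independent_H": [p in independent_ids for p in probes],
            "candidate_set2": [p in set2_ids for p in probes],
            "dependent_H": [p in dependent_ids for p in probes],
            "direction": [total.direction(p) for p in probes],
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return DependencyCalls(
        factor_name=name,
        flags=flags,
        independent_set=independent_set,
        candidate_set2=candidate_set2,
        dependent_set=dependent_set,
    )


@dataclass
class SchemeResult:
    """Everything produced by a full multi-factor scheme run."""

    de: dict[str, pd.DataFrame]
    sets: dict[str, GeneSet]
    calls: dict[str, DependencyCalls]
    policies: dict[str, ThresholdPolicy] = field(default_factory=dict)


def run_full_scheme(
    matrix: ExpressionMatrix,
    de_config: DEConfig | None = None,
    policies: dict[str, ThresholdPolicy] | None = None,
    schemes=("hif", "err", "double"),
    direction_mode: str = "ignore",
) -> SchemeResult:
    """Run every comparison and classification scheme on one matrix.

    Produces the Total set, each factor's independent / set2 / dependent
    sets, and the named HI / HD / ED / DM sets. HI is the
    HIF-scheme-independent set; HD, ED and DM are the dependent sets of the
    HIF, ERR and double-mutant schemes. HI and HD are mutually exclusive by
    construction.
    """
    de_config = de_config or DEConfig()
    policies = {**DEFAULT_POLICIES, **(policies or {})}
    present = matrix.genotypes_present()
    if "control" not in present:
        raise ValueError("the control genotype is required")
    needed = {"control_N_vs_H"}
    for scheme in schemes:
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        _, mutant, indep_cmp, cross_cmp = SCHEMES[scheme]
        if mutant not in present:
            raise ValueError(f"scheme {scheme!r} needs genotype {mutant!r}")
        needed |= {indep_cmp, cross_cmp}

    de: dict[str, pd.DataFrame] = {}
    sets: dict[str, GeneSet] = {}
    for cmp_name in sorted(needed, key=list(COMPARISONS).index):
        group_a, group_b = COMPARISONS[cmp_name]
        result = differential_expression(matrix, group_a, group_b, de_config)
        de[cmp_name] = result
        sets[cmp_name] = call_differential(result, policies[cmp_name], cmp_name)

    total = GeneSet("total_H", dict(sets["control_N_vs_H"].members))
    sets["total_H"] = total

    calls: dict[str, DependencyCalls] = {}
    for scheme in schemes:
        label, _, indep_cmp, cross_cmp = SCHEMES[scheme]
        inputs = SchemeInputs(
            total_h=total,
            factor_independent=sets[indep_cmp],
            cross_h=sets[cross_cmp],
            factor_name=scheme,
        )
        result = classify_factor(inputs, direction_mode, universe=matrix.probe_ids)
        calls[scheme] = result
        sets[f"{scheme}_independent_H"] = result.independent_set
        sets[f"{scheme}_dependent_set1"] = sets[cross_cmp]
        sets[f"{scheme}_dependent_set2"] = result.candidate_set2
        sets[label] = GeneSet(label, dict(result.dependent_set.members))
        if scheme == "hif":
            sets["HI"] = GeneSet("HI", dict(result.independent_set.members))

    return SchemeResult(de=de, sets=sets, calls=calls, policies=policies)


def concordance_calls(
    results: dict[str, pd.DataFrame],
    strict_q: float = 0.01,
    relaxed_q: dict[str, float] | None = None,
    min_abs_fold: float = 1.5,
) -> pd.DataFrame:
    """Tri-state (up / down / none) hypoxic-response calls per genotype.

    ``results`` maps genotype -> its N-vs-H differential result. Each
    genotype uses the strict q gate unless ``relaxed_q`` supplies a looser
    one for it; the gate actually used is recorded. A relaxed gate tighter
    than the strict gate is rejected.
    """
    relaxed_q = relaxed_q or {}
    for genotype, q in relaxed_q.items():
        if q < strict_q:
            raise ValueError(
                f"relaxed gate for {genotype!r} ({q}) is tighter than strict ({strict_q})"
            )
    frames = []
    for genotype, result in results.items():
        gate = relaxed_q.get(genotype, strict_q)
        gate_used = "relaxed" if genotype in relaxed_q else "strict"
        fold = result["fold_change_signed"]
        sig = (fold.abs() >= min_abs_fold) & (result["q_value"] < gate)
        state = pd.Series("none", index=result.index, dtype=object)
        state[sig & (fold > 0)] = "up"
        state[sig & (fold < 0)] = "down"
        frames.append(
            pd.DataFrame(
                {
                    "genotype": genotype,
                    "state": state,
                    "gate_used": gate_used,
                    "gate_q": gate,
                }
            )
        )
    out = pd.concat(frames)
    out.index.name = "probe_id"
    return out.reset_index()
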