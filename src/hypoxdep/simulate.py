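"""Synthetic datasets with planted factor-dependency ground truth.

The generator emulates the statistical structure the analysis assumes:
a 4-genotype x 2-oxygen factorial expression matrix with replicate samples,
log2-scale intensities carrying additive Gaussian noise, and planted probe
classes whose hypoxic induction requires HIF, ERR, both, either, or
neither. It also produces a metabolite table with below-detection censoring
and per-sample protein masses, and a qPCR CT table tied to a constant
reference gene — so every downstream stage can be tested against known
truth without any external download.

Dependency classes and the genotypes in which their hypoxic effect is
realised (a factor must be *functional* for a dependent effect):

======================  ==============================================
class                   genotypes showing the hypoxic effect
======================  ==============================================
HI                      all (independent of both factors)
HD                      control, err_mutant        (needs HIF)
ED                      control, hif_mutant        (needs ERR)
HD_ED                   control                    (needs both)
DM_only                 all but double_mutant      (either suffices)
negative_regulation     all; amplified where the named repressor is absent
null                    none
======================  ==============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ERR_FUNCTIONAL,
    GENOTYPES,
    HIF_FUNCTIONAL,
    OXYGEN_LEVELS,
    ExpressionMatrix,
)

__all__ = [
    "SimulationConfig",
    "DEPENDENCY_CLASSES",
    "generate_expression",
    "generate_metabolites",
    "generate_ct",
    "MetaboliteTable",
]

DEPENDENCY_CLASSES = (
    "HI",
    "HD",
    "ED",
    "HD_ED",
    "DM_only",
    "negative_regulation",
    "null",
)

_CLASS_GENOTYPES = {
    "HI": frozenset(GENOTYPES),
    "HD": HIF_FUNCTIONAL,
    "ED": ERR_FUNCTIONAL,
    "HD_ED": frozenset({"control"}),
    "DM_only": frozenset({"control", "hif_mutant", "err_mutant"}),
    "null": frozenset(),
}

#: genotypes lacking each factor (used by the negative-regulation class)
_FACTOR_ABSENT = {
    "hif": frozenset({"hif_mutant", "double_mutant"}),
    "err": frozenset({"err_mutant", "double_mutant"}),
}


@dataclass
class SimulationConfig:
    """Study-design parameters for all three synthetic datasets.

    Expression: ``n_probes`` probes over ``genotypes`` x (normoxia,
    hypoxia) cells with ``replicates_per_cell`` biological replicates
    (>= 3 in the reference design). ``class_fractions`` assigns dependency
    classes; the remainder is the null class. Hypoxic effect magnitudes
    (log2) are drawn uniformly from ``effect_log2`` with ``p_down``
    probability of being a repression; baselines are Gaussian
    ``baseline_log2`` = (mean, sd); noise is additive Gaussian with
    ``noise_sd`` (log2 units). The 0.25 default for noise_sd is a choice —
    within-group array variance is rarely published — sized so that planted
    effects above the 1.5-fold gate are recoverable but not saturated.

    Metabolites: ``n_compounds`` compounds, ``met_replicates`` per group
    (six in the reference design), lognormal abundances with coefficient of
    variation ``met_cv``, censored below ``detection_floor``;
    ``met_fraction_shifted`` compounds get a hypoxic shift of
    ``met_effect_log2`` log2 units in every genotype.

    qPCR: CT values are ``ct_baseline`` - log2(relative expression) plus
    Gaussian noise ``ct_noise_sd`` cycles; ``ct_reference`` is constant
    across conditions and ``ct_effects`` maps each target gene to its
    hypoxic log2 induction (applied in every genotype).
    """

    n_probes: int = 2000
    replicates_per_cell: int = 3
    genotypes: tuple[str, ...] = GENOTYPES
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"HD": 0.05, "HI": 0.05, "ED": 0.05}
    )
    effect_log2: tuple[float, float] = (0.8, 3.0)
    p_down: float = 0.5
    baseline_log2: tuple[float, float] = (7.0, 1.5)
    noise_sd: float = 0.25
    seed: int = 0
    neg_reg_amplification: float = 2.0

    n_compounds: int = 60
    met_replicates: int = 6
    met_cv: float = 0.25
    met_fraction_shifted: float = 0.2
    met_effect_log2: float = 1.5
    detection_floor: float = 5.0
    protein_mass_mean: float = 100.0
    protein_mass_cv: float = 0.1

    ct_reference: str = "rp49"
    ct_baseline: float = 22.0
    ct_effects: dict[str, float] = field(
        default_factory=lambda: {"ldh": 2.0, "fatiga": 3.0, "pfk": 1.0}
    )
    ct_noise_sd: float = 0.15
    ct_replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 2:
            raise ValueError("replicates_per_cell must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.genotypes:
            raise ValueError("at least one genotype required")
        unknown = set(self.genotypes) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotypes: {sorted(unknown)}")
        bad = set(self.class_fractions) - set(DEPENDENCY_CLASSES)
        if bad:
            raise ValueError(f"unknown dependency classes: {sorted(bad)}")
        total = sum(self.class_fractions.values())
        if total > 1 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be nonnegative")


@dataclass
class MetaboliteTable:
    """Compound x sample abundances with detection flags and protein mass.

    ``abundance`` holds NaN wherever ``detected`` is False (value-masked
    censoring); ``protein_mass`` is micrograms of protein per sample;
    ``processing`` records which pipeline stages have been applied.
    """

    abundance: pd.DataFrame
    detected: pd.DataFrame
    samples: pd.DataFrame
    protein_mass: pd.Series
    processing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.detected.index) or not list(
            self.abundance.columns
        ) == list(self.detected.columns):
            raise ValueError("abundance and detected tables must align")
        masked_ok = self.abundance.to_numpy()[~self.detected.to_numpy()]
        if "imputed" not in self.processing and not np.isnan(masked_ok).all():
            raise ValueError("undetected entries must be value-masked (NaN)")

    def copy_with(self, abundance: pd.DataFrame, stage: str) -> "MetaboliteTable":
        return MetaboliteTable(
            abundance=abundance,
            detected=self.detected.copy(),
            samples=self.samples.copy(),
            protein_mass=self.protein_mass.copy(),
            processing=self.processing + (stage,),
        )


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    n = config.n_probes
    labels = np.array(["null"] * n, dtype=object)
    start = 0
    for cls in DEPENDENCY_CLASSES:
        frac = config.class_fractions.get(cls, 0.0)
        count = int(round(frac * n))
        labels[start : start + count] = cls
        start += count
    perm = rng.permutation(n)
    return pd.Series(labels[perm])


def _effect_realised(cls: str, genotype: str, repressor: str) -> bool:
    if cls == "negative_regulation":
        return True
    return genotype in _CLASS_GENOTYPES[cls]


def generate_expression(config: SimulationConfig):
    """Simulate the factorial expression matrix with planted truth.

    Returns ``(matrix, truth)``. ``truth`` is a DataFrame indexed by
    probe_id with columns dependency_class, direction, effect_log2 (the
    signed magnitude) and one ``effect_<genotype>`` column per genotype
    giving the realised hypoxic effect in that background; null probes have
    zero effect everywhere.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probe_ids = [f"probe_{i:05d}" for i in range(n)]

    classes = _assign_classes(config, rng)
    lo, hi = config.effect_log2
    magnitude = rng.uniform(lo, hi, size=n)
    sign = np.where(rng.random(n) < config.p_down, -1.0, 1.0)
    effect = magnitude * sign
    effect[classes.to_numpy() == "null"] = 0.0
    repressor = rng.choice(["hif", "err"], size=n)

    baseline = rng.normal(config.baseline_log2[0], config.baseline_log2[1], size=n)

    sample_rows = []
    columns = {}
    truth_effects = {g: np.zeros(n) for g in config.genotypes}
    for genotype in config.genotypes:
        realised = np.zeros(n)
        for cls in DEPENDENCY_CLASSES:
            mask = (classes == cls).to_numpy()
            if not mask.any():
                continue
            if cls == "null":
                continue
            if cls == "negative_regulation":
                amp = np.where(
                    np.array([genotype in _FACTOR_ABSENT[r] for r in repressor]),
                    config.neg_reg_amplification,
                    1.0,
                )
                realised[mask] = effect[mask] * amp[mask]
            elif genotype in _CLASS_GENOTYPES[cls]:
                realised[mask] = effect[mask]
        truth_effects[genotype] = realised
        for oxygen in OXYGEN_LEVELS:
            shift = realised if oxygen == "hypoxia" else 0.0
            for rep in range(1, config.replicates_per_cell + 1):
                sample_id = f"{genotype}_{oxygen}_r{rep}"
                noise = (
                    rng.normal(0.0, config.noise_sd, size=n)
                    if config.noise_sd > 0
                    else np.zeros(n)
                )
                columns[sample_id] = baseline + shift + noise
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "genotype": genotype,
                        "oxygen": oxygen,
                        "replicate": rep,
                    }
                )

    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    samples = pd.DataFrame(sample_rows)
    matrix = ExpressionMatrix(values=values, samples=samples)

    truth = pd.DataFrame(
        {
            "dependency_class": classes.to_numpy(),
            "direction": np.where(effect > 0, "up", np.where(effect < 0, "down", "none")),
            "effect_log2": effect,
            "repressor": np.where(
                classes.to_numpy() == "negative_regulation", repressor, ""
            ),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    for g in config.genotypes:
        truth[f"effect_{g}"] = truth_effects[g]
    return matrix, truth


def expected_dependency_sets(
    truth: pd.DataFrame, min_abs_fold: float = 1.5
) -> dict[str, set[str]]:
    """Scheme-level expected memberships implied by the planted effects.

    The dual-evidence scheme classifies by *realised* responses, so a
    planted ED probe (responsive in control and in the HIF mutant) belongs
    in the HIF-independent set as well as in the ED set. This derives, per
    factor, the noise-free expectation from the per-genotype effect
    columns: a probe is in the total set when its control effect clears the
    fold gate; factor-independent when the mutant effect also clears it;
    factor-dependent when it is in the total set, not independent, and the
    control-vs-mutant hypoxic difference clears the gate.

    Returns sets keyed "total", "HI", "HD", "ED", "DM" (only for genotypes
    whose effect columns are present).
    """
    gate = np.log2(min_abs_fold)
    e_control = truth["effect_control"]
    out: dict[str, set[str]] = {"total": set(truth.index[e_control.abs() >= gate])}
    factor_map = {"HI": None, "HD": "hif_mutant", "ED": "err_mutant", "DM": "double_mutant"}
    for label, mutant in factor_map.items():
        col = f"effect_{mutant}" if mutant else "effect_hif_mutant"
        if col not in truth.columns:
            continue
        e_mut = truth[col]
        in_total = e_control.abs() >= gate
        independent = in_total & (e_mut.abs() >= gate)
        if label == "HI":
            out["HI"] = set(truth.index[independent])
            continue
        cross = (e_control - e_mut).abs() >= gate
        out[label] = set(truth.index[in_total & ~independent & cross])
    return out


def generate_metabolites(config: SimulationConfig):
    """Simulate a metabolite table with below-detection censoring.

    Returns ``(table, truth)`` where truth holds the per-compound,
    per-group true mean abundances (linear scale, before protein
    normalisation). Abundances are lognormal around group means; entries
    below ``detection_floor`` are flagged undetected and value-masked.
    """
    if config.detection_floor <= 0:
        raise ValueError("detection_floor must be positive")
    rng = np.random.default_rng(config.seed + 1)
    compounds = [f"compound_{i:03d}" for i in range(config.n_compounds)]
    groups = [(g, o) for g in config.genotypes for o in OXYGEN_LEVELS]

    # base abundance spans detection regimes: some compounds sit near the floor
    log_mean = rng.uniform(
        np.log(config.detection_floor * 0.2),
        np.log(config.detection_floor * 200.0),
        size=config.n_compounds,
    )
    shifted = rng.random(config.n_compounds) < config.met_fraction_shifted
    shift_sign = np.where(rng.random(config.n_compounds) < 0.5, -1.0, 1.0)

    sigma = np.sqrt(np.log1p(config.met_cv**2))
    truth_rows = []
    columns = {}
    sample_rows = []
    for genotype, oxygen in groups:
        mean = np.exp(log_mean)
        if oxygen == "hypoxia":
            mean = mean * np.where(
                shifted, 2.0 ** (shift_sign * config.met_effect_log2), 1.0
            )
        truth_rows.append(
            pd.Series(mean, index=compounds, name=f"{genotype}_{oxygen}")
        )
        for rep in range(1, config.met_replicates + 1):
            sample_id = f"{genotype}_{oxygen}_m{rep}"
            draw = mean * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(compounds)))
            columns[sample_id] = draw
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "genotype": genotype,
                    "oxygen": oxygen,
                    "replicate": rep,
                }
            )

    abundance = pd.DataFrame(columns, index=pd.Index(compounds, name="compound"))
    detected = abundance >= config.detection_floor
    abundance = abundance.where(detected)
    samples = pd.DataFrame(sample_rows)
    protein = pd.Series(
        rng.normal(
            config.protein_mass_mean,
            config.protein_mass_mean * config.protein_mass_cv,
            size=len(samples),
        ).clip(min=1.0),
        index=samples["sample_id"].to_list(),
        name="protein_mass",
    )
    table = MetaboliteTable(
        abundance=abundance, detected=detected, samples=samples, protein_mass=protein
    )
    truth = pd.concat(truth_rows, axis=1)
    truth.index.name = "compound"
    return table, truth


def generate_ct(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a long-form qPCR CT table.

    CT = ct_baseline - log2(relative expression) + noise; the reference
    gene has constant unit expression in every sample, so its CT is flat up
    to noise. Target genes are induced in hypoxia by their configured log2
    effect in every genotype. Returns a DataFrame with columns sample_id,
    genotype, oxygen, replicate, gene, ct and ``attrs['reference_gene']``.
    """
    if not config.ct_reference:
        raise ValueError("a reference gene is required")
    if config.ct_reference in config.ct_effects:
        raise ValueError("reference gene cannot also be a target")
    rng = np.random.default_rng(config.seed + 2)
    genes = {config.ct_reference: 0.0, **config.ct_effects}
    rows = []
    for genotype in config.genotypes:
        for oxygen in OXYGEN_LEVELS:
            for rep in range(1, config.ct_replicates + 1):
                sample_id = f"{genotype}_{oxygen}_q{rep}"
                for gene, effect in genes.items():
                    log2_expr = 0.0
                    if gene != config.ct_reference and oxygen == "hypoxia":
                        log2_expr = effect
                    noise = (
                        rng.normal(0.0, config.ct_noise_sd)
                        if config.ct_noise_sd > 0
                        else 0.0
                    )
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "genotype": genotype,
                            "oxygen": oxygen,
                            "replicate": rep,
                            "gene": gene,
                            "ct": config.ct_baseline - log2_expr + noise,
                        }
                    )
    ct = pd.DataFrame(rows)
    ct.attrs["reference_gene"] = config.ct_reference
    return ct
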