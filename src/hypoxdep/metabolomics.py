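"""Metabolite-table stages: censoring imputation, protein normalisation,
heat-map ratios, and per-compound ANOVA with contrasts.

Pipeline order is impute -> protein-normalise -> log -> ANOVA; the later
stages check the table's ``processing`` record and refuse to run on
value-masked (still-censored) data.

The imputation rule has two branches, applied per compound and replicate
group: when *every* replicate of a group is below detection, each gets the
global minimum detected value across all compounds (a post-hoc detection
floor); when at least one replicate was detected, missing replicates get
that compound's minimum detected value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import MetaboliteTable

__all__ = [
    "impute_below_detection",
    "normalize_protein",
    "relative_log2",
    "anova_contrasts",
    "default_contrasts",
]


def _group_columns(table: MetaboliteTable) -> dict[tuple[str, str], list[str]]:
    groups: dict[tuple[str, str], list[str]] = {}
    for _, row in table.samples.iterrows():
        groups.setdefault((row["genotype"], row["oxygen"]), []).append(row["sample_id"])
    return groups


def impute_below_detection(table: MetaboliteTable) -> MetaboliteTable:
    """Fill value-masked (below-detection) entries.

    All-undetected groups receive the global minimum detected value across
    every compound; partially detected groups receive the compound's
    minimum detected value. Detected entries are never altered.
    """
    detected_values = table.abundance.to_numpy()[table.detected.to_numpy()]
    if detected_values.size == 0:
        raise ValueError("entire table is below detection; nothing to anchor on")
    global_min = float(np.nanmin(detected_values))

    abundance = table.abundance.copy()
    compound_min = table.abundance.where(table.detected).min(axis=1)
    for compound in abundance.index:
        for _, cols in _group_columns(table).items():
            det = table.detected.loc[compound, cols]
            if det.all():
                continue
            if not det.any() and np.isnan(compound_min[compound]):
                fill = global_min
            elif det.any():
                fill = float(compound_min[compound])
            else:
                # group fully undetected but the compound was seen elsewhere:
                # the rule's "five or less undetectable" branch is per group,
                # so a fully dark group still falls back to the global floor
                fill = global_min
            missing = det.index[~det]
            abundance.loc[compound, missing] = fill
    return table.copy_with(abundance, "imputed")


def normalize_protein(table: MetaboliteTable) -> MetaboliteTable:
    """Divide each sample's abundances by its protein mass (counts/µg)."""
    protein = table.protein_mass.reindex(table.abundance.columns)
    if protein.isna().any():
        missing = protein.index[protein.isna()].tolist()
        raise ValueError(f"samples missing protein mass: {missing[:5]}")
    if (protein <= 0).any():
        raise ValueError("protein mass must be positive for every sample")
    return table.copy_with(table.abundance / protein, "protein_normalized")


def _require_imputed(table: MetaboliteTable, stage: str) -> None:
    if table.abundance.isna().any().any():
        raise ValueError(f"{stage} requires an imputed table (masked values remain)")


def relative_log2(
    table: MetaboliteTable,
    reference: tuple[str, str] = ("control", "normoxia"),
) -> pd.DataFrame:
    """Heat-map values: log2 of each group mean over the reference mean.

    Group means are arithmetic on the (linear) normalised scale and then
    logged, so the reference group column is identically zero.
    """
    _require_imputed(table, "relative_log2")
    groups = _group_columns(table)
    if reference not in groups:
        raise ValueError(f"reference group {reference} absent from the table")
    ref_mean = table.abundance[groups[reference]].mean(axis=1)
    if (ref_mean <= 0).any():
        raise ValueError("reference group mean must be positive for every compound")
    out = {}
    for (genotype, oxygen), cols in groups.items():
        out[f"{genotype}_{oxygen}"] = np.log2(
            table.abundance[cols].mean(axis=1) / ref_mean
        )
    result = pd.DataFrame(out, index=table.abundance.index)
    result.attrs["reference"] = reference
    result.attrs["processing"] = list(table.processing)
    return result


def default_contrasts(table: MetaboliteTable) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Within-genotype oxygen contrasts plus control-vs-mutant within oxygen."""
    groups = set(_group_columns(table))
    genotypes = {g for g, _ in groups}
    contrasts = []
    for g in sorted(genotypes):
        if (g, "normoxia") in groups and (g, "hypoxia") in groups:
            contrasts.append(((g, "normoxia"), (g, "hypoxia")))
    for g in sorted(genotypes - {"control"}):
        for ox in ("normoxia", "hypoxia"):
            if ("control", ox) in groups and (g, ox) in groups:
                contrasts.append((("control", ox), (g, ox)))
    return contrasts


def anova_contrasts(
    table: MetaboliteTable,
    contrasts: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """One-way ANOVA per compound with pairwise contrasts on log2 values.

    Fits one model per compound across all genotype x oxygen groups; each
    contrast's t uses the pooled within-group mean square (error df
    N - k), two-sided. q-values are Benjamini-Hochberg within each
    contrast across compounds. Returns a long DataFrame with columns
    compound, contrast, log2_diff, anova_F, anova_p, p_value, q_value.
    """
    _require_imputed(table, "anova_contrasts")
    groups = _group_columns(table)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for key, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {key} has fewer than 2 replicates")
    contrasts = contrasts or default_contrasts(table)
    for a, b in contrasts:
        if a not in groups or b not in groups:
            raise ValueError(f"contrast {a} vs {b} references a missing group")

    log_values = np.log2(table.abundance)
    if not np.isfinite(log_values.to_numpy()).all():
        raise ValueError("nonpositive abundances; normalise/impute before ANOVA")

    keys = list(groups)
    n_per = {k: len(groups[k]) for k in keys}
    n_total = sum(n_per.values())
    k_groups = len(keys)
    df_error = n_total - k_groups

    rows = []
    for compound in log_values.index:
        by_group = {k: log_values.loc[compound, groups[k]].to_numpy() for k in keys}
        grand = np.concatenate(list(by_group.values())).mean()
        ss_between = sum(n_per[k] * (by_group[k].mean() - grand) ** 2 for k in keys)
        ss_within = sum(((by_group[k] - by_group[k].mean()) ** 2).sum() for k in keys)
        ms_within = ss_within / df_error
        if ms_within == 0:
            f_stat = 0.0 if ss_between == 0 else np.inf
        else:
            f_stat = (ss_between / (k_groups - 1)) / ms_within
        anova_p = float(stats.f.sf(f_stat, k_groups - 1, df_error)) if np.isfinite(f_stat) else 0.0
        if f_stat == 0:
            anova_p = 1.0
        for a, b in contrasts:
            diff = by_group[b].mean() - by_group[a].mean()
            se = np.sqrt(ms_within * (1.0 / n_per[a] + 1.0 / n_per[b]))
            if se == 0:
                t_stat = 0.0 if diff == 0 else np.sign(diff) * np.inf
            else:
                t_stat = diff / se
            p = float(2 * stats.t.sf(abs(t_stat), df_error)) if np.isfinite(t_stat) else 0.0
            if t_stat == 0:
                p = 1.0
            rows.append(
                {
                    "compound": compound,
                    "contrast": f"{a[0]}_{a[1]}_vs_{b[0]}_{b[1]}",
                    "log2_diff": diff,
                    "anova_F": f_stat,
                    "anova_p": anova_p,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    for contrast, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "q_value"] = multipletests(out.loc[idx, "p_value"], method="fdr_bh")[1]
    out.attrs["processing"] = list(table.processing) + ["log2", "anova_contrasts"]
    return out
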