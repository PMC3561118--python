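"""Relative qPCR quantification against a reference gene.

Expression relative to the reference is 2^-(CT_gene - CT_reference)
(ΔCT with assumed doubling efficiency); hypoxic induction is reported as
the ratio of mean relative expression in hypoxia over normoxia (H/N), with
1.0 meaning no net response. Hypothesis tests run on the ΔCT values
themselves — two-tailed unpaired t-tests with a Bonferroni correction over
a caller-supplied family size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "validate_ct_table",
    "relative_expression",
    "delta_ct",
    "hn_fold_change",
    "delta_ct_tests",
]

_CT_COLUMNS = ("sample_id", "gene", "ct")


def validate_ct_table(ct_table: pd.DataFrame, reference_gene: str | None = None) -> str:
    """Check the long-form CT table and return the reference gene name."""
    missing = [c for c in _CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    reference_gene = reference_gene or ct_table.attrs.get("reference_gene")
    if not reference_gene:
        raise ValueError("no reference gene given (argument or table attrs)")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    ref_samples = set(ct_table.loc[ct_table["gene"] == reference_gene, "sample_id"])
    all_samples = set(ct_table["sample_id"])
    absent = sorted(all_samples - ref_samples)
    if absent:
        raise ValueError(
            f"reference gene {reference_gene!r} missing in samples: {absent[:5]}"
        )
    return reference_gene


def delta_ct(
    ct_table: pd.DataFrame, gene: str, reference_gene: str | None = None
) -> pd.DataFrame:
    """Per-sample ΔCT = CT_gene - CT_reference with sample annotations."""
    reference_gene = validate_ct_table(ct_table, reference_gene)
    gene_rows = ct_table[ct_table["gene"] == gene]
    if gene_rows.empty:
        raise ValueError(f"gene {gene!r} absent from the CT table")
    ref_rows = ct_table[ct_table["gene"] == reference_gene]
    meta_cols = [
        c for c in ct_table.columns if c not in ("gene", "ct")
    ]
    merged = gene_rows[meta_cols + ["ct"]].merge(
        ref_rows[["sample_id", "ct"]],
        on="sample_id",
        suffixes=("_gene", "_ref"),
    )
    if len(merged) < len(gene_rows):
        raise ValueError(f"reference measurement missing for some samples of {gene!r}")
    merged["delta_ct"] = merged["ct_gene"] - merged["ct_ref"]
    return merged


def relative_expression(
    ct_table: pd.DataFrame, gene: str, reference_gene: str | None = None
) -> pd.DataFrame:
    """Per-sample expression of ``gene`` relative to the reference.

    Returns the ΔCT frame with an added ``relative_expression`` column
    equal to 2^-ΔCT.
    """
    out = delta_ct(ct_table, gene, reference_gene)
    out["relative_expression"] = np.exp2(-out["delta_ct"])
    return out


def hn_fold_change(
    rel: pd.DataFrame,
    oxygen_column: str = "oxygen",
    value_column: str = "relative_expression",
) -> float:
    """Mean hypoxic over mean normoxic relative expression (H/N ratio)."""
    if oxygen_column not in rel.columns:
        raise ValueError(f"column {oxygen_column!r} absent")
    h = rel.loc[rel[oxygen_column] == "hypoxia", value_column]
    n = rel.loc[rel[oxygen_column] == "normoxia", value_column]
    if h.empty or n.empty:
        raise ValueError("both oxygen groups must be present")
    return float(h.mean() / n.mean())


def _match(df: pd.DataFrame, selector: dict) -> pd.DataFrame:
    mask = pd.Series(True, index=df.index)
    for column, value in selector.items():
        if column not in df.columns:
            raise ValueError(f"selector column {column!r} absent from CT table")
        mask &= df[column] == value
    return df[mask]


def delta_ct_tests(
    ct_table: pd.DataFrame,
    comparisons: list[dict],
    m_tests: int,
    reference_gene: str | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Bonferroni-adjusted two-tailed unpaired t-tests on ΔCT values.

    Each comparison is a dict with keys ``gene``, ``group_a`` and
    ``group_b`` (the groups are column->value selectors over the sample
    annotations). ``m_tests`` is the Bonferroni family size and must cover
    every comparison made; adjusted p = min(1, p * m_tests). ``equal_var``
    selects the classic pooled t-test (default) or Welch.
    """
    if m_tests < len(comparisons):
        raise ValueError("m_tests must be at least the number of comparisons")
    rows = []
    for cmp in comparisons:
        d = delta_ct(ct_table, cmp["gene"], reference_gene)
        a = _match(d, cmp["group_a"])["delta_ct"].to_numpy()
        b = _match(d, cmp["group_b"])["delta_ct"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"comparison on {cmp['gene']!r} has fewer than 2 replicates per side"
            )
        if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and np.isclose(
            a.mean(), b.mean()
        ):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "gene": cmp["gene"],
                "group_a": str(cmp["group_a"]),
                "group_b": str(cmp["group_b"]),
                "n_a": a.size,
                "n_b": b.size,
                "mean_delta_ct_a": a.mean(),
                "mean_delta_ct_b": b.mean(),
                "t_statistic": float(t_stat),
                "p_value": float(p),
                "p_adjusted": min(1.0, float(p) * m_tests),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["m_tests"] = m_tests
    out.attrs["equal_var"] = equal_var
    return out
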