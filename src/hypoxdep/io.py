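"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as tab-delimited probes x samples tables (first
column ``probe_id``) with a companion sample-sheet CSV (sample_id,
genotype, oxygen, replicate). Gene sets use GMT (name, description, then
tab-separated members carrying ``:up``/``:down`` direction suffixes,
sorted for byte-stable output). Metabolite and CT tables are TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import SAMPLE_SHEET_COLUMNS, ExpressionMatrix, GeneSet
from .simulate import MetaboliteTable

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_metabolites",
    "write_metabolites",
    "read_ct",
    "write_ct",
    "read_annotation",
]


def read_expression(matrix_path, sheet_path) -> ExpressionMatrix:
    """Load an expression TSV plus its sample-sheet CSV, with validation."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index.name = "probe_id"
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe rows in {matrix_path}: {dups[:5]}")
    non_numeric = values.columns[
        [values[c].dtype == object for c in values.columns]
    ].tolist()
    if non_numeric:
        raise ValueError(f"non-numeric expression columns: {non_numeric[:5]}")
    samples = pd.read_csv(sheet_path)
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise ValueError(f"sample sheet {sheet_path} missing columns: {missing_cols}")
    absent = sorted(set(values.columns) - set(samples["sample_id"]))
    if absent:
        raise ValueError(f"samples in matrix missing from sheet: {absent}")
    return ExpressionMatrix(values=values, samples=samples)


def write_expression(matrix: ExpressionMatrix, matrix_path, sheet_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t")
    matrix.samples[list(SAMPLE_SHEET_COLUMNS)].to_csv(sheet_path, index=False)


def write_gene_sets(sets, path, descriptions: dict[str, str] | None = None) -> None:
    """Write gene sets as GMT, one line per set, members sorted.

    ``sets`` is an iterable of :class:`GeneSet` (or a name->GeneSet dict).
    Members carry their direction as a ``:up``/``:down`` suffix.
    """
    if isinstance(sets, dict):
        sets = list(sets.values())
    descriptions = descriptions or {}
    lines = []
    for gs in sets:
        desc = descriptions.get(gs.name, "")
        members = [f"{p}:{d}" for p, d in sorted(gs.members.items())]
        lines.append("\t".join([gs.name, desc] + members))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_sets(path) -> dict[str, GeneSet]:
    """Read a GMT file back into named gene sets."""
    sets: dict[str, GeneSet] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        name = fields[0]
        members = {}
        for token in fields[2:]:
            if ":" in token:
                probe, direction = token.rsplit(":", 1)
            else:
                probe, direction = token, "up"
            members[probe] = direction
        sets[name] = GeneSet(name, members)
    return sets


def write_metabolites(table: MetaboliteTable, prefix) -> dict[str, Path]:
    """Write abundance, detection-flag, sample and protein TSVs.

    ``prefix`` is a path stem; four files are produced:
    ``<prefix>_abundance.tsv``, ``<prefix>_detected.tsv``,
    ``<prefix>_samples.tsv`` and ``<prefix>_protein.tsv``.
    """
    prefix = Path(prefix)
    paths = {
        "abundance": prefix.with_name(prefix.name + "_abundance.tsv"),
        "detected": prefix.with_name(prefix.name + "_detected.tsv"),
        "samples": prefix.with_name(prefix.name + "_samples.tsv"),
        "protein": prefix.with_name(prefix.name + "_protein.tsv"),
    }
    table.abundance.to_csv(paths["abundance"], sep="\t")
    table.detected.to_csv(paths["detected"], sep="\t")
    table.samples.to_csv(paths["samples"], sep="\t", index=False)
    table.protein_mass.rename_axis("sample_id").to_csv(paths["protein"], sep="\t")
    return paths


def read_metabolites(prefix) -> MetaboliteTable:
    prefix = Path(prefix)
    abundance = pd.read_csv(
        prefix.with_name(prefix.name + "_abundance.tsv"), sep="\t", index_col=0
    )
    detected = pd.read_csv(
        prefix.with_name(prefix.name + "_detected.tsv"), sep="\t", index_col=0
    ).astype(bool)
    samples = pd.read_csv(prefix.with_name(prefix.name + "_samples.tsv"), sep="\t")
    protein = pd.read_csv(
        prefix.with_name(prefix.name + "_protein.tsv"), sep="\t", index_col=0
    )["protein_mass"]
    return MetaboliteTable(
        abundance=abundance, detected=detected, samples=samples, protein_mass=protein
    )


def write_ct(ct_table: pd.DataFrame, path) -> None:
    out = ct_table.copy()
    out["reference_gene"] = ct_table.attrs.get("reference_gene", "")
    out.to_csv(path, sep="\t", index=False)


def read_ct(path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t")
    if "reference_gene" in ct.columns:
        refs = ct["reference_gene"].dropna().unique()
        if len(refs) == 1:
            ct.attrs["reference_gene"] = refs[0]
        ct = ct.drop(columns=["reference_gene"])
    return ct


def read_annotation(path) -> dict[str, set[str]]:
    """Read a term->gene annotation from two-column TSV or GMT.

    Two-column TSV has (term_id, probe_id) rows; GMT is detected by lines
    having a description field (3+ columns where column 2 is not a member
    of column 1's term in any row).
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"annotation file {path} is empty")
    lines = [l for l in text.splitlines() if l.strip()]
    n_fields = {len(l.split("\t")) for l in lines}
    annotation: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt" or min(n_fields) >= 3:
        for line in lines:
            fields = line.split("\t")
            members = {t.rsplit(":", 1)[0] if ":" in t else t for t in fields[2:]}
            annotation[fields[0]] = members
    else:
        for line in lines:
            term, probe = line.split("\t")[:2]
            annotation.setdefault(term, set()).add(probe)
    return annotation
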