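"""Core data containers shared across the pipeline.

The experimental design is a 4 (genotype) x 2 (oxygen) factorial: control
animals, a HIF-alpha mutant, an ERR mutant, and the double mutant, each
assayed in normoxia and after a hypoxic challenge, with replicate biological
samples per cell. Expression values are log2-scale probe intensities as
produced by standard array normalisation (RMA-style), held as a probes x
samples matrix with a parallel sample sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("control", "hif_mutant", "err_mutant", "double_mutant")
OXYGEN_LEVELS = ("normoxia", "hypoxia")

#: genotypes in which each factor is functional
HIF_FUNCTIONAL = frozenset({"control", "err_mutant"})
ERR_FUNCTIONAL = frozenset({"control", "hif_mutant"})

SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "oxygen", "replicate")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (probes x samples) plus sample annotations.

    ``values`` is a DataFrame indexed by probe_id with one column per
    sample_id; ``samples`` is a DataFrame with columns
    (sample_id, genotype, oxygen, replicate), one row per sample, aligned
    with the value columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        sheet_ids = list(self.samples["sample_id"])
        if len(set(sheet_ids)) != len(sheet_ids):
            raise ValueError("duplicate sample ids in sample sheet")
        matrix_ids = list(self.values.columns)
        absent = sorted(set(matrix_ids) - set(sheet_ids))
        if absent:
            raise ValueError(f"samples in matrix missing from sheet: {absent}")
        # order columns to follow the sheet
        self.samples = self.samples[self.samples["sample_id"].isin(matrix_ids)].reset_index(drop=True)
        self.values = self.values[list(self.samples["sample_id"])]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains missing or non-finite values")
        trip = self.samples[["genotype", "oxygen", "replicate"]]
        if trip.duplicated().any():
            raise ValueError("(genotype, oxygen, replicate) triples must be unique")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def group_mask(self, genotype: str, oxygen: str) -> np.ndarray:
        """Boolean mask over sample columns for one genotype x oxygen cell."""
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}")
        if oxygen not in OXYGEN_LEVELS:
            raise ValueError(f"unknown oxygen level {oxygen!r}")
        mask = (self.samples["genotype"] == genotype) & (self.samples["oxygen"] == oxygen)
        return mask.to_numpy()

    def genotypes_present(self) -> set[str]:
        return set(self.samples["genotype"])


@dataclass
class GeneSet:
    """A named, directed probe set.

    ``members`` maps probe_id -> direction ("up" or "down"). Direction
    records the sign of the change in the comparison that produced the set.
    """

    name: str
    members: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a nonempty name")
        if "\t" in self.name:
            raise ValueError("tab characters are not allowed in set names")
        bad = {d for d in self.members.values() if d not in ("up", "down")}
        if bad:
            raise ValueError(f"invalid directions: {sorted(bad)}")

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.members

    def direction(self, probe_id: str) -> str:
        return self.members[probe_id]

    def subset(self, ids, name: str | None = None) -> "GeneSet":
        keep = {p: d for p, d in self.members.items() if p in set(ids)}
        return GeneSet(name or self.name, keep)
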