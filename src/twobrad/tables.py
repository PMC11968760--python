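"""Samples x taxa abundance table with group labels and taxonomic lineages.

The substrate of all comparative statistics: rows are samples, columns are
taxa (relative abundances summing to <= 1 per row, or raw counts), each
sample carries a two-group label (M / H in the reference study design) and
each taxon an optional lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AbundanceMatrix:
    values: pd.DataFrame                 # samples x taxa
    groups: pd.Series                    # sample -> group label
    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = self.groups.reindex(self.values.index)
        if (self.values.values < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate taxon ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_labels(self) -> list[str]:
        return sorted(self.groups.unique())

    def split(self) -> dict[str, pd.DataFrame]:
        """Per-group sub-tables."""
        return {g: self.values.loc[self.groups == g] for g in self.group_labels()}

    def top_taxa(self, k: int) -> list[str]:
        """The k taxa with the largest mean abundance (ties by name)."""
        means = self.values.mean(axis=0)
        order = means.sort_values(ascending=False, kind="mergesort")
        return list(order.index[:k])

    def presence_partition(self) -> dict[str, int]:
        """Venn partition of detected taxa between the two groups.

        A taxon is detected in a group if any of its samples has abundance
        > 0.  Satisfies |A-only| + |B-only| + |shared| = |union|.
        """
        groups = self.group_labels()
        if len(groups) != 2:
            raise ValueError("presence partition requires exactly two groups")
        a, b = groups
        split = self.split()
        in_a = set(self.values.columns[(split[a] > 0).any(axis=0)])
        in_b = set(self.values.columns[(split[b] > 0).any(axis=0)])
        return {
            f"{a}_only": len(in_a - in_b),
            f"{b}_only": len(in_b - in_a),
            "shared": len(in_a & in_b),
            "union": len(in_a | in_b),
        }

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, matrix_path, metadata_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="sample")
        meta = pd.DataFrame({"sample": self.groups.index, "group": self.groups.values})
        meta.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, metadata_path,
                 lineages: dict[str, dict[str, str]] | None = None) -> "AbundanceMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="sample")
        meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
        return cls(values=values, groups=meta["group"], lineages=lineages or {})


def permuted_labels(matrix: AbundanceMatrix, rng: np.random.Generator) -> AbundanceMatrix:
    """A copy of the matrix with group labels randomly permuted (null model)."""
    perm = rng.permutation(len(matrix.groups))
    shuffled = pd.Series(matrix.groups.values[perm], index=matrix.groups.index)
    return AbundanceMatrix(values=matrix.values.copy(), groups=shuffled,
                           lineages=matrix.lineages)
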