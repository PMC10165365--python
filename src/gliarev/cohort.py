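"""Core data containers for the glial aging-reversal pipeline.

A :class:`CellCohort` holds a sparse genes x cells integer count matrix
together with a per-gene table, a per-cell table, and named normalized
layers appended by downstream stages.  A :class:`CohortDesign` maps sample
ids to (age, treatment, replicate) and derives the four contrast groups of
a 2 age x 2 treatment cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

AGES = ("young", "aged")
TREATMENTS = ("GFP", "IL2")
#: The four design groups, named age+treatment.
GROUPS = ("youngGFP", "youngIL2", "agedGFP", "agedIL2")

REQUIRED_CELL_COLUMNS = ("barcode", "sample", "age", "treatment", "replicate", "celltype")


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


class FormatError(ValueError):
    """Malformed input file or inconsistent tables."""


class DependencyError(RuntimeError):
    """A pipeline stage was run before its upstream stage outputs exist."""


@dataclass
class CohortDesign:
    """Sample -> (age, treatment, replicate) map defining contrast groups."""

    samples: pd.DataFrame  # index: sample id; columns: age, treatment, replicate

    def __post_init__(self) -> None:
        df = self.samples
        for col in ("age", "treatment", "replicate"):
            if col not in df.columns:
                raise FormatError(f"design table missing column {col!r}")
        bad_age = set(df["age"]) - set(AGES)
        if bad_age:
            raise FormatError(f"unknown age levels {sorted(bad_age)}; expected {AGES}")
        bad_trt = set(df["treatment"]) - set(TREATMENTS)
        if bad_trt:
            raise FormatError(f"unknown treatment levels {sorted(bad_trt)}; expected {TREATMENTS}")
        grp = df["age"].astype(str) + df["treatment"].astype(str)
        if grp.size and df.groupby(grp)["replicate"].nunique().lt(df.groupby(grp).size()).any():
            raise FormatError("replicate labels must be unique within each age x treatment group")

    @property
    def group_of_sample(self) -> pd.Series:
        return self.samples["age"].astype(str) + self.samples["treatment"].astype(str)

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ParameterError(f"unknown group {group!r}; expected one of {GROUPS}")
        g = self.group_of_sample
        return list(g.index[g == group])

    @classmethod
    def from_cell_table(cls, cell_table: pd.DataFrame) -> "CohortDesign":
        """Derive the design from per-cell metadata columns."""
        cols = ["sample", "age", "treatment", "replicate"]
        df = cell_table[cols].drop_duplicates().set_index("sample")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"sample {dup!r} has inconsistent age/treatment/replicate metadata")
        return cls(df)


@dataclass
class CellCohort:
    """Sparse counts plus per-gene and per-cell metadata.

    ``counts`` is genes x cells, nonnegative integers.  ``gene_table`` has at
    least columns gene_id, symbol, is_mitochondrial and is indexed 0..n_genes-1;
    ``cell_table`` has the columns in :data:`REQUIRED_CELL_COLUMNS` plus any
    columns appended by pipeline stages (total_counts, mito_fraction, cluster,
    dam_score, is_dam, pseudotime, branch).  ``layers`` holds dense or sparse
    normalized matrices of the same shape as ``counts``.
    """

    counts: sp.spmatrix
    gene_table: pd.DataFrame
    cell_table: pd.DataFrame
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_table = self.gene_table.reset_index(drop=True)
        self.cell_table = self.cell_table.reset_index(drop=True)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        ng, nc = self.counts.shape
        if len(self.gene_table) != ng:
            raise FormatError(
                f"gene_table has {len(self.gene_table)} rows but counts has {ng} genes"
            )
        if len(self.cell_table) != nc:
            raise FormatError(
                f"cell_table has {len(self.cell_table)} rows but counts has {nc} cells"
            )
        for col in ("gene_id", "symbol", "is_mitochondrial"):
            if col not in self.gene_table.columns:
                raise FormatError(f"gene_table missing column {col!r}")
        for col in REQUIRED_CELL_COLUMNS:
            if col not in self.cell_table.columns:
                raise FormatError(f"cell_table missing column {col!r}")
        bc = self.cell_table["barcode"]
        if bc.duplicated().any():
            dup = bc[bc.duplicated()].iloc[0]
            raise FormatError(f"duplicate barcode {dup!r}")
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise FormatError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise FormatError("counts are not integral")

    def check_samples(self, design: CohortDesign) -> None:
        unknown = set(self.cell_table["sample"]) - set(design.samples.index)
        if unknown:
            raise FormatError(
                f"cell metadata references sample(s) absent from design: {sorted(unknown)}"
            )

    # -- convenience ----------------------------------------------------
    @property
    def group(self) -> pd.Series:
        """Per-cell design group (age+treatment)."""
        return (self.cell_table["age"].astype(str) + self.cell_table["treatment"].astype(str))

    def cells_of_type(self, celltype: str) -> np.ndarray:
        """Integer indices of cells of the given type."""
        return np.flatnonzero((self.cell_table["celltype"] == celltype).to_numpy())

    def subset_cells(self, idx: np.ndarray) -> "CellCohort":
        sub = CellCohort.__new__(CellCohort)
        sub.counts = sp.csr_matrix(self.counts[:, idx])
        sub.gene_table = self.gene_table.copy()
        sub.cell_table = self.cell_table.iloc[idx].reset_index(drop=True)
        sub.layers = {k: v[:, idx] for k, v in self.layers.items()}
        return sub

    def subset_genes(self, idx: np.ndarray) -> "CellCohort":
        sub = CellCohort.__new__(CellCohort)
        sub.counts = sp.csr_matrix(self.counts[idx, :])
        sub.gene_table = self.gene_table.iloc[idx].reset_index(drop=True)
        sub.cell_table = self.cell_table.copy()
        sub.layers = {k: v[idx, :] for k, v in self.layers.items()}
        return sub

    def copy(self) -> "CellCohort":
        sub = CellCohort.__new__(CellCohort)
        sub.counts = self.counts.copy()
        sub.gene_table = self.gene_table.copy()
        sub.cell_table = self.cell_table.copy()
        sub.layers = {k: v.copy() for k, v in self.layers.items()}
        return sub


@dataclass
class GeneSetCollection:
    """Named gene sets (symbol lists) with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def match(self, symbols: pd.Series) -> tuple[dict[str, np.ndarray], float]:
        """Match member symbols case-insensitively against a gene symbol column.

        Returns (set name -> integer gene indices, overall match rate).
        """
        lookup: dict[str, int] = {}
        for i, s in enumerate(symbols.astype(str)):
            lookup.setdefault(s.lower(), i)
        matched: dict[str, np.ndarray] = {}
        n_tot = n_hit = 0
        for name, members in self.sets.items():
            idx = [lookup[m.lower()] for m in members if m.lower() in lookup]
            n_tot += len(members)
            n_hit += len(idx)
            matched[name] = np.asarray(sorted(set(idx)), dtype=int)
        rate = n_hit / n_tot if n_tot else 0.0
        return matched, rate
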