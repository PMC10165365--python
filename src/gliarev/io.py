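"""Readers and writers: 10x-convention Matrix-Market triplet directories,
single delimited count tables, GMT gene-set collections, and stage CSVs."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .cohort import CellCohort, CohortDesign, FormatError, GeneSetCollection

log = logging.getLogger(__name__)


def read_cohort(
    dir_or_table: str | Path,
    design: CohortDesign | None = None,
    metadata: str | Path | None = None,
    mito_prefix: str = "mt-",
) -> CellCohort:
    """Read a cohort from a triplet directory or a single delimited table.

    A directory must contain matrix.mtx (genes x cells), features.tsv
    (gene_id, symbol[, type]; no header), barcodes.tsv and metadata.tsv.
    A file is read as a wide genes x cells table (first column = gene symbol)
    and requires ``metadata=`` pointing at the per-cell table.  Mitochondrial
    genes are flagged by case-insensitive symbol prefix (default "mt-").
    """
    path = Path(dir_or_table)
    if path.is_dir():
        counts = sp.csr_matrix(mmread(str(path / "matrix.mtx")))
        feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
        gene_table = pd.DataFrame({"gene_id": feats[0], "symbol": feats[1] if 1 in feats else feats[0]})
        try:
            barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
        except pd.errors.EmptyDataError:
            barcodes = pd.Series([], dtype=object)
        meta = pd.read_csv(path / "metadata.tsv", sep="\t")
        if not (meta["barcode"].to_numpy() == barcodes.to_numpy()).all():
            raise FormatError("barcodes.tsv and metadata.tsv disagree on barcode order")
    elif path.is_file():
        wide = pd.read_csv(path, sep=None, engine="python", index_col=0)
        counts = sp.csr_matrix(wide.to_numpy())
        gene_table = pd.DataFrame({"gene_id": wide.index, "symbol": wide.index})
        if metadata is None:
            raise FormatError("single-table input requires a metadata= per-cell table")
        meta = pd.read_csv(metadata, sep="\t")
    else:
        raise FormatError(f"no such cohort input: {path}")

    if counts.shape[1] != len(meta):
        raise FormatError(
            f"count matrix has {counts.shape[1]} cells but metadata has {len(meta)} rows"
        )
    gene_table["is_mitochondrial"] = (
        gene_table["symbol"].astype(str).str.lower().str.startswith(mito_prefix.lower())
    )
    cohort = CellCohort(counts=counts, gene_table=gene_table, cell_table=meta)
    if design is not None:
        cohort.check_samples(design)
    return cohort


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, name TAB description TAB member genes.

    Duplicate member symbols are deduplicated with a warning; an empty member
    list is a format error naming the line.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(m.strip() for m in parts[2:]):
            raise FormatError(f"{path}:{lineno}: GMT line needs a name, description and >=1 member")
        name, desc = parts[0], parts[1]
        members: list[str] = []
        seen = set()
        for m in parts[2:]:
            m = m.strip()
            if not m:
                continue
            key = m.lower()
            if key in seen:
                log.warning("%s:%d: duplicate member %r in set %r dropped", path, lineno, m, name)
                continue
            seen.add(key)
            members.append(m)
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write named stage outputs as CSVs with stable column order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    return written
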