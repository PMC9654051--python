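"""Count-matrix I/O, FPKM normalisation, low-expression filtering, and
assembly of the mined table (per-gene FPKM features + tissue attribute + diet
class) that feeds attribute weighting.

File formats are plain tab-separated text: counts as genes x samples with a
header row of sample ids and the gene length as a ``length`` column; metadata
as (sample_id, diet, tissue) rows. Writers and readers round-trip exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LENGTH_COLUMN = "length"
TISSUE_FEATURE = "tissue"
CLASS_COLUMN = "diet"
VALID_DIETS = ("control", "CR")


class ParseError(ValueError):
    """Malformed input table (duplicate ids, bad values, missing columns)."""


@dataclass
class CountMatrix:
    """Genes x samples read counts plus per-gene transcript lengths (bp)."""

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ParseError(f"duplicate gene ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ParseError(f"duplicate sample ids: {dup}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals), atol=0):
                raise ParseError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.lt(0)
            gene = bad.any(axis=1).idxmax()
            sample = bad.loc[gene].idxmax()
            raise ParseError(f"negative count at gene {gene!r}, sample {sample!r}")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()].tolist()
            raise ParseError(f"missing gene length for: {missing}")
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths.index[self.gene_lengths <= 0].tolist()
            raise ParseError(f"non-positive gene length for: {bad}")
        self.gene_lengths = self.gene_lengths.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)].copy(), self.gene_lengths.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.gene_lengths.equals(other.gene_lengths)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a tab-separated genes x samples count table with a length column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if LENGTH_COLUMN not in df.columns:
        raise ParseError(f"{path}: missing required column {LENGTH_COLUMN!r}")
    lengths = df.pop(LENGTH_COLUMN)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"{path}: non-numeric count in column {col!r}, rows {bad.index.tolist()}"
            )
    return CountMatrix(counts=df, gene_lengths=lengths)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, LENGTH_COLUMN, cm.gene_lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read (sample_id, diet, tissue) metadata; validates diet labels."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "diet", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dup}")
    bad = sorted(set(meta["diet"]) - set(VALID_DIETS))
    if bad:
        raise ParseError(f"{path}: unknown diet labels {bad}; expected {VALID_DIETS}")
    return meta.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[["sample_id", "diet", "tissue"]].to_csv(path, sep="\t", index=False)


def validate_design(cm: CountMatrix, meta: pd.DataFrame) -> None:
    """Every sample must have exactly one metadata row; both diets per tissue."""
    meta_ids = set(meta["sample_id"])
    missing = [s for s in cm.sample_ids if s not in meta_ids]
    if missing:
        raise ParseError(f"samples missing from metadata: {missing}")
    extra = sorted(meta_ids - set(cm.sample_ids))
    if extra:
        raise ParseError(f"metadata rows with no matching sample: {extra}")
    for tissue, grp in meta.groupby("tissue"):
        diets = set(grp["diet"])
        if set(VALID_DIETS) - diets:
            raise ParseError(f"tissue {tissue!r} lacks diet group(s) {sorted(set(VALID_DIETS) - diets)}")


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM(g, s) = counts(g, s) * 1e9 / (library_size(s) * length(g)), with
    library size the per-sample total assigned counts.
    """
    lib = cm.library_sizes()
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    return cm.counts * 1e9 / (lib.to_numpy()[None, :] * cm.gene_lengths.to_numpy()[:, None])


def filter_low_expression(
    fpkm: pd.DataFrame, threshold: float = 5.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes whose mean FPKM over all samples is strictly below threshold.

    Returns the kept table and the list of removed gene ids. A gene whose
    mean equals the threshold exactly is kept.
    """
    if fpkm.empty:
        raise ValueError("empty FPKM table")
    means = fpkm.mean(axis=1)
    removed = list(fpkm.index[means < threshold])
    kept = fpkm.loc[means >= threshold]
    if kept.empty:
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return kept, removed


def assemble_mined_table(fpkm: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Build the samples x features mined table for attribute weighting.

    Numeric features are the per-gene FPKM columns (sorted by gene id), the
    categorical ``tissue`` attribute comes last, and ``diet`` is the class
    label. Row order follows the metadata.
    """
    meta_idx = meta.set_index("sample_id")
    missing = [s for s in fpkm.columns if s not in meta_idx.index]
    extra = [s for s in meta_idx.index if s not in fpkm.columns]
    if missing or extra:
        raise ValueError(
            f"sample mismatch between FPKM and metadata: missing={missing} extra={extra}"
        )
    table = fpkm.T.loc[meta_idx.index, sorted(fpkm.index)]
    table[TISSUE_FEATURE] = pd.Categorical(meta_idx["tissue"])
    table[CLASS_COLUMN] = pd.Categorical(meta_idx["diet"], categories=VALID_DIETS)
    if table[TISSUE_FEATURE].nunique() == 1:
        logger.warning("tissue attribute is constant (single-tissue input)")
    return table


def write_mined_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")
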