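"""Count-table and study-design containers plus delimited-text I/O.

The canonical in-memory orientation is samples x OTUs.  A :class:`CountTable`
holds non-negative integer read counts with per-sample library sizes (row
sums); a :class:`StudyDesign` holds the batch label, the encoded covariate
matrix and the one-hot batch indicators for the same samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_BATCH_SIZE = 3


class DataError(ValueError):
    """Raised when an input table or metadata file fails validation."""


@dataclass
class CountTable:
    """Samples x OTUs integer count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix; index = sample ids, columns = OTU ids.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].tolist()
            raise DataError(f"duplicate OTU ids: {dup}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            bad = np.argwhere(~np.isclose(arr.astype(float) % 1, 0) | ~np.isfinite(arr.astype(float)))
            if bad.size:
                i, j = bad[0]
                raise DataError(
                    f"non-integer count {arr[i, j]!r} at sample "
                    f"{df.index[i]!r}, OTU {df.columns[j]!r}"
                )
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            arr = df.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
            )
        if self.library_sizes is None:
            # Full table: N_i is the row sum, and empty samples are rejected.
            sizes = df.sum(axis=1)
            zero = sizes == 0
            if zero.any():
                raise DataError(
                    f"samples with zero library size: {df.index[zero].tolist()}"
                )
            self.library_sizes = sizes
        else:
            # Derived table (OTU subset / corrected output): N_i is inherited
            # from the parent so the model offset stays the TOTAL library size.
            sizes = self.library_sizes.loc[df.index].astype(np.int64)
            if (sizes <= 0).any():
                raise DataError("library sizes must be positive")
            self.library_sizes = sizes

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts.div(self.library_sizes, axis=0)

    def subset_otus(self, otu_ids) -> "CountTable":
        return CountTable(
            self.counts.loc[:, list(otu_ids)].copy(),
            library_sizes=self.library_sizes.copy(),
        )


@dataclass
class StudyDesign:
    """Per-sample batch label and encoded covariates.

    ``covariates`` is the numeric design matrix after dummy encoding (no
    intercept column); ``batch_indicators`` is the one-hot batch matrix whose
    rows sum to one.  ``reference_batch`` is filled in once a reference has
    been selected or forced.
    """

    batch: pd.Series
    covariates: pd.DataFrame
    reference_batch: str | None = None
    min_batch_size: int = DEFAULT_MIN_BATCH_SIZE
    batch_indicators: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.batch = self.batch.astype(str)
        if not self.batch.index.equals(self.covariates.index):
            raise DataError("batch and covariates must share the sample index")
        sizes = self.batch.value_counts()
        small = sizes[sizes < self.min_batch_size]
        if len(small):
            raise DataError(
                f"batches below the minimum size ({self.min_batch_size}): "
                f"{dict(small)}"
            )
        cov = self.covariates.astype(float)
        if cov.shape[1] and np.linalg.matrix_rank(cov.to_numpy()) < cov.shape[1]:
            raise DataError("covariate matrix is rank deficient after encoding")
        self.covariates = cov
        self.batch_indicators = pd.get_dummies(self.batch).astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.batch.index)

    @property
    def batch_levels(self) -> list[str]:
        return sorted(self.batch.unique())

    @property
    def n_batches(self) -> int:
        return self.batch.nunique()

    def batch_sizes(self) -> dict[str, int]:
        return {g: int((self.batch == g).sum()) for g in self.batch_levels}

    def subset(self, sample_ids) -> "StudyDesign":
        ids = list(sample_ids)
        return StudyDesign(
            batch=self.batch.loc[ids].copy(),
            covariates=self.covariates.loc[ids].copy(),
            reference_batch=self.reference_batch,
            min_batch_size=self.min_batch_size,
        )


@dataclass
class CorrectionResult:
    """Bundle of the two correction stages plus provenance."""

    corrected: CountTable
    stage1_table: CountTable
    nb_fits: dict
    zero_fits: dict
    cqr_fits: dict
    provenance: dict

    def __post_init__(self) -> None:
        if self.corrected.counts.shape != self.stage1_table.counts.shape:
            raise DataError("corrected and stage-1 tables differ in shape")


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_count_table(path, orientation: str = "samples_by_otus") -> CountTable:
    """Read a delimited count table; transpose if OTUs are rows.

    The first column holds row ids and the header holds column ids.  Cells
    must be non-negative integers; the offending cell is named otherwise.
    """
    if orientation not in ("samples_by_otus", "otus_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    if orientation == "otus_by_samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0)
        if bad.any():
            sid = df.index[bad.to_numpy().nonzero()[0][0]]
            raise DataError(
                f"non-integer count {df.loc[sid, col]!r} at sample {sid!r}, "
                f"OTU {col!r} in {path}"
            )
    return CountTable(df.astype(np.int64))


def write_count_table(table: CountTable, path, orientation: str = "samples_by_otus") -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = table.counts if orientation == "samples_by_otus" else table.counts.T
    df.to_csv(path, sep=sep)


def encode_covariates(meta: pd.DataFrame, covariate_columns) -> pd.DataFrame:
    """Dummy-encode categorical columns, first lexicographic level as reference."""
    pieces = []
    for col in covariate_columns:
        s = meta[col]
        if pd.api.types.is_numeric_dtype(s):
            pieces.append(s.astype(float).rename(col))
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:  # levels[0] is the reference
                pieces.append((s.astype(str) == lev).astype(float).rename(f"{col}[{lev}]"))
    if not pieces:
        return pd.DataFrame(index=meta.index)
    return pd.concat(pieces, axis=1)


def read_metadata(
    path,
    batch_column: str,
    covariate_columns,
    min_batch_size: int = DEFAULT_MIN_BATCH_SIZE,
) -> StudyDesign:
    """Read sample metadata into a :class:`StudyDesign`.

    Missing covariate or batch values are an error (no imputation); the
    affected samples are listed.
    """
    meta = _read_delimited(path)
    meta.index = meta.index.astype(str)
    missing_cols = [c for c in [batch_column, *covariate_columns] if c not in meta.columns]
    if missing_cols:
        raise DataError(f"metadata columns not found: {missing_cols}")
    na = meta[[batch_column, *covariate_columns]].isna().any(axis=1)
    if na.any():
        raise DataError(
            f"missing batch/covariate values for samples: {meta.index[na].tolist()}"
        )
    return StudyDesign(
        batch=meta[batch_column].astype(str),
        covariates=encode_covariates(meta, covariate_columns),
        min_batch_size=min_batch_size,
    )


def align(table: CountTable, design: StudyDesign) -> tuple[CountTable, StudyDesign]:
    """Restrict table and design to their common samples, in table order."""
    common = [s for s in table.sample_ids if s in set(design.sample_ids)]
    if not common:
        raise DataError("count table and metadata share no sample ids")
    dropped = (set(table.sample_ids) | set(design.sample_ids)) - set(common)
    if dropped:
        logger.info("align: dropped %d samples absent from one input", len(dropped))
    if common == table.sample_ids and common == design.sample_ids:
        return table, design
    return (
        CountTable(table.counts.loc[common].copy()),
        design.subset(common),
    )


def filter_otus(
    table: CountTable,
    design: StudyDesign,
    min_prevalence: float = 0.0,
    min_nonzero_per_batch: int = DEFAULT_MIN_BATCH_SIZE,
) -> tuple[CountTable, list[str]]:
    """Split OTUs into a correctable set and a passed-through remainder.

    An OTU enters the correction set when its overall nonzero fraction is at
    least ``min_prevalence`` AND every batch contributes at least
    ``min_nonzero_per_batch`` nonzero samples (per-batch count-model and
    quantile fits need support in every batch).  Returns the correctable
    sub-table and the ids of the excluded ("uncorrected") OTUs, which callers
    re-attach untouched.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    nz = table.counts > 0
    keep = nz.mean(axis=0) >= min_prevalence
    for g in design.batch_levels:
        in_g = (design.batch == g).to_numpy()
        keep &= nz.loc[in_g].sum(axis=0) >= min_nonzero_per_batch
    kept = [o for o, k in zip(table.otu_ids, keep) if k]
    excluded = [o for o, k in zip(table.otu_ids, keep) if not k]
    if not kept:
        raise DataError("all OTUs excluded by the prevalence filter")
    if excluded:
        logger.info("filter_otus: %d OTUs excluded from correction", len(excluded))
    return table.subset_otus(kept), excluded


def reattach_otus(corrected: CountTable, original: CountTable, excluded: list[str]) -> CountTable:
    """Re-attach untouched OTU columns in the original column order."""
    cols = {**{o: corrected.counts[o] for o in corrected.otu_ids},
            **{o: original.counts[o] for o in excluded}}
    df = pd.DataFrame({o: cols[o] for o in original.otu_ids}, index=original.counts.index)
    return CountTable(df.astype(np.int64), library_sizes=original.library_sizes.copy())
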