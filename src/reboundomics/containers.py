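"""Core in-memory containers shared across the pipeline.

The two central objects are :class:`OmicsMatrix` (a features x samples
numeric matrix with a declared measurement kind) and :class:`SampleTable`
(per-sample design information: donor, group, timepoint, covariates).
Both are thin, validated wrappers around :class:`pandas.DataFrame` so that
every downstream stage can rely on unique identifiers and in-range values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Measurement kinds an OmicsMatrix may declare.
VALID_KINDS = ("beta", "m", "count", "logcpm")

#: Fixed ordering of the longitudinal sampling timepoints:
#: before pregnancy, 1st/2nd/3rd trimester, post-partum.
TIMEPOINT_ORDER = ("BP", "T1", "T2", "T3", "PP")

#: Columns every SampleTable must carry.
REQUIRED_SAMPLE_COLUMNS = ("donor", "group", "timepoint")


class ValidationError(ValueError):
    """Raised when a container or configuration violates its invariants."""


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix with a measurement kind.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
    kind
        One of ``beta`` (methylation fractions in [0, 1]), ``m``
        (log2-odds M-values), ``count`` (non-negative integer read
        counts) or ``logcpm`` (log2 counts per million).
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValidationError(
                f"kind must be one of {VALID_KINDS}, got {self.kind!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dups[:5])}")
        x = self.values.to_numpy()
        if not np.issubdtype(x.dtype, np.number):
            raise ValidationError("matrix values must be numeric")
        if self.kind == "beta":
            if np.nanmin(x) < 0.0 or np.nanmax(x) > 1.0:
                raise ValidationError("beta values must lie in [0, 1]")
        elif self.kind == "count":
            if np.nanmin(x) < 0 or not np.allclose(x, np.round(x)):
                raise ValidationError("counts must be non-negative integers")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_features(self, ids: Iterable[str]) -> "OmicsMatrix":
        ids = pd.Index(ids)
        missing = ids.difference(self.feature_ids)
        if len(missing):
            raise ValidationError(f"unknown feature ids: {list(missing[:5])}")
        return OmicsMatrix(self.values.loc[ids], self.kind)

    def subset_samples(self, ids: Iterable[str]) -> "OmicsMatrix":
        ids = pd.Index(ids)
        missing = ids.difference(self.sample_ids)
        if len(missing):
            raise ValidationError(f"unknown sample ids: {list(missing[:5])}")
        return OmicsMatrix(self.values[list(ids)], self.kind)

    def write_tsv(self, path: str | Path, index_label: str = "feature") -> None:
        self.values.to_csv(path, sep="\t", index_label=index_label)

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str) -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, kind)


@dataclass
class SampleTable:
    """Per-sample design information.

    ``data`` is indexed by sample id and must contain ``donor``, ``group``
    and ``timepoint`` columns; additional numeric columns (age,
    memory_fraction, viability, activation_level, batch, ...) are treated
    as covariates by the design builder.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.data.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in sample table")
        bad = set(self.data["timepoint"]) - set(TIMEPOINT_ORDER)
        if bad:
            raise ValidationError(
                f"unknown timepoints {sorted(bad)}; expected subset of {TIMEPOINT_ORDER}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    @property
    def timepoints(self) -> list[str]:
        present = set(self.data["timepoint"])
        return [t for t in TIMEPOINT_ORDER if t in present]

    def subset(self, mask: pd.Series) -> "SampleTable":
        return SampleTable(self.data.loc[mask])

    def aligned_to(self, matrix: OmicsMatrix) -> "SampleTable":
        """Reorder rows to match a matrix's sample columns."""
        missing = matrix.sample_ids.difference(self.data.index)
        if len(missing):
            raise ValidationError(f"samples absent from table: {list(missing[:5])}")
        return SampleTable(self.data.loc[matrix.sample_ids])

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", index_col="sample"))


@dataclass
class CpGAnnotation:
    """CpG -> gene mapping; a probe may map to zero, one or several genes.

    ``table`` has columns ``cpg`` and ``gene`` with one row per
    (probe, gene) association.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("cpg", "gene"):
            if col not in self.table.columns:
                raise ValidationError(f"annotation missing column {col!r}")

    def genes_for(self, cpgs: Iterable[str]) -> set[str]:
        cpgs = set(cpgs)
        hit = self.table[self.table["cpg"].isin(cpgs)]
        return set(hit["gene"])

    def annotated_cpgs(self) -> set[str]:
        return set(self.table["cpg"])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CpGAnnotation":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors.

    Invariant: factors are positive with geometric mean 1.
    """

    sample_ids: pd.Index
    lib_size: np.ndarray
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = pd.Index(self.sample_ids)
        self.lib_size = np.asarray(self.lib_size, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValidationError("TMM factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.factors))))
        if abs(gm - 1.0) > 1e-8:
            raise ValidationError(f"geometric mean of factors is {gm}, expected 1")

    @property
    def effective_lib_size(self) -> np.ndarray:
        return self.lib_size * self.factors

    def reindex(self, sample_ids: Sequence[str]) -> "NormFactors":
        pos = self.sample_ids.get_indexer(sample_ids)
        if np.any(pos < 0):
            raise ValidationError("norm factors missing requested samples")
        sub_f = self.factors[pos]
        sub_f = sub_f / np.exp(np.mean(np.log(sub_f)))
        return NormFactors(pd.Index(sample_ids), self.lib_size[pos], sub_f)
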