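"""Reading, validating, filtering and writing OTU/ASV abundance tables.

Input tables are oriented taxa x samples: the first column holds the
OTU/ASV identifier, an optional second column holds a ";"-delimited
taxonomic lineage (kingdom;phylum;...;species), and the remaining
columns hold per-sample counts or relative abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "TaxonomyRecord",
    "AbundanceError",
    "read_abundance",
    "filter_low_abundance",
    "write_matrix",
    "read_matrix",
]

N_TAXONOMIC_RANKS = 7


class AbundanceError(ValueError):
    """Raised for malformed or inconsistent abundance inputs."""


@dataclass
class TaxonomyRecord:
    """One ";"-delimited taxonomic lineage, kingdom through species."""

    raw: str
    ranks: list[str] = field(init=False)

    def __post_init__(self) -> None:
        ranks = [r.strip() for r in self.raw.split(";")]
        self.ranks = ranks[:N_TAXONOMIC_RANKS]

    @property
    def phylum(self) -> str:
        """Second rank of the lineage, or "NA" when unassigned/absent."""
        if len(self.ranks) > 1 and self.ranks[1]:
            return self.ranks[1]
        return "NA"


@dataclass
class AbundanceTable:
    """A taxa x samples matrix of non-negative counts or abundances.

    Parameters
    ----------
    taxon_ids
        Unique OTU/ASV identifiers, one per row of ``counts``.
    sample_ids
        Unique sample identifiers, one per column of ``counts``.
    counts
        Non-negative matrix of shape ``(n_taxa, n_samples)``.
    taxonomy
        Optional ";"-delimited lineage strings, aligned with ``taxon_ids``.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise AbundanceError("counts must be a 2-D matrix (taxa x samples)")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise AbundanceError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise AbundanceError(f"duplicate {name} IDs: {sorted(dupes)}")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise AbundanceError("counts must be finite and non-negative")
        if self.taxonomy is not None and len(self.taxonomy) != len(self.taxon_ids):
            raise AbundanceError("taxonomy length must equal the number of taxa")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def taxonomy_records(self) -> list[TaxonomyRecord] | None:
        if self.taxonomy is None:
            return None
        return [TaxonomyRecord(t) for t in self.taxonomy]

    def is_compositional(self, atol: float = 1e-6) -> bool:
        """True when every sample's abundances sum to 1 (relative data)."""
        return bool(np.allclose(self.counts.sum(axis=0), 1.0, atol=atol))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)
        df.index.name = "taxon_id"
        if self.taxonomy is not None:
            df.insert(0, "taxonomy", self.taxonomy)
        return df

    def write(self, path: str | Path, delimiter: str = "auto") -> None:
        sep = _resolve_delimiter(path, delimiter)
        self.to_dataframe().to_csv(path, sep=sep)


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for i in ids:
        (dupes if i in seen else seen).add(i)
    return dupes


def _resolve_delimiter(path: str | Path, delimiter: str) -> str:
    if delimiter in ("\t", "tab"):
        return "\t"
    if delimiter in (",", "comma"):
        return ","
    if delimiter == "auto":
        return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","
    raise AbundanceError(f"unknown delimiter {delimiter!r}")


def read_abundance(
    path: str | Path,
    has_taxonomy: bool | str = "auto",
    delimiter: str = "auto",
) -> AbundanceTable:
    """Read a TSV/CSV abundance table.

    The first column is the taxon ID. With ``has_taxonomy=True`` the second
    column is a ";"-delimited lineage; with ``"auto"`` the second column is
    treated as taxonomy iff any of its cells contains ";".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _resolve_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0)
    if raw.empty or raw.shape[1] == 0:
        raise AbundanceError(f"{path}: empty abundance table")

    taxon_ids = [str(i) for i in raw.index]
    dupes = _duplicates(taxon_ids)
    if dupes:
        raise AbundanceError(f"{path}: duplicate taxon IDs: {sorted(dupes)}")

    if has_taxonomy == "auto":
        first = raw.iloc[:, 0]
        has_taxonomy = bool(first.astype(str).str.contains(";").any())

    taxonomy: list[str] | None = None
    data = raw
    if has_taxonomy:
        taxonomy = [str(v) for v in raw.iloc[:, 0]]
        data = raw.iloc[:, 1:]
    if data.shape[1] < 2:
        raise AbundanceError(
            f"{path}: need at least 2 sample columns, found {data.shape[1]}"
        )

    counts = np.empty(data.shape, dtype=float)
    for j, col in enumerate(data.columns):
        parsed = pd.to_numeric(data[col], errors="coerce")
        bad = parsed.isna() & data[col].notna()
        if bad.any():
            row = data.index[np.flatnonzero(bad)[0]]
            raise AbundanceError(
                f"{path}: non-numeric abundance value {data.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        counts[:, j] = parsed.to_numpy(dtype=float)

    return AbundanceTable(
        taxon_ids=taxon_ids,
        sample_ids=[str(c) for c in data.columns],
        counts=counts,
        taxonomy=taxonomy,
    )


def filter_low_abundance(
    table: AbundanceTable,
    min_total: float = 5,
    remove_unique: bool = True,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Remove singleton and unique taxa.

    A taxon is a *singleton* when its total count over all samples is below
    ``min_total`` (strict ``<``, so a total of exactly 5 survives the
    default), and *unique* when it is present (count > 0) in exactly one
    sample. For relative-abundance (compositional) input the total-count
    rule is meaningless and only the unique rule is applied, with a warning.

    Returns the filtered table and a removal report with columns
    ``taxon_id`` and ``reason`` (``singleton`` or ``unique``).
    """
    counts = table.counts
    compositional = table.is_compositional()
    if compositional:
        warnings.warn(
            "relative-abundance input detected: skipping the total-count "
            "(singleton) rule, applying only the unique-sample rule",
            stacklevel=2,
        )
    elif not np.allclose(counts, np.round(counts)):
        warnings.warn(
            "non-integer abundances detected; singleton filtering assumes "
            "raw counts",
            stacklevel=2,
        )

    totals = counts.sum(axis=1)
    n_present = (counts > 0).sum(axis=1)
    singleton = np.zeros(table.n_taxa, dtype=bool)
    if not compositional:
        singleton = totals < min_total
    unique = (n_present == 1) if remove_unique else np.zeros(table.n_taxa, dtype=bool)

    removed = singleton | unique
    reasons = np.where(singleton, "singleton", "unique")
    report = pd.DataFrame(
        {
            "taxon_id": [t for t, r in zip(table.taxon_ids, removed) if r],
            "reason": [x for x, r in zip(reasons, removed) if r],
        }
    )
    keep = ~removed
    if not keep.any():
        raise AbundanceError(
            "filtering removed every taxon; lower min_total or disable "
            "unique-taxon removal"
        )
    filtered = AbundanceTable(
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        sample_ids=list(table.sample_ids),
        counts=counts[keep],
        taxonomy=(
            None
            if table.taxonomy is None
            else [t for t, k in zip(table.taxonomy, keep) if k]
        ),
    )
    return filtered, report


def write_matrix(
    matrix: np.ndarray | pd.DataFrame,
    path: str | Path,
    labels: list[str] | None = None,
) -> None:
    """Write a labeled square matrix as CSV (header row + label column)."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        matrix = np.asarray(matrix, dtype=float)
        if labels is None:
            raise AbundanceError("labels required for a bare array")
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise AbundanceError(f"matrix must be square, got shape {matrix.shape}")
        if len(labels) != matrix.shape[0]:
            raise AbundanceError(
                f"{len(labels)} labels for a {matrix.shape[0]}-row matrix"
            )
        df = pd.DataFrame(matrix, index=labels, columns=labels)
    if df.shape[0] != df.shape[1]:
        raise AbundanceError(f"matrix must be square, got shape {df.shape}")
    if len(set(df.index)) != len(df.index):
        raise AbundanceError("row/column labels must be unique")
    df.to_csv(path, float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled square matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise AbundanceError(f"{path}: matrix is not square ({df.shape})")
    return df
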