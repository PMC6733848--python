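"""OTU count tables: I/O, low-fraction filtering, rarefaction, Shannon diversity.

The central object is :class:`OtuTable`, a samples x OTUs matrix of
non-negative integer counts with optional greengenes-style taxonomy strings.
Tables are read and written in the classic tab-delimited layout
(OTUs in rows, samples in columns, a trailing ``taxonomy`` column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "DiversityResult",
    "OtuTableParseError",
    "read_otu_table",
    "write_otu_table",
    "filter_low_fraction_otus",
    "rarefy",
    "shannon_index",
]

TAXONOMY_COLUMN = "taxonomy"


class OtuTableParseError(ValueError):
    """Raised when a classic OTU table file is malformed."""


@dataclass
class OtuTable:
    """A samples x OTUs count matrix with per-OTU taxonomy.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers (rows of ``counts``).
    otu_ids : list of str
        Ordered OTU identifiers (columns of ``counts``).
    counts : ndarray of shape (n_samples, n_otus)
        Non-negative integer counts.
    taxonomy : list of str
        Per-OTU lineage string; empty strings if unknown.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n_samples, n_otus = self.counts.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} count rows"
            )
        if len(self.otu_ids) != n_otus:
            raise ValueError(
                f"{len(self.otu_ids)} OTU ids for {n_otus} count columns"
            )
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != n_otus:
            raise ValueError("duplicate OTU ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.taxonomy:
            self.taxonomy = [""] * n_otus
        if len(self.taxonomy) != n_otus:
            raise ValueError("taxonomy length must match number of OTUs")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        """Total reads (library size) per sample."""
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> np.ndarray:
        """Counts divided by per-sample totals; all-zero samples yield zeros."""
        totals = self.sample_sums().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / totals[:, None]
        rel[totals == 0, :] = 0.0
        return rel

    def select_samples(self, keep: np.ndarray) -> "OtuTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return OtuTable(
            sample_ids=[self.sample_ids[i] for i in keep],
            otu_ids=list(self.otu_ids),
            counts=self.counts[keep, :].copy(),
            taxonomy=list(self.taxonomy),
        )

    def select_otus(self, keep: np.ndarray) -> "OtuTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return OtuTable(
            sample_ids=list(self.sample_ids),
            otu_ids=[self.otu_ids[i] for i in keep],
            counts=self.counts[:, keep].copy(),
            taxonomy=[self.taxonomy[i] for i in keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a samples x OTUs DataFrame."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and self.taxonomy == other.taxonomy
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class DiversityResult:
    """Shannon diversity for one sample, natural-log units."""

    sample_id: str
    shannon: float
    depth_used: int
    included: bool


def read_otu_table(path) -> OtuTable:
    """Read a classic tab-delimited OTU table (OTUs in rows, samples in columns).

    The first column holds OTU ids; a trailing ``taxonomy`` column is optional.
    Lines starting with ``#`` before the header (QIIME-style preamble) are
    skipped, except a ``#OTU ID``-style header line which is used as the header.

    Raises
    ------
    OtuTableParseError
        On duplicate ids, non-integer or negative counts, or ragged rows,
        with the offending 1-based line number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = fh.readlines()

    header = None
    header_lineno = 0
    data_start = 0
    for i, line in enumerate(raw_lines):
        stripped = line.rstrip("\n")
        if not stripped.strip():
            continue
        if stripped.startswith("#") and not stripped.lower().startswith("#otu"):
            continue
        header = stripped.lstrip("#").split("\t")
        header_lineno = i + 1
        data_start = i + 1
        break
    if header is None:
        raise OtuTableParseError(f"{path}: no header row found")

    has_taxonomy = header[-1].strip().lower() == TAXONOMY_COLUMN
    sample_ids = [h.strip() for h in (header[1:-1] if has_taxonomy else header[1:])]
    if len(set(sample_ids)) != len(sample_ids):
        raise OtuTableParseError(
            f"{path}:{header_lineno}: duplicate sample ids in header"
        )
    n_fields = len(header)

    otu_ids: list[str] = []
    taxonomy: list[str] = []
    rows: list[list[int]] = []
    for i in range(data_start, len(raw_lines)):
        lineno = i + 1
        stripped = raw_lines[i].rstrip("\n")
        if not stripped.strip():
            continue
        fields = stripped.split("\t")
        if len(fields) != n_fields:
            raise OtuTableParseError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        otu_ids.append(fields[0].strip())
        value_fields = fields[1:-1] if has_taxonomy else fields[1:]
        row = []
        for f in value_fields:
            try:
                # tolerate "12.0"-style floats that are whole numbers
                v = float(f)
            except ValueError:
                raise OtuTableParseError(
                    f"{path}:{lineno}: non-numeric count {f!r}"
                ) from None
            if v != int(v):
                raise OtuTableParseError(f"{path}:{lineno}: non-integer count {f!r}")
            if v < 0:
                raise OtuTableParseError(f"{path}:{lineno}: negative count {f!r}")
            row.append(int(v))
        rows.append(row)
        taxonomy.append(fields[-1].strip() if has_taxonomy else "")

    if len(set(otu_ids)) != len(otu_ids):
        raise OtuTableParseError(f"{path}: duplicate OTU ids")
    counts = np.array(rows, dtype=np.int64).reshape(len(otu_ids), len(sample_ids))
    return OtuTable(
        sample_ids=sample_ids, otu_ids=otu_ids, counts=counts.T, taxonomy=taxonomy
    )


def write_otu_table(table: OtuTable, path) -> None:
    """Write *table* in the classic tab-delimited layout read by
    :func:`read_otu_table` (round-trip identity on counts, ids, taxonomy)."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["#OTU ID", *table.sample_ids, TAXONOMY_COLUMN]
        fh.write("\t".join(cols) + "\n")
        for j, otu in enumerate(table.otu_ids):
            row = [otu] + [str(int(c)) for c in table.counts[:, j]]
            row.append(table.taxonomy[j])
            fh.write("\t".join(row) + "\n")


def filter_low_fraction_otus(
    table: OtuTable, min_fraction: float = 0.001, min_samples: int = 2
) -> OtuTable:
    """Keep OTUs reaching ``min_fraction`` of a sample's reads in at least
    ``min_samples`` samples.

    The fraction is computed within each sample against that sample's total;
    all-zero samples contribute no qualifying fractions. The sample set is
    unchanged.
    """
    rel = table.relative_abundances()
    qualifying = (rel >= min_fraction).sum(axis=0)
    return table.select_otus(qualifying >= min_samples)


def rarefy(
    table: OtuTable, depth: int = 5000, seed: int | np.random.Generator = 0
) -> tuple[OtuTable, list[str]]:
    """Subsample each sample to exactly *depth* reads without replacement.

    Samples whose library size is below *depth* are dropped and returned in the
    second element. Each retained sample is a single multivariate-hypergeometric
    draw, so per-cell rarefied counts never exceed the originals and row sums
    equal *depth* exactly.

    Returns
    -------
    (OtuTable, list of str)
        The rarefied table and the ids of dropped samples.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    totals = table.sample_sums()
    keep = totals >= depth
    dropped = [sid for sid, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        warnings.warn(
            f"no sample reaches rarefaction depth {depth}; returning empty table",
            stacklevel=2,
        )
    sub = table.select_samples(keep)
    out = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        out[i] = rng.multivariate_hypergeometric(sub.counts[i], depth)
    return (
        OtuTable(sub.sample_ids, sub.otu_ids, out, list(sub.taxonomy)),
        dropped,
    )


def shannon_index(table: OtuTable) -> list[DiversityResult]:
    """Shannon diversity H = -sum_i p_i ln p_i per sample (natural log).

    p_i is the within-sample relative abundance; terms with p_i = 0 are
    omitted. All-zero samples are returned with ``included=False`` and NaN.
    """
    results = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = int(row.sum())
        if total == 0:
            results.append(DiversityResult(sid, float("nan"), 0, False))
            continue
        p = row[row > 0] / total
        h = float(-(p * np.log(p)).sum())
        # guard -0.0 from single-OTU samples
        results.append(DiversityResult(sid, abs(h) if h == 0 else h, total, True))
    return results


def shannon_series(table: OtuTable) -> pd.Series:
    """Shannon index as a Series indexed by sample id (NaN for empty samples)."""
    res = shannon_index(table)
    return pd.Series(
        {r.sample_id: r.shannon for r in res}, name="shannon", dtype=float
    )
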