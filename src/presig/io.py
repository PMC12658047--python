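"""Readers and writers for the plain-text formats the pipeline touches.

Formats: GMT gene-set collections (Broad 3+ column dialect), genes x samples
count matrices as TSV (optionally matrix-market triplets), and per-sample
metadata as CSV.  Readers validate and reject malformed input instead of
coercing silently; writers are deterministic.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default prefix marking spike-in rows in a count matrix
SPIKEIN_PREFIX = "ERCC-"

#: metadata columns that must always be present
REQUIRED_METADATA_COLUMNS = ("condition", "library")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) == 0:
            raise FormatError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"gene set {self.name!r} has duplicate members")


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {s.name: s.members for s in self.sets}


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a Broad-format GMT file (name, description, members...).

    Duplicate member ids within one set are dropped (first occurrence kept)
    with a warning; a line with fewer than 3 fields or a duplicate set name
    is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m != ""]
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} empty")
            if name in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                warnings.warn(
                    f"{path}: line {lineno}: set {name!r} lists duplicate "
                    f"member ids; duplicates dropped",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, desc, tuple(uniq)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer UMI counts, genes x samples, with spike-in and library labels.

    ``counts`` is indexed by unique gene ids with unique sample-id columns;
    ``is_spikein`` is a boolean Series over genes; ``library`` is a per-sample
    Series (may be ``None`` until metadata is attached).
    """

    counts: pd.DataFrame
    is_spikein: pd.Series
    library: pd.Series | None = None

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids in count matrix")
        if not self.is_spikein.index.equals(self.counts.index):
            raise FormatError("is_spikein index does not match gene ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.floor(vals)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        if self.library is not None:
            if not self.library.index.equals(self.counts.columns):
                raise FormatError("library index does not match sample ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def spikein_ids(self) -> pd.Index:
        return self.counts.index[self.is_spikein.to_numpy()]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[gene_ids],
            self.is_spikein.loc[gene_ids],
            self.library,
        )

    def subset_samples(self, sample_ids) -> "CountMatrix":
        lib = None if self.library is None else self.library.loc[sample_ids]
        return CountMatrix(self.counts[list(sample_ids)], self.is_spikein, lib)

    def require_spikeins(self) -> None:
        if int(self.is_spikein.sum()) == 0:
            raise FormatError("stage requires spike-in rows but none are flagged")


def read_counts(
    path: str | os.PathLike,
    spikein_prefix: str = SPIKEIN_PREFIX,
    library: pd.Series | None = None,
) -> CountMatrix:
    """Read a genes x samples TSV count matrix.

    First column holds gene ids, header holds sample ids.  Rows whose id
    starts with ``spikein_prefix`` are flagged as spike-ins.  Non-integer
    cells are an error naming row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        bad = ~(arr == np.floor(arr)) | ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"{path}: non-integer count at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        df = df.astype(np.int64)
    is_spike = pd.Series(
        df.index.astype(str).str.startswith(spikein_prefix), index=df.index
    )
    logger.info(
        "read_counts: %d genes (%d spike-ins) x %d samples from %s",
        df.shape[0], int(is_spike.sum()), df.shape[1], path,
    )
    return CountMatrix(df, is_spike, library)


def write_counts(cm: CountMatrix, path: str | os.PathLike) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_counts_mtx(cm: CountMatrix, prefix: str | os.PathLike) -> None:
    """Write sparse triplets: ``<prefix>.mtx``, ``<prefix>.genes.txt``,
    ``<prefix>.samples.txt``."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(cm.counts.to_numpy()))
    with open(f"{prefix}.genes.txt", "w") as fh:
        fh.write("\n".join(map(str, cm.gene_ids)) + "\n")
    with open(f"{prefix}.samples.txt", "w") as fh:
        fh.write("\n".join(map(str, cm.sample_ids)) + "\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-sample metadata CSV (first column = sample id).

    Must contain ``condition`` (PE/NP) and ``library`` columns.
    """
    meta = pd.read_csv(path, index_col=0)
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"{path}: metadata missing required column {col!r}")
    bad = set(meta["condition"].unique()) - {"PE", "NP"}
    if bad:
        raise FormatError(f"{path}: unexpected condition labels {sorted(bad)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def attach_metadata(cm: CountMatrix, meta: pd.DataFrame) -> CountMatrix:
    """Attach per-sample library labels from a metadata table."""
    missing = cm.sample_ids.difference(meta.index)
    if len(missing):
        raise FormatError(f"metadata lacks samples: {list(missing)[:5]}")
    return CountMatrix(cm.counts, cm.is_spikein, meta.loc[cm.sample_ids, "library"])
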