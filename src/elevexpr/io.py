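"""Data model and tab-separated readers/writers.

The pipeline's on-disk currency is plain UTF-8 TSV: a gene x sample count
matrix (first column gene IDs, header row sample IDs), a sample metadata
table (sample_id, landrace, zone, block), and newline-delimited gene lists
('#' comments and blank lines ignored).  All-zero genes are retained at read
time; filtering is an explicit downstream step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Admissible elevational zones of landrace origin, low to high.
ZONES = ("lowland", "midland", "highland")

#: Field blocks of the common-garden design.
BLOCKS = (1, 2, 3)


class DataError(ValueError):
    """Raised when an input file violates the data model."""


@dataclass(frozen=True)
class SampleInfo:
    """One RNA-seq library: landrace of origin, elevational zone, field block."""

    landrace: str
    zone: str
    block: int

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise DataError(
                f"unknown zone {self.zone!r}; expected one of {ZONES}"
            )
        if self.block not in BLOCKS:
            raise DataError(
                f"block {self.block!r} outside {BLOCKS}"
            )


@dataclass
class CountMatrix:
    """Integer gene x sample read counts plus per-sample design factors.

    Invariants: unique gene and sample IDs, counts integral and
    non-negative, one :class:`SampleInfo` per column.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    samples: list[SampleInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample IDs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise DataError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise DataError("counts must be non-negative")
        if self.samples and len(self.samples) != len(self.sample_ids):
            raise DataError(
                f"{len(self.samples)} SampleInfo records for "
                f"{len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def zones(self) -> np.ndarray:
        return np.array([s.zone for s in self.samples])

    def blocks(self) -> np.ndarray:
        return np.array([s.block for s in self.samples])

    def landraces(self) -> np.ndarray:
        return np.array([s.landrace for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        """Column subset preserving counts / SampleInfo alignment."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise DataError(f"unknown sample IDs: {missing}")
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, cols],
            samples=[self.samples[c] for c in cols] if self.samples else [],
        )

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise DataError(f"unknown gene IDs: {missing[:10]}")
        rows = [idx[g] for g in gene_ids]
        return CountMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts[rows, :],
            samples=list(self.samples),
        )


@dataclass
class GeneSet:
    """A named set of gene identifiers (e.g. the 190 phenolic candidates)."""

    name: str
    gene_ids: set[str]

    def __post_init__(self) -> None:
        self.gene_ids = set(self.gene_ids)
        if not self.gene_ids:
            raise DataError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def sorted(self) -> list[str]:
        return sorted(self.gene_ids)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path) -> CountMatrix:
    """Read a gene x sample count matrix from TSV.

    Header row holds sample IDs; first column holds gene IDs.  Raises
    :class:`DataError` for duplicate IDs, non-integer, negative or missing
    cells, naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene IDs in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise DataError(f"duplicate sample IDs in {path}")
    values = np.empty(df.shape, dtype=np.int64)
    for i, (gene, row) in enumerate(df.iterrows()):
        try:
            numeric = pd.to_numeric(row, errors="raise")
        except (ValueError, TypeError) as exc:
            raise DataError(f"non-numeric cell in row {gene!r}: {exc}") from exc
        if numeric.isna().any():
            raise DataError(f"missing/ragged cell in row {gene!r}")
        arr = numeric.to_numpy()
        if np.any(np.mod(arr, 1) != 0):
            raise DataError(f"non-integer count in row {gene!r}")
        if np.any(arr < 0):
            raise DataError(f"negative count in row {gene!r}")
        values[i] = arr.astype(np.int64)
    return CountMatrix(
        gene_ids=df.index.tolist(),
        sample_ids=df.columns.tolist(),
        counts=values,
    )


def write_counts(cm: CountMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> tuple[list[str], list[SampleInfo]]:
    """Read sample metadata (sample_id, landrace, zone, block) from TSV.

    Zone labels are case-normalized; order is preserved.  Returns the
    sample IDs and the aligned :class:`SampleInfo` records.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "landrace", "zone", "block"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"metadata missing columns {missing}")
    sample_ids: list[str] = []
    infos: list[SampleInfo] = []
    for _, row in df.iterrows():
        if row[required].isna().any():
            raise DataError(f"missing field in metadata row {row.to_dict()}")
        zone = str(row["zone"]).strip().lower()
        if zone not in ZONES:
            raise DataError(
                f"unknown zone {row['zone']!r} for sample {row['sample_id']!r}; "
                f"expected one of {ZONES}"
            )
        try:
            block = int(row["block"])
        except ValueError as exc:
            raise DataError(
                f"non-integer block {row['block']!r} for {row['sample_id']!r}"
            ) from exc
        sample_ids.append(str(row["sample_id"]))
        infos.append(SampleInfo(str(row["landrace"]), zone, block))
    if len(set(sample_ids)) != len(sample_ids):
        raise DataError("duplicate sample IDs in metadata")
    return sample_ids, infos


def write_metadata(sample_ids: list[str], samples: list[SampleInfo], path) -> None:
    pd.DataFrame(
        {
            "sample_id": sample_ids,
            "landrace": [s.landrace for s in samples],
            "zone": [s.zone for s in samples],
            "block": [s.block for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def attach_metadata(cm: CountMatrix, sample_ids: list[str], samples: list[SampleInfo]) -> CountMatrix:
    """Attach metadata to a count matrix; sample order must match exactly."""
    if sample_ids != cm.sample_ids:
        raise DataError(
            "metadata sample order does not match count-matrix columns; "
            "reorder the metadata file rather than relying on silent matching"
        )
    return CountMatrix(cm.gene_ids, cm.sample_ids, cm.counts, list(samples))


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """Read a gene list, one ID per line; '#' comments and blanks ignored.

    Duplicates are collapsed with a logged warning; an empty result is an
    error.
    """
    seen: set[str] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            if token in seen:
                n_dup += 1
            seen.add(token)
    if n_dup:
        logger.warning("%s: %d duplicate gene IDs collapsed", path, n_dup)
    if not seen:
        raise DataError(f"gene list {path} is empty")
    label = name if name is not None else str(path)
    gs = GeneSet(label, seen)
    logger.info("%s: %d unique gene IDs", path, len(gs))
    return gs


def write_gene_list(gs: GeneSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in gs.sorted():
            fh.write(g + "\n")


def write_de_table(table: pd.DataFrame, path, contrast: tuple[str, str]) -> None:
    """Write a DE result table as TSV with a header naming the contrast."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# contrast: {contrast[0]} vs {contrast[1]}\n")
        table.to_csv(fh, sep="\t", index_label="gene_id")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
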