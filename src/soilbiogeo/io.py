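"""Readers, writers and validated containers for the pipeline's external formats.

The on-disk dialects are the QIIME-era ones a 16S amplicon workflow produces:

* OTU table — classic tab-separated layout, rows = OTUs, columns = samples,
  optional trailing ``taxonomy`` column holding a semicolon-delimited
  greengenes/SILVA-style lineage (``k__Bacteria; p__Proteobacteria; ...``).
  In memory the table is transposed to samples x OTUs.
* Site metadata — TSV with ``sample_id``, ``latitude``, ``longitude``,
  environmental covariates (pH unitless; AK/AN/AP and OC/TN in mg/kg;
  PRE in mm; TEM in degrees C) and an optional categorical ``soil_type``.
* Phylogeny — single-tree newick with branch lengths (for weighted UniFrac).

All files are UTF-8, tab-delimited, '.' decimal separator.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "RANKS",
    "Lineage",
    "OtuTable",
    "SiteMetadata",
    "OtuTableParseError",
    "MetadataParseError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "validate_tree",
]

#: Canonical taxonomic ranks, kingdom through genus.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


class OtuTableParseError(ValueError):
    """Raised when an OTU table file violates the classic-TSV contract."""


class MetadataParseError(ValueError):
    """Raised when a metadata file is malformed or out of range."""


@dataclass(frozen=True)
class Lineage:
    """Taxonomic lineage, kingdom..genus; ``None`` marks an unassigned rank.

    Ranks always appear in canonical order; a rank may be unassigned (None)
    at any depth, which is how an ``g__`` with an empty name is recorded.
    """

    names: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(f"lineage needs {len(RANKS)} ranks, got {len(self.names)}")

    def get(self, rank: str) -> str | None:
        return self.names[RANKS.index(rank)]

    @property
    def phylum(self) -> str | None:
        return self.names[1]

    @property
    def genus(self) -> str | None:
        return self.names[5]

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        """Parse a ``k__...; p__...`` string; prefixes matched case-insensitively.

        Tokens past genus (e.g. ``s__``) are ignored.  A missing or
        empty-named prefix yields an unassigned rank.
        """
        names: list[str | None] = [None] * len(RANKS)
        for token in text.split(";"):
            token = token.strip()
            if not token:
                continue
            low = token.lower()
            for i, pref in enumerate(_PREFIXES):
                if low.startswith(pref):
                    name = token[len(pref):].strip()
                    names[i] = name or None
                    break
        return cls(tuple(names))

    def format(self) -> str:
        parts = []
        for pref, name in zip(_PREFIXES, self.names):
            parts.append(f"{pref}{name if name is not None else ''}")
        return "; ".join(parts)


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with optional per-OTU taxonomy.

    Invariants enforced at construction: unique ids, integer counts >= 0,
    matrix dimensions matching the id lists.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    lineages: list[Lineage] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers (relative abundances are rejected; "
                                 "normalization is an explicit pipeline step)")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if self.lineages is not None and len(self.lineages) != len(self.otu_ids):
            raise ValueError("one lineage per OTU required")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Total-sum-scaled matrix; every row sums to 1.  Zero-total rows error."""
        totals = self.sample_totals()
        if np.any(totals == 0):
            bad = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValueError(f"samples with zero total counts: {bad}")
        return self.counts / totals[:, None]

    def prevalence(self) -> np.ndarray:
        """Per-OTU fraction of samples with a nonzero count."""
        return (self.counts > 0).mean(axis=0)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        index = {o: i for i, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in index]
        if missing:
            raise KeyError(f"OTUs not in table: {missing[:5]}")
        cols = [index[o] for o in otu_ids]
        return OtuTable(
            list(self.sample_ids),
            list(otu_ids),
            self.counts[:, cols].copy(),
            [self.lineages[c] for c in cols] if self.lineages is not None else None,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[rows].copy(),
                        list(self.lineages) if self.lineages is not None else None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and self.lineages == other.lineages
        )


@dataclass
class SiteMetadata:
    """Per-sample geography and environment.

    ``env`` holds the named covariates aligned with ``sample_ids``; any
    numeric column other than the coordinates is treated as a covariate.
    """

    sample_ids: list[str]
    latitude: np.ndarray
    longitude: np.ndarray
    env: pd.DataFrame
    soil_type: list[str] | None = None

    def __post_init__(self) -> None:
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise MetadataParseError("duplicate sample ids in metadata")
        if self.latitude.shape != (n,) or self.longitude.shape != (n,):
            raise MetadataParseError("coordinate vectors must align with sample_ids")
        if np.any(np.abs(self.latitude) > 90):
            raise MetadataParseError("latitude outside [-90, 90]")
        if np.any(np.abs(self.longitude) > 180):
            raise MetadataParseError("longitude outside [-180, 180]")
        if len(self.env) != n:
            raise MetadataParseError("env covariates must align with sample_ids")
        self.env = self.env.set_axis(self.sample_ids, axis=0)
        if self.soil_type is not None and len(self.soil_type) != n:
            raise MetadataParseError("soil_type must align with sample_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def covariates(self) -> list[str]:
        return list(self.env.columns)

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame({"latitude": self.latitude, "longitude": self.longitude},
                             index=self.sample_ids)
        frame = pd.concat([frame, self.env], axis=1)
        if self.soil_type is not None:
            frame["soil_type"] = self.soil_type
        return frame


# ---------------------------------------------------------------------------
# OTU table TSV
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, format: str = "tsv_classic") -> OtuTable:
    """Read a classic tab-separated OTU table (rows = OTUs, columns = samples).

    The first header field names the OTU-id column, the remaining fields are
    sample ids; an optional final ``taxonomy`` column carries lineages.
    Returned orientation is samples x OTUs.
    """
    if format != "tsv_classic":
        raise ValueError(f"unsupported format: {format!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip() and not ln.startswith("# ")]
    if not lines:
        raise OtuTableParseError(f"{path}: empty file")
    header = lines[0].lstrip("#").split("\t")
    if len(header) < 2:
        raise OtuTableParseError(f"{path}: header must name at least one sample")
    has_taxonomy = header[-1].strip().lower() == "taxonomy"
    sample_ids = [h.strip() for h in (header[1:-1] if has_taxonomy else header[1:])]
    if len(set(sample_ids)) != len(sample_ids):
        raise OtuTableParseError(f"{path}: duplicated sample id in header")
    n_fields = len(header)
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    lineages: list[Lineage] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise OtuTableParseError(
                f"{path}:{lineno}: expected {n_fields} fields, found {len(fields)} (ragged row)")
        otu_ids.append(fields[0].strip())
        raw = fields[1:-1] if has_taxonomy else fields[1:]
        try:
            values = [int(v) for v in raw]
        except ValueError:
            # integers written as 3.0 are tolerated; true fractions are not
            values = []
            for v in raw:
                x = float(v)  # may raise -> non-numeric
                if x != int(x):
                    raise OtuTableParseError(
                        f"{path}:{lineno}: non-integer count {v!r} (counts required)") from None
                values.append(int(x))
        if any(v < 0 for v in values):
            raise OtuTableParseError(f"{path}:{lineno}: negative count")
        rows.append(values)
        if has_taxonomy:
            lineages.append(Lineage.parse(fields[-1]))
    if len(set(otu_ids)) != len(otu_ids):
        raise OtuTableParseError(f"{path}: duplicated OTU id")
    counts = (np.asarray(rows, dtype=np.int64).T if rows
              else np.zeros((len(sample_ids), 0), dtype=np.int64))
    try:
        return OtuTable(sample_ids, otu_ids, counts, lineages if has_taxonomy else None)
    except ValueError as exc:
        raise OtuTableParseError(f"{path}: {exc}") from exc


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the classic TSV layout; ``read_otu_table`` round-trips bit-exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        header = ["#OTU ID", *table.sample_ids]
        if table.lineages is not None:
            header.append("taxonomy")
        handle.write("\t".join(header) + "\n")
        for j, otu in enumerate(table.otu_ids):
            fields = [otu, *(str(int(v)) for v in table.counts[:, j])]
            if table.lineages is not None:
                fields.append(table.lineages[j].format())
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Site metadata TSV
# ---------------------------------------------------------------------------

_META_REQUIRED = ("sample_id", "latitude", "longitude")


def read_metadata(path: str | Path) -> SiteMetadata:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in _META_REQUIRED:
        if col not in frame.columns:
            raise MetadataParseError(f"{path}: missing required column {col!r}")
    soil = frame.pop("soil_type").astype(str).tolist() if "soil_type" in frame.columns else None
    env = frame.drop(columns=list(_META_REQUIRED))
    env = env.apply(pd.to_numeric)
    return SiteMetadata(
        sample_ids=frame["sample_id"].tolist(),
        latitude=frame["latitude"].to_numpy(float),
        longitude=frame["longitude"].to_numpy(float),
        env=env.reset_index(drop=True),
        soil_type=soil,
    )


def write_metadata(metadata: SiteMetadata, path: str | Path) -> None:
    frame = metadata.to_dataframe().reset_index(names="sample_id")
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> skbio.TreeNode:
    """Read a single rooted newick tree and validate it for UniFrac use.

    Missing branch lengths default to 0 (with a warning); negative lengths
    and duplicated leaf labels are errors.
    """
    import warnings

    path = Path(path)
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise ValueError(f"{path}: newick parse error: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(f"{path}: {n_missing} branches had no length; defaulted to 0",
                      stacklevel=2)
    validate_tree(tree)
    return tree


def validate_tree(tree: skbio.TreeNode) -> None:
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate leaf labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is not None and (not np.isfinite(node.length) or node.length < 0):
            raise ValueError(f"invalid branch length {node.length!r}")
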