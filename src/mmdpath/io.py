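"""Domain containers and file I/O for omics blocks, metadata and gene sets.

An :class:`OmicsBlock` is one samples x features real matrix (e.g. gene
expression, or fatty-acid concentrations).  Blocks are always stored
samples-in-rows; file orientation is declared explicitly at load time and
never auto-detected, because a silently transposed matrix is one of the
classic failure modes of omics pipelines.

Missing values are a hard error: the two-sample tests implemented here have
no missing-data model, so imputation belongs upstream of this package.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsBlock",
    "SampleMetadata",
    "GeneSet",
    "load_block",
    "write_block",
    "load_gene_set",
    "load_metadata",
    "subset_block",
    "align_samples",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class OmicsBlock:
    """One sample x feature real matrix with row/column identifiers.

    Parameters
    ----------
    name:
        Block label used in provenance records (e.g. ``"genes"``).
    sample_ids, feature_ids:
        Unique, ordered identifiers matching the rows / columns of ``values``.
    values:
        Real ``(n_samples, n_features)`` array; all entries must be finite.
    """

    name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"block {self.name!r}: matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample ids x {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.sample_ids, f"sample ids in block {self.name!r}")
        _check_unique(self.feature_ids, f"feature ids in block {self.name!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"block {self.name!r}: non-finite value at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def reorder(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        """Return a copy with rows restricted/reordered to ``sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"block {self.name!r} lacks samples {missing}")
        idx = [pos[s] for s in sample_ids]
        return OmicsBlock(self.name, list(sample_ids), list(self.feature_ids), self.values[idx])


@dataclass
class SampleMetadata:
    """Per-sample factor levels (e.g. genotype, diet)."""

    sample_ids: list[str]
    factors: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "metadata sample ids")
        for name, levels in self.factors.items():
            if len(levels) != len(self.sample_ids):
                raise ValueError(f"factor {name!r} has {len(levels)} entries for "
                                 f"{len(self.sample_ids)} samples")
            self.factors[name] = [str(v) for v in levels]

    def levels(self, factor: str) -> list[str]:
        """Distinct levels of ``factor`` in first-appearance order."""
        if factor not in self.factors:
            raise KeyError(f"unknown factor {factor!r}; available: {sorted(self.factors)}")
        return list(dict.fromkeys(self.factors[factor]))

    def binary_labels(
        self, factor: str, levels: tuple[str, str] | None = None
    ) -> np.ndarray:
        """Boolean mask (True = first level) for a two-level comparison.

        When the factor has more than two observed levels the caller must name
        the two levels to compare; samples at other levels are excluded via
        :meth:`select`, not here.
        """
        vals = np.asarray(self.factors[factor] if factor in self.factors else
                          self._missing(factor))
        if levels is None:
            obs = self.levels(factor)
            if len(obs) != 2:
                raise ValueError(
                    f"factor {factor!r} has levels {obs}; name exactly two to compare"
                )
            levels = (obs[0], obs[1])
        for lv in levels:
            if lv not in vals:
                raise ValueError(
                    f"level {lv!r} not found in factor {factor!r}; "
                    f"available: {self.levels(factor)}"
                )
        keep = np.isin(vals, levels)
        if not keep.all():
            raise ValueError(
                "metadata contains samples outside the two chosen levels; "
                "subset with select() first"
            )
        return vals == levels[0]

    def _missing(self, factor: str):
        raise KeyError(f"unknown factor {factor!r}; available: {sorted(self.factors)}")

    def select(self, factor: str, levels: Iterable[str]) -> "SampleMetadata":
        """Restrict to samples whose ``factor`` value is in ``levels``."""
        levels = list(levels)
        vals = self.factors[factor] if factor in self.factors else self._missing(factor)
        keep = [i for i, v in enumerate(vals) if v in levels]
        return SampleMetadata(
            [self.sample_ids[i] for i in keep],
            {f: [v[i] for i in keep] for f, v in self.factors.items()},
        )

    def reorder(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"metadata lacks samples {missing}")
        idx = [pos[s] for s in sample_ids]
        return SampleMetadata(
            list(sample_ids), {f: [v[i] for i in idx] for f, v in self.factors.items()}
        )


@dataclass
class GeneSet:
    """Named list of feature identifiers defining a pathway."""

    name: str
    feature_ids: list[str]

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise ValueError(f"gene set {self.name!r} is empty")
        _check_unique(self.feature_ids, f"members of gene set {self.name!r}")

    def __len__(self) -> int:
        return len(self.feature_ids)


Orientation = Literal["samples-in-rows", "samples-in-columns"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def load_block(
    path: str | Path,
    orientation: Orientation = "samples-in-rows",
    name: str | None = None,
) -> OmicsBlock:
    """Read a delimited numeric matrix (TSV or CSV) into an :class:`OmicsBlock`.

    The first column holds row ids and the header row holds column ids.
    ``orientation`` states which axis carries the samples in the *file*; the
    returned block is always samples-in-rows.  Non-numeric or missing cells
    are an error naming the offending cell.
    """
    path = Path(path)
    df = _read_table(path)
    if orientation not in ("samples-in-rows", "samples-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "samples-in-columns":
        df = df.T
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path.name}: non-numeric or missing value at row {bad[0]!r}, "
                f"column {col!r}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path.name}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return OmicsBlock(
        name=name if name is not None else path.stem,
        sample_ids=list(df.index.astype(str)),
        feature_ids=list(df.columns.astype(str)),
        values=values,
    )


def write_block(block: OmicsBlock, path: str | Path) -> None:
    """Write a block as TSV/CSV (samples in rows); inverse of :func:`load_block`."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = block.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def load_gene_set(path: str | Path, set_name: str) -> GeneSet:
    """Read one named set from a GMT file (name, description, tab-separated members).

    Duplicate members are dropped with a warning; an absent ``set_name``
    raises an error listing the sets present in the file.
    """
    path = Path(path)
    available: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            available.append(parts[0])
            if parts[0] != set_name:
                continue
            members = [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"gene set {set_name!r} in {path.name} has no members")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"gene set {set_name!r}: removed {len(members) - len(unique)} "
                    "duplicate member(s)", stacklevel=2,
                )
            return GeneSet(set_name, unique)
    raise KeyError(f"gene set {set_name!r} not found in {path.name}; available: {available}")


def subset_block(
    block: OmicsBlock,
    gene_set: GeneSet,
    on_missing: Literal["error", "warn-drop"] = "error",
) -> OmicsBlock:
    """Restrict a block's columns to the members of ``gene_set``.

    The *block's* column order is preserved (kernels are order-invariant, and
    block order keeps provenance simple).  Members absent from the block are
    an error, or dropped with a warning under ``on_missing="warn-drop"``.
    """
    wanted = set(gene_set.feature_ids)
    keep = [f for f in block.feature_ids if f in wanted]
    absent = [f for f in gene_set.feature_ids if f not in set(block.feature_ids)]
    if not keep:
        raise ValueError(
            f"gene set {gene_set.name!r} shares no features with block {block.name!r}"
        )
    if absent:
        if on_missing == "error":
            raise ValueError(
                f"gene set {gene_set.name!r}: members absent from block "
                f"{block.name!r}: {absent}"
            )
        warnings.warn(
            f"gene set {gene_set.name!r}: dropping {len(absent)} member(s) absent "
            f"from block {block.name!r}: {absent}", stacklevel=2,
        )
    cols = [block.feature_ids.index(f) for f in keep]
    return OmicsBlock(block.name, list(block.sample_ids), keep, block.values[:, cols])


def align_samples(
    blocks: Sequence[OmicsBlock], metadata: SampleMetadata
) -> tuple[list[OmicsBlock], SampleMetadata]:
    """Restrict all blocks and the metadata to one shared, ordered sample set.

    The common order is the metadata's sample order restricted to the
    intersection of all blocks' ids (an empty intersection is an error).
    Required before kernels over different blocks can be added.
    """
    if not blocks:
        raise ValueError("align_samples needs at least one block")
    common = set(metadata.sample_ids)
    for b in blocks:
        common &= set(b.sample_ids)
    order = [s for s in metadata.sample_ids if s in common]
    if not order:
        raise ValueError("no samples shared by all blocks and the metadata")
    dropped = sum(b.n_samples - len(order) for b in blocks)
    if dropped:
        logger.info("align_samples: intersection keeps %d samples", len(order))
    return [b.reorder(order) for b in blocks], metadata.reorder(order)


def load_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata from TSV/CSV (one row per sample) or JSON.

    Tabular input: first column = sample id, remaining columns = factors.
    JSON input: ``{"sample_ids": [...], "factors": {name: [levels...]}}``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return SampleMetadata(payload["sample_ids"], payload["factors"])
    df = _read_table(path)
    return SampleMetadata(
        list(df.index.astype(str)),
        {c: list(df[c].astype(str)) for c in df.columns},
    )
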