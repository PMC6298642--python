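"""Data model and I/O for enhancer-promoter (EP) pair datasets.

An *EP pair* is a candidate (enhancer, promoter) element pair on one
chromosome, labelled interacting (1) or not (0).  Each pair carries a
feature vector partitioned into three blocks of epigenomic signal
summaries:

``E``
    signals over the enhancer element,
``P``
    signals over the promoter element, shared verbatim by every pair
    attached to the same promoter,
``W``
    signals over the *window*, the genomic interval between the two
    elements, which overlapping pairs partially share.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Strand is ignored throughout.

File formats
------------
Pairs file
    tab-separated with header
    ``pair_id chrom enh_start enh_end prom_start prom_end promoter_id label``.
Features file
    tab-separated with a ``pair_id`` column followed by feature columns
    named ``<BLOCK>|<mark_name>`` with ``BLOCK`` one of ``E``, ``P``, ``W``
    (e.g. ``P|H3K4me3``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BLOCKS",
    "EPDataError",
    "FormatError",
    "JoinError",
    "GenomicInterval",
    "EPPair",
    "FeatureTable",
    "EPDataset",
    "window_interval",
    "feature_subset",
    "load_pairs",
    "write_pairs",
    "assign_promoter_ids",
    "natural_chrom_key",
]

BLOCKS = ("E", "P", "W")

PAIRS_COLUMNS = [
    "pair_id",
    "chrom",
    "enh_start",
    "enh_end",
    "prom_start",
    "prom_end",
    "promoter_id",
    "label",
]


class EPDataError(ValueError):
    """Base class for EP dataset validation failures."""


class FormatError(EPDataError):
    """A file or field violates the documented format."""


class JoinError(EPDataError):
    """Pairs file and features file cannot be joined one-to-one."""


def natural_chrom_key(name: str) -> tuple:
    """Sort key placing ``chr2`` before ``chr10`` (natural numeric order).

    Digit runs compare numerically, other runs lexicographically; the key
    is usable across heterogeneous names (``chr1``, ``chrX``, ``scaffold_2``).
    """
    parts = []
    for token in re.split(r"(\d+)", name):
        if token == "":
            continue
        if token.isdigit():
            parts.append((0, int(token), ""))
        else:
            parts.append((1, 0, token))
    return tuple(parts)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise FormatError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class EPPair:
    """One candidate enhancer-promoter pair with its interaction label."""

    pair_id: str
    enhancer: GenomicInterval
    promoter: GenomicInterval
    promoter_id: str
    label: int

    def __post_init__(self) -> None:
        if self.enhancer.chrom != self.promoter.chrom:
            raise FormatError(
                f"pair {self.pair_id}: enhancer on {self.enhancer.chrom} but "
                f"promoter on {self.promoter.chrom}"
            )
        if self.enhancer.overlaps(self.promoter):
            raise FormatError(
                f"pair {self.pair_id}: enhancer and promoter intervals overlap"
            )
        if self.label not in (0, 1):
            raise FormatError(
                f"pair {self.pair_id}: label must be 0 or 1, got {self.label!r}"
            )

    @property
    def chrom(self) -> str:
        return self.enhancer.chrom


def window_interval(pair: EPPair) -> GenomicInterval:
    """The window of a pair: the open gap between enhancer and promoter.

    The window excludes both elements.  For an enhancer ``[100, 200)`` and
    promoter ``[500, 600)`` the window is ``[200, 500)``, regardless of
    which element comes first on the chromosome.

    Raises
    ------
    FormatError
        If the elements are adjacent, so the gap has zero width.
    """
    start = min(pair.enhancer.end, pair.promoter.end)
    end = max(pair.enhancer.start, pair.promoter.start)
    if start >= end:
        raise FormatError(
            f"pair {pair.pair_id}: enhancer and promoter are adjacent; "
            "the window between them has zero width"
        )
    return GenomicInterval(pair.chrom, start, end)


def window_midpoint(pair: EPPair) -> float:
    """Midpoint of the gap between the elements (defined even at width 0)."""
    lo = min(pair.enhancer.end, pair.promoter.end)
    hi = max(pair.enhancer.start, pair.promoter.start)
    return (lo + hi) / 2.0


@dataclass
class FeatureTable:
    """A pairs x features matrix with a block tag (E/P/W) per column."""

    values: np.ndarray
    column_names: list[str]
    column_blocks: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("feature values must be a 2-D matrix")
        if len(self.column_names) != self.values.shape[1]:
            raise FormatError("one name per feature column required")
        if len(self.column_blocks) != self.values.shape[1]:
            raise FormatError("one block tag per feature column required")
        bad = sorted({b for b in self.column_blocks} - set(BLOCKS))
        if bad:
            raise FormatError(f"unknown feature block tag(s): {bad}")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def block_counts(self) -> dict[str, int]:
        """Number of columns per block, e.g. ``{'E': 136, 'P': 136, 'W': 136}``."""
        counts = {b: 0 for b in BLOCKS}
        for b in self.column_blocks:
            counts[b] += 1
        return counts

    def file_column_names(self) -> list[str]:
        return [f"{b}|{n}" for b, n in zip(self.column_blocks, self.column_names)]

    @staticmethod
    def empty(n_rows: int) -> "FeatureTable":
        return FeatureTable(np.empty((n_rows, 0)), [], [])


@dataclass
class EPDataset:
    """An ordered collection of EP pairs plus an aligned feature table.

    Row ``i`` of ``features.values`` belongs to ``pairs[i]``.
    """

    pairs: list[EPPair]
    features: FeatureTable

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate pair_id(s): {dupes[:5]}")
        if self.features.n_rows != len(self.pairs):
            raise FormatError(
                f"feature table has {self.features.n_rows} rows for "
                f"{len(self.pairs)} pairs"
            )
        by_prom: dict[str, GenomicInterval] = {}
        for p in self.pairs:
            seen = by_prom.setdefault(p.promoter_id, p.promoter)
            if seen != p.promoter:
                raise FormatError(
                    f"promoter_id {p.promoter_id} maps to two distinct "
                    "promoter intervals"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=int)

    @property
    def promoter_ids(self) -> list[str]:
        return [p.promoter_id for p in self.pairs]

    def pairs_frame(self) -> pd.DataFrame:
        rows = [
            (
                p.pair_id,
                p.chrom,
                p.enhancer.start,
                p.enhancer.end,
                p.promoter.start,
                p.promoter.end,
                p.promoter_id,
                p.label,
            )
            for p in self.pairs
        ]
        return pd.DataFrame(rows, columns=PAIRS_COLUMNS)


def feature_subset(dataset: EPDataset, blocks: Iterable[str]) -> FeatureTable:
    """Select the feature columns whose block tag is in ``blocks``.

    Column order is preserved; ``blocks={'E','P','W'}`` returns the full
    EPW table, ``{'W'}`` only the window block, and so on.
    """
    blocks = set(blocks)
    if not blocks:
        raise EPDataError("blocks must be a non-empty subset of {'E','P','W'}")
    bad = sorted(blocks - set(BLOCKS))
    if bad:
        raise EPDataError(f"unknown feature block(s): {bad}")
    ft = dataset.features
    keep = [i for i, b in enumerate(ft.column_blocks) if b in blocks]
    return FeatureTable(
        ft.values[:, keep],
        [ft.column_names[i] for i in keep],
        [ft.column_blocks[i] for i in keep],
    )


def assign_promoter_ids(pairs_frame: pd.DataFrame) -> pd.Series:
    """Derive promoter IDs from exact promoter-interval identity.

    Used when a pairs table lacks the ``promoter_id`` column; pairs whose
    promoter intervals are byte-identical get the same ID.  IDs are
    assigned in order of first appearance.
    """
    keys = list(
        zip(pairs_frame["chrom"], pairs_frame["prom_start"], pairs_frame["prom_end"])
    )
    mapping: dict[tuple, str] = {}
    out = []
    for key in keys:
        if key not in mapping:
            mapping[key] = f"prom_{len(mapping):05d}"
        out.append(mapping[key])
    return pd.Series(out, index=pairs_frame.index)


def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - delegated parse failures
        raise FormatError(f"could not parse {path}: {exc}") from exc


def load_pairs(pairs_path: str | Path, features_path: str | Path) -> EPDataset:
    """Load a dataset from a pairs file and a matching features file.

    Feature rows are joined to pairs by ``pair_id``; the returned dataset
    keeps the pair-file row order.

    Raises
    ------
    JoinError
        A ``pair_id`` present in one file is missing from the other.
    FormatError
        Malformed intervals (reported with the offending line number),
        duplicate pair IDs, bad labels, or unknown block tags.
    """
    pdf = _read_table(pairs_path)
    missing_cols = [c for c in PAIRS_COLUMNS if c not in pdf.columns and c != "promoter_id"]
    if missing_cols:
        raise FormatError(f"{pairs_path}: missing column(s) {missing_cols}")
    if "promoter_id" not in pdf.columns:
        pdf = pdf.assign(promoter_id=assign_promoter_ids(pdf))

    pairs: list[EPPair] = []
    for idx, row in enumerate(pdf.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        try:
            enh = GenomicInterval(str(row.chrom), int(row.enh_start), int(row.enh_end))
            prom = GenomicInterval(str(row.chrom), int(row.prom_start), int(row.prom_end))
            pairs.append(
                EPPair(str(row.pair_id), enh, prom, str(row.promoter_id), int(row.label))
            )
        except (FormatError, TypeError) as exc:
            raise FormatError(f"{pairs_path}, line {line_no}: {exc}") from exc

    fdf = _read_table(features_path)
    if "pair_id" not in fdf.columns:
        raise FormatError(f"{features_path}: missing pair_id column")
    if fdf["pair_id"].duplicated().any():
        dupes = fdf.loc[fdf["pair_id"].duplicated(), "pair_id"].tolist()
        raise FormatError(f"{features_path}: duplicate pair_id(s): {dupes[:5]}")

    pair_ids = [p.pair_id for p in pairs]
    if len(set(pair_ids)) != len(pair_ids):
        dupes = sorted({i for i in pair_ids if pair_ids.count(i) > 1})
        raise FormatError(f"{pairs_path}: duplicate pair_id(s): {dupes[:5]}")

    feat_ids = set(fdf["pair_id"])
    missing = [i for i in pair_ids if i not in feat_ids]
    if missing:
        raise JoinError(
            f"pair_id {missing[0]!r} from {pairs_path} has no feature row"
        )
    extra = sorted(feat_ids - set(pair_ids))
    if extra:
        raise JoinError(
            f"pair_id {extra[0]!r} from {features_path} is absent from the pairs file"
        )

    fdf = fdf.set_index("pair_id").loc[pair_ids]
    names, blocks = [], []
    for col in fdf.columns:
        if "|" not in col:
            raise FormatError(
                f"{features_path}: feature column {col!r} is not of the form "
                "<BLOCK>|<mark_name>"
            )
        block, name = col.split("|", 1)
        if block not in BLOCKS:
            raise FormatError(f"{features_path}: unknown block {block!r} in {col!r}")
        blocks.append(block)
        names.append(name)
    values = fdf.to_numpy(dtype=float) if len(fdf.columns) else np.empty((len(pairs), 0))
    return EPDataset(pairs, FeatureTable(values, names, blocks))


def write_pairs(
    dataset: EPDataset, pairs_path: str | Path, features_path: str | Path
) -> None:
    """Write a dataset as the two tab-separated files read by `load_pairs`.

    Feature values are serialized with 17 significant digits so a round
    trip reproduces them exactly to double precision.
    """
    dataset.pairs_frame().to_csv(pairs_path, sep="\t", index=False)
    fdf = pd.DataFrame(
        dataset.features.values,
        columns=dataset.features.file_column_names(),
    )
    fdf.insert(0, "pair_id", dataset.pair_ids)
    fdf.to_csv(features_path, sep="\t", index=False, float_format="%.17g")
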