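"""Domain types and TSV readers/writers for ASV feature tables, taxonomy and metadata.

The on-disk dialects are the QIIME2 export conventions: a tab-separated
feature table with features as rows and a ``#OTU ID`` header cell, a
taxonomy table with ``Feature ID`` / ``Taxon`` / optional ``Confidence``
columns (Greengenes-style ``k__...;p__...;...;s__...`` lineage strings),
and a plain sample-metadata table.  All files are UTF-8, tab-delimited,
with ``.`` as the decimal separator.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "Lineage",
    "TaxonomyMap",
    "SampleMetadata",
    "RANKS",
    "RANK_PREFIXES",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

BODY_SITES = ("nasal", "rectal")
NASAL_SITES = ("external", "standard", "middle", "deep", "not-applicable")
MOLECULES = ("DNA", "RNA")

METADATA_COLUMNS = (
    "sample_id",
    "animal_id",
    "farm",
    "body_site",
    "nasal_site",
    "molecule",
    "is_control",
)


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} {i!r}")
        seen.add(i)
    return ids


@dataclasses.dataclass
class FeatureTable:
    """Sample x ASV matrix of non-negative integer read counts.

    ``sample_ids`` index the rows and ``asv_ids`` the columns of
    ``counts``; both orders are preserved through read/write round-trips.
    ASV identity is the exact identifier string (an amplicon sequence or a
    stable hash of one), so cross-file matching is plain string equality.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample id")
        self.asv_ids = _check_unique(self.asv_ids, "ASV id")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if counts.size == 0:
            raise FormatError("empty feature table")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                bad = np.argwhere(rounded != counts)[0]
                raise FormatError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"ASV {self.asv_ids[bad[1]]!r}"
                )
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"ASV {self.asv_ids[bad[1]]!r}"
            )
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def depths(self) -> pd.Series:
        """Total read count per sample."""
        return pd.Series(self.counts.sum(axis=1), index=self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        """Samples as rows, ASVs as columns."""
        return pd.DataFrame(
            self.counts.copy(), index=list(self.sample_ids), columns=list(self.asv_ids)
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        keep = list(sample_ids)
        missing = [s for s in keep if s not in set(self.sample_ids)]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [self.sample_ids.index(s) for s in keep]
        return FeatureTable(keep, list(self.asv_ids), self.counts[idx, :])

    def drop_asvs(self, asv_ids: Iterable[str]) -> "FeatureTable":
        drop = set(asv_ids)
        keep_idx = [j for j, a in enumerate(self.asv_ids) if a not in drop]
        return FeatureTable(
            list(self.sample_ids),
            [self.asv_ids[j] for j in keep_idx],
            self.counts[:, keep_idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclasses.dataclass(frozen=True)
class Lineage:
    """A Greengenes 13.8-style seven-rank lineage.

    ``ranks`` holds the seven names kingdom..species; unnamed ranks are
    empty strings.  Square brackets mark contested names in Greengenes and
    are preserved verbatim (e.g. ``[Weeksellaceae]``).  ``raw`` keeps the
    original string for faithful round-trips.
    """

    ranks: tuple[str, ...]
    raw: str = ""

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValueError("a lineage has exactly 7 rank slots")
        if not self.raw:
            object.__setattr__(self, "raw", self.to_string())

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse ``k__Bacteria; p__...``; missing deeper ranks become empty."""
        tokens = [t.strip() for t in text.split(";")] if text.strip() else []
        names: list[str] = []
        for i, tok in enumerate(tokens):
            if i >= 7:
                raise FormatError(f"more than 7 rank tokens in lineage {text!r}")
            if "__" not in tok:
                raise FormatError(
                    f"malformed rank token {tok!r} (missing '__') in lineage {text!r}"
                )
            prefix, _, name = tok.partition("__")
            if prefix + "__" != RANK_PREFIXES[i]:
                raise FormatError(
                    f"rank token {tok!r} out of order in lineage {text!r}: "
                    f"expected prefix {RANK_PREFIXES[i]!r}"
                )
            names.append(name.strip())
        names.extend([""] * (7 - len(names)))
        return cls(tuple(names), raw=text)

    def to_string(self) -> str:
        return "; ".join(p + n for p, n in zip(RANK_PREFIXES, self.ranks))

    def name_at(self, rank: str) -> str:
        return self.ranks[rank_index(rank)]

    @property
    def kingdom(self) -> str:
        return self.ranks[0]

    @property
    def order(self) -> str:
        return self.ranks[3]

    @property
    def family(self) -> str:
        return self.ranks[4]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    def prefix(self, rank: str) -> tuple[str, ...]:
        """Lineage names from kingdom down to ``rank`` inclusive."""
        return self.ranks[: rank_index(rank) + 1]

    def display_label(self, rank: str) -> str:
        """Name at ``rank``, or ``<deepest named ancestor> (unclass.)``.

        Mirrors the common display convention for taxa unnamed at the
        requested rank, e.g. an ASV with ``o__Bacteroidales; f__; g__``
        shown at genus level as ``Bacteroidales (unclass.)``.
        """
        k = rank_index(rank)
        if self.ranks[k]:
            return self.ranks[k]
        for name in reversed(self.ranks[:k]):
            if name:
                return f"{name} (unclass.)"
        return "Unassigned (unclass.)"


def rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank.lower())
    except ValueError:
        raise ValueError(f"invalid rank {rank!r}; expected one of {RANKS}") from None


def normalize_taxon(name: str) -> str:
    """Case-fold and strip contested-name brackets, for matching only."""
    return name.strip().strip("[]").lower()


class TaxonomyMap:
    """Mapping of ASV id to :class:`Lineage`, with optional confidences.

    Lookups of unknown ASVs raise ``KeyError`` — there is no silent
    "Unassigned" fallback, so a table/taxonomy mismatch fails loudly.
    """

    def __init__(
        self,
        mapping: Mapping[str, Lineage],
        confidence: Mapping[str, float] | None = None,
    ) -> None:
        self._map = dict(mapping)
        for asv in self._map:
            if not asv or not asv.strip():
                raise FormatError("blank ASV id in taxonomy")
        self.confidence = dict(confidence) if confidence is not None else None
        if self.confidence is not None:
            for asv, c in self.confidence.items():
                if not 0.0 <= float(c) <= 1.0:
                    raise FormatError(f"confidence for {asv!r} outside [0, 1]: {c}")

    def __getitem__(self, asv_id: str) -> Lineage:
        try:
            return self._map[asv_id]
        except KeyError:
            raise KeyError(f"ASV {asv_id!r} has no taxonomy assignment") from None

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self):
        return iter(self._map)

    def items(self):
        return self._map.items()

    def require(self, asv_ids: Iterable[str]) -> None:
        """Fail loudly if any of ``asv_ids`` lacks a lineage."""
        missing = [a for a in asv_ids if a not in self._map]
        if missing:
            raise KeyError(
                f"{len(missing)} ASV(s) missing from taxonomy, e.g. {missing[0]!r}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyMap):
            return NotImplemented
        return self._map == other._map and self.confidence == other.confidence


class SampleMetadata:
    """Per-sample study factors.

    Columns: ``sample_id``, ``animal_id``, ``farm``, ``body_site``
    (nasal/rectal), ``nasal_site`` (external/standard/middle/deep or
    not-applicable for rectal samples), ``molecule`` (DNA/RNA) and
    ``is_control``.  Vocabularies are closed sets: unknown levels are
    errors, not new categories.  Input case is folded to the canonical
    spelling.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        df = frame.copy()
        missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"metadata missing columns {missing_cols}")
        df = df[list(METADATA_COLUMNS)]
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample id")
        df["body_site"] = [
            _canonical(v, BODY_SITES, "body_site") for v in df["body_site"]
        ]
        df["nasal_site"] = [
            _canonical(v, NASAL_SITES, "nasal_site") for v in df["nasal_site"]
        ]
        df["molecule"] = [_canonical(v, MOLECULES, "molecule") for v in df["molecule"]]
        df["is_control"] = [_parse_bool(v) for v in df["is_control"]]
        for _, row in df.iterrows():
            rectal = row.body_site == "rectal"
            na = row.nasal_site == "not-applicable"
            if rectal != na:
                raise FormatError(
                    f"sample {row.sample_id!r}: nasal_site must be "
                    f"'not-applicable' iff body_site is 'rectal' "
                    f"(got {row.body_site!r}/{row.nasal_site!r})"
                )
        noncontrol = df[~df["is_control"]]
        key = ["animal_id", "body_site", "nasal_site", "molecule"]
        dup = noncontrol[noncontrol.duplicated(subset=key, keep=False)]
        if len(dup):
            first = dup.iloc[0]
            raise FormatError(
                "duplicate non-control sample slot "
                f"({first.animal_id}, {first.body_site}, {first.nasal_site}, "
                f"{first.molecule})"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def control_ids(self, molecule: str | None = None) -> list[str]:
        df = self.frame[self.frame["is_control"]]
        if molecule is not None:
            df = df[df["molecule"] == _canonical(molecule, MOLECULES, "molecule")]
        return list(df["sample_id"])

    def subset(self, **conditions) -> "pd.DataFrame":
        """Rows matching all ``column=value`` conditions."""
        df = self.frame
        for col, val in conditions.items():
            if col not in df.columns:
                raise KeyError(f"unknown metadata column {col!r}")
            df = df[df[col] == val]
        return df

    def row(self, sample_id: str) -> pd.Series:
        hit = self.frame[self.frame["sample_id"] == sample_id]
        if hit.empty:
            raise KeyError(f"sample {sample_id!r} not in metadata")
        return hit.iloc[0]

    def drop_samples(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        drop = set(sample_ids)
        return SampleMetadata(self.frame[~self.frame["sample_id"].isin(drop)])

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.frame.equals(other.frame)


def _canonical(value: object, vocabulary: tuple[str, ...], what: str) -> str:
    v = str(value).strip()
    for canon in vocabulary:
        if v.lower() == canon.lower():
            return canon
    raise FormatError(f"unknown {what} value {value!r}; allowed: {vocabulary}")


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise FormatError(f"unknown boolean value {value!r} in is_control")


# ---------------------------------------------------------------------------
# Readers / writers


def read_feature_table(path: str | Path, samples_as_rows: bool = False) -> FeatureTable:
    """Read a QIIME2-export style TSV feature table.

    The default dialect has features as rows with a ``#OTU ID`` header
    cell; pass ``samples_as_rows=True`` for the transposed dialect.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=0, index_col=0, dtype=str, comment=None,
        skip_blank_lines=True,
    )
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: empty feature table")
    if not samples_as_rows and df.index.name != "#OTU ID":
        raise FormatError(
            f"{path}: first header cell is {df.index.name!r}, expected '#OTU ID' "
            "(use samples_as_rows=True for the transposed dialect)"
        )
    _check_unique(df.index.astype(str), "ASV id" if not samples_as_rows else "sample id")
    _check_unique(df.columns.astype(str), "sample id" if not samples_as_rows else "ASV id")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count cell ({exc})") from None
    if not samples_as_rows:
        return FeatureTable(
            sample_ids=[str(c) for c in df.columns],
            asv_ids=[str(i) for i in df.index],
            counts=values.T,
        )
    return FeatureTable(
        sample_ids=[str(i) for i in df.index],
        asv_ids=[str(c) for c in df.columns],
        counts=values,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write features-as-rows TSV with the ``#OTU ID`` header cell."""
    df = pd.DataFrame(
        table.counts.T, index=table.asv_ids, columns=table.sample_ids
    )
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a ``Feature ID / Taxon [/ Confidence]`` TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    for col in ("Feature ID", "Taxon"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    _check_unique(df["Feature ID"], "Feature ID")
    mapping = {
        str(row["Feature ID"]): Lineage.from_string(str(row["Taxon"]))
        for _, row in df.iterrows()
    }
    confidence = None
    if "Confidence" in df.columns:
        confidence = {
            str(row["Feature ID"]): float(row["Confidence"])
            for _, row in df.iterrows()
        }
    return TaxonomyMap(mapping, confidence)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    rows = []
    for asv, lin in tax.items():
        row = {"Feature ID": asv, "Taxon": lin.raw or lin.to_string()}
        if tax.confidence is not None:
            row["Confidence"] = tax.confidence.get(asv, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(Path(path), sep="\t", header=0, dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.frame.copy()
    out["is_control"] = out["is_control"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)
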