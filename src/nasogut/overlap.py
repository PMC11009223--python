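"""Top-N ASV overlap between body sites, within a farm, and across farms.

For each farm and taxon group (a gut-associated order, or a nasal-
colonizer family), the N most abundant ASVs in nasal and in rectal
samples are selected by mean relative abundance across that stratum's
animals (zeros included).  ASVs in both top lists are "shared"; the
shared percentage can be expressed relative to the union of the two
lists (default) or to N itself — the two conventions differ whenever the
lists do not coincide, and both are exposed because published figures
rarely say which one they use.  ASVs shared in every farm (by exact
sequence identity) form the cross-farm shared set.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

from .composition import RelAbundTable
from .iotab import TaxonomyMap, normalize_taxon

__all__ = [
    "NASAL_COLONIZER_FAMILIES",
    "TaxonGroupFilter",
    "OverlapResult",
    "top_n_asvs",
    "classify_overlap",
    "cross_farm_shared",
]

#: Families repeatedly reported as nasal colonizers in pigs.
NASAL_COLONIZER_FAMILIES = (
    "Lactobacillaceae",
    "Moraxellaceae",
    "Pasteurellaceae",
    "Streptococcaceae",
    "[Weeksellaceae]",
)


@dataclasses.dataclass(frozen=True)
class TaxonGroupFilter:
    """A set of order- or family-level labels restricting the ASV universe."""

    mode: str  # "order" | "family"
    labels: frozenset[str]

    def __post_init__(self) -> None:
        if self.mode not in ("order", "family"):
            raise ValueError(f"mode must be 'order' or 'family', got {self.mode!r}")
        if not self.labels:
            raise ValueError("a taxon group needs at least one label")
        object.__setattr__(self, "labels", frozenset(self.labels))

    @property
    def name(self) -> str:
        return "+".join(sorted(self.labels))

    def matches(self, lineage) -> bool:
        name = lineage.name_at(self.mode)
        targets = {normalize_taxon(l) for l in self.labels}
        return normalize_taxon(name) in targets


@dataclasses.dataclass
class OverlapResult:
    """Shared / site-specific classification of one farm x group cell."""

    farm: str
    group: str
    nasal_only: set[str]
    rectal_only: set[str]
    shared: set[str]
    shared_pct: float
    denominator: str
    mean_nasal: dict[str, float]
    mean_rectal: dict[str, float]
    cross_farm_shared: set[str] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        if self.nasal_only & self.rectal_only or self.nasal_only & self.shared or (
            self.rectal_only & self.shared
        ):
            raise ValueError("overlap classes must be pairwise disjoint")

    @property
    def union(self) -> set[str]:
        return self.nasal_only | self.rectal_only | self.shared

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for asv in sorted(self.union):
            if asv in self.cross_farm_shared:
                cls = "shared_cross_farm"
            elif asv in self.shared:
                cls = "shared"
            elif asv in self.nasal_only:
                cls = "nasal_only"
            else:
                cls = "rectal_only"
            rows.append(
                {
                    "farm": self.farm,
                    "group": self.group,
                    "asv_id": asv,
                    "mean_nasal": self.mean_nasal.get(asv, 0.0),
                    "mean_rectal": self.mean_rectal.get(asv, 0.0),
                    "class": cls,
                }
            )
        return pd.DataFrame(rows)


def top_n_asvs(
    rel: RelAbundTable,
    tax: TaxonomyMap,
    group: TaxonGroupFilter,
    n: int,
) -> list[tuple[str, float]]:
    """The n most abundant group ASVs in one stratum, with their means.

    ``rel`` must contain only the stratum's samples (one farm, one body
    site, one molecule).  Ranking is by mean relative abundance across
    those samples (zero-count animals included), descending; ties broken
    by ascending ASV id, so the output is deterministic.  Truncated to
    min(n, matching ASVs) — no padding.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tax.require(rel.asv_ids)
    df = rel.to_dataframe()
    matching = [a for a in rel.asv_ids if group.matches(tax[a])]
    if not matching:
        raise ValueError(
            f"no ASV matches taxon group {group.name!r} at rank {group.mode}"
        )
    means = df[matching].mean(axis=0)
    ranked = sorted(matching, key=lambda a: (-means[a], a))
    return [(a, float(means[a])) for a in ranked[:n]]


def classify_overlap(
    top_nasal: Sequence[tuple[str, float]],
    top_rectal: Sequence[tuple[str, float]],
    denominator: str = "union",
    farm: str = "",
    group: str = "",
) -> OverlapResult:
    """Set-classify two ranked top-N lists into shared / site-only ASVs.

    ``shared_pct`` = 100 * |shared| / |union of the two lists| for
    ``denominator='union'`` (default), or 100 * |shared| / N with
    ``denominator='per_site_n'`` where N is the longer list's length.
    """
    if denominator not in ("union", "per_site_n"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if not top_nasal or not top_rectal:
        raise ValueError("both top-N lists must be non-empty")
    mean_nasal = {a: m for a, m in top_nasal}
    mean_rectal = {a: m for a, m in top_rectal}
    nasal_set, rectal_set = set(mean_nasal), set(mean_rectal)
    shared = nasal_set & rectal_set
    union = nasal_set | rectal_set
    denom = len(union) if denominator == "union" else max(
        len(top_nasal), len(top_rectal)
    )
    return OverlapResult(
        farm=farm,
        group=group,
        nasal_only=nasal_set - shared,
        rectal_only=rectal_set - shared,
        shared=shared,
        shared_pct=100.0 * len(shared) / denom,
        denominator=denominator,
        mean_nasal=mean_nasal,
        mean_rectal=mean_rectal,
    )


def cross_farm_shared(
    results: Mapping[str, OverlapResult], min_farms: int | None = None
) -> set[str]:
    """ASVs in the shared set of at least ``min_farms`` farms (default: all).

    Annotates each farm's result's ``cross_farm_shared`` in place and
    returns the set.  All results must concern the same taxon group.
    """
    if len(results) < 2:
        raise ValueError("cross-farm sharing needs at least 2 farms")
    groups = {r.group for r in results.values()}
    if len(groups) != 1:
        raise ValueError(f"taxon group mismatch across farms: {sorted(groups)}")
    if min_farms is None:
        min_farms = len(results)
    counts: dict[str, int] = {}
    for res in results.values():
        for asv in res.shared:
            counts[asv] = counts.get(asv, 0) + 1
    across = {asv for asv, c in counts.items() if c >= min_farms}
    for res in results.values():
        res.cross_farm_shared = across & res.shared
    return across
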