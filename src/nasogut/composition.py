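"""Relative abundance, rank aggregation, gut-associated fraction, display summaries.

The gut-microbiota associated fraction of a sample is the summed relative
abundance of the orders Bacteroidales and Clostridiales — the dominant
orders of the pig gut microbiota.  Order names are matched by string
equality against the Greengenes 13.8 ``o__`` slot; no synonym mapping
(e.g. no Eubacteriales aliasing) is applied.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .iotab import FeatureTable, TaxonomyMap, rank_index

__all__ = [
    "GUT_ORDERS",
    "RelAbundTable",
    "to_relative",
    "aggregate_by_rank",
    "gut_fraction",
    "stratum_stats",
    "summarize_orders",
    "select_taxa_by_mean",
    "rank_by_prevalence",
]

GUT_ORDERS = ("Bacteroidales", "Clostridiales")


@dataclasses.dataclass
class RelAbundTable:
    """Sample x ASV compositional fractions; each row sums to 1.

    Construction rejects rows that do not lie on the simplex (within
    1e-9), so zero-depth samples can never be silently present.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValueError("values shape does not match axis labels")
        sums = values.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"sample {self.sample_ids[bad[0]]!r} row sums to {sums[bad[0]]!r}, "
                "not 1 (zero-depth or unnormalized sample?)"
            )
        if (values < 0).any():
            raise ValueError("negative relative abundance")
        self.values = values

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.asv_ids)
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "RelAbundTable":
        keep = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in keep]
        return RelAbundTable(keep, list(self.asv_ids), self.values[idx, :])


def to_relative(table: FeatureTable) -> RelAbundTable:
    """Divide each count by its sample's depth; rows then sum to 1."""
    depths = table.counts.sum(axis=1)
    zero = np.where(depths == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-depth sample {table.sample_ids[zero[0]]!r}; "
            "drop it before normalizing"
        )
    values = table.counts / depths[:, None]
    return RelAbundTable(list(table.sample_ids), list(table.asv_ids), values)


def aggregate_by_rank(
    rel: RelAbundTable, tax: TaxonomyMap, rank: str
) -> pd.DataFrame:
    """Sum ASV fractions at a taxonomic rank; returns taxon x sample frame.

    ASVs sharing the full lineage prefix down to ``rank`` are summed.
    ASVs unnamed at ``rank`` are labeled ``<deepest named ancestor>
    (unclass.)``.  Column (per-sample) sums are preserved exactly.
    """
    rank_index(rank)  # validates the token
    tax.require(rel.asv_ids)
    df = rel.to_dataframe()
    # group by full lineage prefix (distinct lineages stay distinct even
    # when unnamed at `rank`), then merge prefixes sharing a display label
    prefix_of = {a: tax[a].prefix(rank) for a in rel.asv_ids}
    label_of_prefix = {
        prefix_of[a]: tax[a].display_label(rank) for a in rel.asv_ids
    }
    by_label = df.T.groupby(
        [label_of_prefix[prefix_of[a]] for a in df.columns], sort=False
    ).sum()
    by_label.index.name = "taxon"
    return by_label


def gut_fraction(
    rel: RelAbundTable, tax: TaxonomyMap
) -> pd.DataFrame:
    """Per-sample summed relative abundance of each gut-associated order.

    Returns a frame indexed by sample with columns ``bacteroidales`` and
    ``clostridiales``.  Use :func:`stratum_stats` for mean +/- SD per
    metadata stratum.
    """
    tax.require(rel.asv_ids)
    orders = np.array([tax[a].order for a in rel.asv_ids])
    out = {}
    for order in GUT_ORDERS:
        mask = orders == order
        out[order.lower()] = rel.values[:, mask].sum(axis=1)
    return pd.DataFrame(out, index=list(rel.sample_ids))


def stratum_stats(
    per_sample: pd.DataFrame,
    strata: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of per-sample values within strata.

    ``strata`` maps a stratum name to its member sample ids; an empty
    stratum is a hard error (it signals a metadata/selection bug).
    """
    rows = []
    for name, samples in strata.items():
        samples = list(samples)
        if not samples:
            raise ValueError(f"empty stratum {name!r}")
        missing = [s for s in samples if s not in per_sample.index]
        if missing:
            raise KeyError(f"stratum {name!r} has unknown samples {missing[:5]}")
        sub = per_sample.loc[samples]
        for col in per_sample.columns:
            rows.append(
                {
                    "stratum": name,
                    "quantity": col,
                    "n": len(samples),
                    "mean": float(sub[col].mean()),
                    "sd_n_minus_1": float(sub[col].std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)


def summarize_orders(
    rel: RelAbundTable,
    tax: TaxonomyMap,
    display_threshold: float = 0.01,
) -> pd.DataFrame:
    """Four-part per-sample composition for the stacked-bar display.

    Per sample: ``bacteroidales`` and ``clostridiales`` fractions (always
    reported separately, whatever their mean), ``other`` = summed non-gut
    orders whose MEAN relative abundance across the summarized samples
    exceeds ``display_threshold``, and ``low_abundant`` = the rest.  The
    four parts partition the simplex (sum to 1 per sample).
    """
    if not 0.0 < display_threshold < 1.0:
        raise ValueError(f"display_threshold must be in (0, 1), got {display_threshold}")
    by_order = aggregate_by_rank(rel, tax, "order")  # taxon x sample
    means = by_order.mean(axis=1)
    gut_labels = [o for o in GUT_ORDERS if o in by_order.index]
    non_gut = [t for t in by_order.index if t not in GUT_ORDERS]
    other_labels = [t for t in non_gut if means[t] > display_threshold]
    low_labels = [t for t in non_gut if means[t] <= display_threshold]
    out = pd.DataFrame(
        {
            "bacteroidales": by_order.loc[["Bacteroidales"]].sum(axis=0)
            if "Bacteroidales" in gut_labels
            else 0.0,
            "clostridiales": by_order.loc[["Clostridiales"]].sum(axis=0)
            if "Clostridiales" in gut_labels
            else 0.0,
            "other": by_order.loc[other_labels].sum(axis=0),
            "low_abundant": by_order.loc[low_labels].sum(axis=0),
        },
        index=by_order.columns,
    )
    return out


def select_taxa_by_mean(
    rel_aggregated: pd.DataFrame,
    threshold: float,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> list[str]:
    """Taxa whose mean abundance exceeds ``threshold`` in >= 1 sample group.

    ``rel_aggregated`` is taxon x sample.  With ``groups`` (name -> sample
    ids), the predicate is an OR across groups — e.g. mean > t in the DNA
    samples OR in the RNA samples.  Without groups, a single group of all
    samples.  Result ordered by descending overall mean, ties broken
    lexicographically.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if groups is None:
        groups = {"all": list(rel_aggregated.columns)}
    keep = set()
    for samples in groups.values():
        gm = rel_aggregated[list(samples)].mean(axis=1)
        keep |= set(gm.index[gm > threshold])
    overall = rel_aggregated.mean(axis=1)
    return sorted(keep, key=lambda t: (-overall[t], t))


def rank_by_prevalence(
    rel_aggregated: pd.DataFrame, detection: float = 0.0
) -> list[str]:
    """Order taxa by prevalence (descending), then global mean, then name.

    Prevalence is the fraction of samples where a taxon's abundance
    exceeds ``detection``.
    """
    if detection < 0:
        raise ValueError("detection must be >= 0")
    prevalence = (rel_aggregated > detection).mean(axis=1)
    overall = rel_aggregated.mean(axis=1)
    return sorted(
        rel_aggregated.index, key=lambda t: (-prevalence[t], -overall[t], t)
    )
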