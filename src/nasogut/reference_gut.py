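"""Prevalence-based identification of gut-associated taxa from a reference cohort.

An alternative to the fixed two-order definition: aggregate a reference
gut dataset (e.g. rectal samples from a few hundred animals) at a chosen
rank and call a taxon gut-associated when it is detected above a
``detection_threshold`` in at least a ``prevalence_threshold`` fraction of
the reference samples — a core-microbiome style criterion.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import pandas as pd

from .composition import RelAbundTable, aggregate_by_rank, gut_fraction
from .iotab import TaxonomyMap, rank_index

__all__ = ["GutTaxonSet", "identify_gut_taxa", "gut_fraction_by_set"]


@dataclasses.dataclass(frozen=True)
class GutTaxonSet:
    """The taxa considered gut-associated, with the thresholds that made them so."""

    rank: str
    taxa: frozenset[str]
    prevalence_threshold: float
    detection_threshold: float
    n_reference_samples: int

    def write_tsv(self, path: str | Path) -> None:
        lines = [
            f"# rank={self.rank} prevalence_threshold={self.prevalence_threshold} "
            f"detection_threshold={self.detection_threshold} "
            f"n_reference_samples={self.n_reference_samples}",
            "rank\ttaxon",
        ]
        lines += [f"{self.rank}\t{t}" for t in sorted(self.taxa)]
        Path(path).write_text("\n".join(lines) + "\n")


def identify_gut_taxa(
    reference_rel: RelAbundTable,
    tax: TaxonomyMap,
    rank: str = "genus",
    prevalence_threshold: float = 0.5,
    detection_threshold: float = 0.0,
) -> GutTaxonSet:
    """Taxa detected above ``detection_threshold`` in >= ``prevalence_threshold``
    of reference samples, at ``rank``.

    Lowering either threshold can only grow the result.  An empty result
    is a warning, not an error — thresholds may simply be strict.
    """
    rank_index(rank)
    for name, t in (
        ("prevalence_threshold", prevalence_threshold),
        ("detection_threshold", detection_threshold),
    ):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    agg = aggregate_by_rank(reference_rel, tax, rank)  # taxon x sample
    prevalence = (agg > detection_threshold).mean(axis=1)
    taxa = frozenset(prevalence.index[prevalence >= prevalence_threshold])
    if not taxa:
        warnings.warn(
            "no taxon passed the prevalence criterion; thresholds may be too strict",
            stacklevel=2,
        )
    return GutTaxonSet(
        rank=rank,
        taxa=taxa,
        prevalence_threshold=prevalence_threshold,
        detection_threshold=detection_threshold,
        n_reference_samples=reference_rel.n_samples,
    )


def gut_fraction_by_set(
    rel: RelAbundTable, tax: TaxonomyMap, gut_set: GutTaxonSet
) -> pd.DataFrame:
    """Per-sample summed abundance over the gut taxon set.

    Returns a frame with the set-based fraction, the order-based
    (Bacteroidales + Clostridiales) fraction, and their difference, so
    the two gut definitions can be compared sample by sample.
    """
    agg = aggregate_by_rank(rel, tax, gut_set.rank)
    members = [t for t in agg.index if t in gut_set.taxa]
    set_fraction = agg.loc[members].sum(axis=0) if members else pd.Series(
        0.0, index=agg.columns
    )
    order_based = gut_fraction(rel, tax)
    combined = order_based["bacteroidales"] + order_based["clostridiales"]
    return pd.DataFrame(
        {
            "set_fraction": set_fraction,
            "order_fraction": combined,
            "difference": set_fraction - combined,
        }
    )
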