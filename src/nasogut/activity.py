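"""RNA/DNA 16S relative-abundance ratios as a proxy for microbial activity.

Sequencing the 16S rRNA transcript pool (cDNA) alongside the gene pool
(DNA) gives, per taxon, a ratio of relative abundances that indexes
protein-synthesis potential: a taxon at 10% of DNA reads but 20% of RNA
reads is transcribing rRNA at roughly twice the community-average rate.

Two deliberately distinct estimators are produced and labeled as such:

* ratio of means (``taxon_activity``): mean RNA abundance across matched
  animals divided by mean DNA abundance — stable, but dominated by
  high-abundance animals;
* mean of per-animal ratios (``per_animal_family_ratios`` feeding
  ``compare_ratio_distributions``): one pseudocounted ratio per animal,
  suitable for rank-based distribution comparisons.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .composition import GUT_ORDERS, RelAbundTable, aggregate_by_rank
from .iotab import SampleMetadata, TaxonomyMap, normalize_taxon, rank_index
from .overlap import NASAL_COLONIZER_FAMILIES

__all__ = [
    "ActivityRecord",
    "GroupActivityPoint",
    "match_dna_rna",
    "taxon_activity",
    "group_activity",
    "per_animal_family_ratios",
    "default_epsilon",
    "compare_ratio_distributions",
]


@dataclasses.dataclass(frozen=True)
class ActivityRecord:
    """Per-taxon mean abundances in each molecule and their ratio.

    ``ratio`` is ``mean_rna / mean_dna``; it is undefined (None) when
    ``mean_dna`` is zero — no pseudocount is applied at this level.
    """

    taxon: str
    rank: str
    mean_dna: float
    mean_rna: float
    ratio: float | None
    n_animals: int


@dataclasses.dataclass(frozen=True)
class GroupActivityPoint:
    """Summed group abundance for one animal, in DNA and in RNA."""

    animal_id: str
    group: str  # Bacteroidales | Clostridiales | nasal_colonizers
    dna_sum: float
    rna_sum: float

    def __post_init__(self) -> None:
        for v in (self.dna_sum, self.rna_sum):
            if not 0.0 <= v <= 1.0 + 1e-9:
                raise ValueError(f"group sum outside [0, 1]: {v}")


def match_dna_rna(
    meta: SampleMetadata,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Pair DNA and RNA samples of the same (animal, body site, nasal site).

    Returns ``(pairs, unpaired)``: pairs of (dna_id, rna_id), and the ids
    of non-control samples with no partner.  Duplicate candidates for one
    slot are a hard error (the metadata invariant should prevent them).
    """
    df = meta.frame[~meta.frame["is_control"]]
    key_cols = ["animal_id", "body_site", "nasal_site"]
    pairs: list[tuple[str, str]] = []
    unpaired: list[str] = []
    for _, sub in df.groupby(key_cols, sort=False):
        dna = list(sub[sub["molecule"] == "DNA"]["sample_id"])
        rna = list(sub[sub["molecule"] == "RNA"]["sample_id"])
        if len(dna) > 1 or len(rna) > 1:
            raise ValueError(
                f"duplicate samples for slot {tuple(sub.iloc[0][key_cols])}: "
                f"DNA={dna} RNA={rna}"
            )
        if dna and rna:
            pairs.append((dna[0], rna[0]))
        else:
            unpaired.extend(dna + rna)
    return pairs, unpaired


def _paired_tables(
    rel_dna: RelAbundTable, rel_rna: RelAbundTable
) -> None:
    if rel_dna.n_samples != rel_rna.n_samples:
        raise ValueError(
            "DNA and RNA tables must cover the same matched animals "
            f"({rel_dna.n_samples} vs {rel_rna.n_samples} samples)"
        )


def taxon_activity(
    rel_dna: RelAbundTable,
    rel_rna: RelAbundTable,
    tax: TaxonomyMap,
    rank: str = "genus",
) -> list[ActivityRecord]:
    """Ratio-of-means RNA/DNA activity per taxon at ``rank``.

    Both tables must hold the same matched animals, in pairing order
    (row i of each table is the same animal).  Taxa with zero mean DNA
    abundance are retained with an undefined ratio.
    """
    rank_index(rank)
    _paired_tables(rel_dna, rel_rna)
    agg_dna = aggregate_by_rank(rel_dna, tax, rank)
    agg_rna = aggregate_by_rank(rel_rna, tax, rank)
    taxa = list(dict.fromkeys(list(agg_dna.index) + list(agg_rna.index)))
    n = rel_dna.n_samples
    records = []
    for t in taxa:
        md = float(agg_dna.loc[t].mean()) if t in agg_dna.index else 0.0
        mr = float(agg_rna.loc[t].mean()) if t in agg_rna.index else 0.0
        ratio = mr / md if md > 0 else None
        records.append(
            ActivityRecord(
                taxon=t, rank=rank, mean_dna=md, mean_rna=mr, ratio=ratio, n_animals=n
            )
        )
    return records


def group_activity(
    rel_dna: RelAbundTable,
    rel_rna: RelAbundTable,
    tax: TaxonomyMap,
    meta: SampleMetadata,
    colonizer_families: Sequence[str] = NASAL_COLONIZER_FAMILIES,
) -> list[GroupActivityPoint]:
    """Per-animal summed abundance of each taxon group, in DNA and RNA.

    Groups are the two gut orders plus ``nasal_colonizers`` (the summed
    colonizer families).  Tables must be matched in pairing order; the
    animal of row i is read from the metadata of the DNA sample id.
    """
    if not colonizer_families:
        raise ValueError("colonizer family set must be non-empty")
    _paired_tables(rel_dna, rel_rna)
    tax.require(rel_dna.asv_ids)
    tax.require(rel_rna.asv_ids)
    colonizer_norm = {normalize_taxon(f) for f in colonizer_families}

    def group_masks(asv_ids):
        orders = np.array([tax[a].order for a in asv_ids])
        fams = np.array([normalize_taxon(tax[a].family) for a in asv_ids])
        masks = {o: orders == o for o in GUT_ORDERS}
        masks["nasal_colonizers"] = np.isin(fams, sorted(colonizer_norm))
        return masks

    masks_dna = group_masks(rel_dna.asv_ids)
    masks_rna = group_masks(rel_rna.asv_ids)
    points = []
    for i, dna_id in enumerate(rel_dna.sample_ids):
        animal = str(meta.row(dna_id)["animal_id"])
        for grp in (*GUT_ORDERS, "nasal_colonizers"):
            points.append(
                GroupActivityPoint(
                    animal_id=animal,
                    group=grp,
                    dna_sum=float(rel_dna.values[i, masks_dna[grp]].sum()),
                    rna_sum=float(rel_rna.values[i, masks_rna[grp]].sum()),
                )
            )
    return points


def default_epsilon(rel_dna: RelAbundTable, rel_rna: RelAbundTable) -> float:
    """Half the smallest nonzero relative abundance in either table.

    A deterministic, scale-aware pseudocount for per-animal ratios.
    """
    nz = np.concatenate(
        [rel_dna.values[rel_dna.values > 0], rel_rna.values[rel_rna.values > 0]]
    )
    if nz.size == 0:
        raise ValueError("tables contain no nonzero abundance")
    return float(nz.min()) / 2.0


def per_animal_family_ratios(
    rel_dna: RelAbundTable,
    rel_rna: RelAbundTable,
    tax: TaxonomyMap,
    epsilon: float | None = None,
) -> dict[str, list[float]]:
    """Per-animal pseudocounted RNA/DNA ratio per family.

    ratio = (rna + eps) / (dna + eps) per matched animal; ``epsilon``
    defaults to :func:`default_epsilon`.
    """
    _paired_tables(rel_dna, rel_rna)
    if epsilon is None:
        epsilon = default_epsilon(rel_dna, rel_rna)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    agg_dna = aggregate_by_rank(rel_dna, tax, "family")
    agg_rna = aggregate_by_rank(rel_rna, tax, "family")
    families = sorted(set(agg_dna.index) | set(agg_rna.index))
    out: dict[str, list[float]] = {}
    n = rel_dna.n_samples
    for f in families:
        dna = agg_dna.loc[f].to_numpy() if f in agg_dna.index else np.zeros(n)
        rna = agg_rna.loc[f].to_numpy() if f in agg_rna.index else np.zeros(n)
        out[f] = list((rna + epsilon) / (dna + epsilon))
    return out


def compare_ratio_distributions(
    per_animal_ratios: Mapping[str, Sequence[float]],
    reference_families: Sequence[str] = NASAL_COLONIZER_FAMILIES,
    min_animals: int = 3,
    alpha: float = 0.05,
    test: str = "mannwhitneyu",
) -> pd.DataFrame:
    """Compare each family's ratio distribution against pooled reference ratios.

    Each non-reference family with >= ``min_animals`` usable ratios is
    compared to the pooled ratios of the reference (nasal-colonizer)
    families with a two-sided rank test (Mann-Whitney U by default;
    ``test='brunnermunzel'`` is the pluggable alternative).  P-values are
    Benjamini-Hochberg adjusted across families at ``alpha``.
    """
    ref_norm = {normalize_taxon(f) for f in reference_families}
    pooled: list[float] = []
    for fam, ratios in per_animal_ratios.items():
        if normalize_taxon(fam) in ref_norm:
            pooled.extend(ratios)
    if len(pooled) < min_animals:
        raise ValueError("too few reference-family ratios to compare against")
    rows = []
    for fam, ratios in per_animal_ratios.items():
        if normalize_taxon(fam) in ref_norm:
            continue
        ratios = [r for r in ratios if np.isfinite(r)]
        if len(ratios) < min_animals:
            import warnings

            warnings.warn(
                f"family {fam!r} has < {min_animals} usable animals; excluded",
                stacklevel=2,
            )
            continue
        if test == "mannwhitneyu":
            stat, p = stats.mannwhitneyu(ratios, pooled, alternative="two-sided")
        elif test == "brunnermunzel":
            res = stats.brunnermunzel(ratios, pooled)
            stat, p = res.statistic, res.pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"family": fam, "statistic": float(stat), "p": float(p)})
    result = pd.DataFrame(rows, columns=["family", "statistic", "p"])
    if len(result):
        reject, p_adj, _, _ = multipletests(result["p"], alpha=alpha, method="fdr_bh")
        result["p_adj"] = p_adj
        result["significant"] = reject
    else:
        result["p_adj"] = []
        result["significant"] = []
    return result
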