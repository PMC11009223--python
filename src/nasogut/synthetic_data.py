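"""Synthetic paired nasal/rectal, DNA/RNA 16S amplicon datasets with known truth.

The generator emulates the statistical structure of a multi-farm paired
body-site amplicon survey so every pipeline stage can be exercised
without downloads:

* per farm, a pool of ASVs (random 250-nt sequences, so cross-file
  identity is exact-string semantics as in real data) split into a
  nasal/rectal shared subset and site-specific subsets;
* per site, base community proportions drawn log-normally over the
  site's pool (shared plus site-only) and normalized;
* per animal, proportions drawn from a Dirichlet around the base
  (concentration alpha0 controls animal-to-animal variation), then read
  counts from a multinomial at a log-normally varying depth;
* RNA libraries reweight each animal's proportions by a per-family
  activity factor (16S transcript yield relative to gene abundance)
  before multinomial sampling;
* negative-control samples containing only planted contaminant ASVs,
  drawn from a namespace disjoint from the community pools (an optional
  leak puts them at low abundance in real samples too).

The planted parameters are returned as a :class:`SyntheticTruth` ledger
so recovery tests can compare estimates against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iotab import (
    FeatureTable,
    Lineage,
    SampleMetadata,
    TaxonomyMap,
    normalize_taxon,
)
from .overlap import TaxonGroupFilter

__all__ = [
    "TaxonSpec",
    "SimConfig",
    "SyntheticTruth",
    "generate_dataset",
    "expected_overlap",
    "expected_activity_ratio",
    "DEFAULT_TAXONOMY",
]

SITES = ("nasal", "rectal")

# order -> (phylum, class) for lineage construction (Greengenes 13.8 names)
_HIGHER_RANKS = {
    "Bacteroidales": ("Bacteroidetes", "Bacteroidia"),
    "Clostridiales": ("Firmicutes", "Clostridia"),
    "Lactobacillales": ("Firmicutes", "Bacilli"),
    "Pseudomonadales": ("Proteobacteria", "Gammaproteobacteria"),
    "Pasteurellales": ("Proteobacteria", "Gammaproteobacteria"),
    "Flavobacteriales": ("Bacteroidetes", "Flavobacteriia"),
}


@dataclasses.dataclass(frozen=True)
class TaxonSpec:
    """One (order, family, genus) cell and its share of the ASV pool."""

    order: str
    family: str
    genus: str
    fraction: float


#: Default community: the two gut-associated orders plus the five
#: reported nasal-colonizer families, at pool shares loosely shaped like
#: a piglet nasal/rectal survey.
DEFAULT_TAXONOMY = (
    TaxonSpec("Bacteroidales", "Prevotellaceae", "Prevotella", 0.12),
    TaxonSpec("Bacteroidales", "Bacteroidaceae", "Bacteroides", 0.08),
    TaxonSpec("Clostridiales", "Ruminococcaceae", "Oscillospira", 0.12),
    TaxonSpec("Clostridiales", "Lachnospiraceae", "", 0.10),
    TaxonSpec("Clostridiales", "Clostridiaceae", "Clostridium", 0.08),
    TaxonSpec("Pseudomonadales", "Moraxellaceae", "Moraxella", 0.12),
    TaxonSpec("Pasteurellales", "Pasteurellaceae", "Glaesserella", 0.10),
    TaxonSpec("Lactobacillales", "Lactobacillaceae", "Lactobacillus", 0.10),
    TaxonSpec("Lactobacillales", "Streptococcaceae", "Streptococcus", 0.08),
    TaxonSpec("Flavobacteriales", "[Weeksellaceae]", "", 0.10),
)


@dataclasses.dataclass
class SimConfig:
    """All knobs of the generator; defaults are the package's reference
    study conditions (3 farms x 8 animals, paired sites and molecules,
    ~5e4 reads/sample)."""

    n_farms: int = 3
    animals_per_farm_per_site: int = 8
    n_shared: int = 40
    n_nasal_only: int = 40
    n_rectal_only: int = 40
    #: ASVs planted identically in every farm's shared pool (cross-farm set)
    n_cross_farm: int = 0
    taxonomy: Sequence[TaxonSpec] = DEFAULT_TAXONOMY
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    #: multiplier on shared ASVs' base abundance
    shared_abundance_boost: float = 1.0
    #: if True, the k largest base weights are assigned to the shared
    #: subset, so (with a boost >= 2) the shared pool is planted as the
    #: top-k of both sites with a guaranteed abundance gap to the next ASV
    plant_shared_on_top: bool = False
    #: optional order -> fraction targets; base abundances are rescaled so
    #: each listed order's total equals the target in every site
    target_order_fractions: Mapping[str, float] | None = None
    #: optional family -> fraction targets, same mechanism at family rank
    #: (mutually exclusive with order targets)
    target_family_fractions: Mapping[str, float] | None = None
    dirichlet_concentration: float = 50.0
    depth: float = 5e4
    depth_cv: float = 0.3
    #: family -> RNA activity factor (unlisted families default to 1)
    activity_factors: Mapping[str, float] = dataclasses.field(default_factory=dict)
    n_contam_dna: int = 21
    n_contam_rna: int = 41
    contam_lambda: float = 5.0
    #: expected total relative abundance of contaminants leaked into real samples
    contaminant_leak: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_farms < 1 or self.animals_per_farm_per_site < 1:
            raise ValueError("need at least one farm and one animal per site")
        for name in ("n_shared", "n_nasal_only", "n_rectal_only", "n_cross_farm",
                     "n_contam_dna", "n_contam_rna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cross_farm > self.n_shared:
            raise ValueError("n_cross_farm cannot exceed n_shared")
        if self.n_shared + self.n_nasal_only == 0:
            raise ValueError("nasal site pool is empty")
        if self.n_shared + self.n_rectal_only == 0:
            raise ValueError("rectal site pool is empty")
        total = sum(t.fraction for t in self.taxonomy)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxonomy fractions sum to {total}, not 1")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for fam, a in self.activity_factors.items():
            if a <= 0:
                raise ValueError(f"activity factor for {fam!r} must be > 0")
        if self.shared_abundance_boost <= 0:
            raise ValueError("shared_abundance_boost must be > 0")
        if not 0.0 <= self.contaminant_leak < 1.0:
            raise ValueError("contaminant_leak must be in [0, 1)")
        if (self.target_order_fractions is not None
                and self.target_family_fractions is not None):
            raise ValueError("set order or family targets, not both")
        for targets in (self.target_order_fractions, self.target_family_fractions):
            if targets is not None:
                tot = sum(targets.values())
                if not 0.0 < tot < 1.0:
                    raise ValueError("target group fractions must sum into (0, 1)")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted parameters of one generated dataset.

    ``pools[farm]`` partitions the farm's pool into shared / nasal_only /
    rectal_only id lists; ``base_abundance[farm][site]`` maps ASV id to
    its noiseless expected proportion (the Dirichlet mean), from which
    ``expected_order_fractions`` and :func:`expected_overlap` derive.
    """

    farms: list[str]
    pools: dict[str, dict[str, list[str]]]
    lineages: dict[str, str]
    base_abundance: dict[str, dict[str, dict[str, float]]]
    expected_order_fractions: dict[str, dict[str, dict[str, float]]]
    activity_factors: dict[str, float]
    contaminants: dict[str, list[str]]
    cross_farm: list[str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _lineage_for(spec: TaxonSpec) -> Lineage:
    phylum, cls = _HIGHER_RANKS.get(
        spec.order, (f"{spec.order}_phylum", f"{spec.order}_class")
    )
    return Lineage(
        ("Bacteria", phylum, cls, spec.order, spec.family, spec.genus, "")
    )


def _random_sequences(rng: np.random.Generator, n: int, length: int = 250) -> list[str]:
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, size=length)]) for _ in range(n)]


def _assign_taxa(
    rng: np.random.Generator, taxonomy: Sequence[TaxonSpec], n: int
) -> list[TaxonSpec]:
    """Largest-remainder apportionment of n ASVs to taxonomy cells, shuffled."""
    raw = np.array([t.fraction for t in taxonomy]) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    for k in range(remainder):
        counts[order[k % len(counts)]] += 1
    assignment = [t for t, c in zip(taxonomy, counts) for _ in range(c)]
    rng.shuffle(assignment)
    return assignment


def _depth_draw(rng: np.random.Generator, depth: float, cv: float) -> int:
    if cv <= 0:
        return max(1, int(round(depth)))
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(depth) - sigma**2 / 2
    return max(1, int(round(rng.lognormal(mu, sigma))))


def _apply_group_targets(
    base: pd.Series,
    group_of: Mapping[str, str],
    targets: Mapping[str, float],
) -> pd.Series:
    """Rescale a normalized base so each targeted group totals its target."""
    orders = pd.Series({a: group_of[a] for a in base.index})
    out = base.copy()
    targeted = set(targets)
    rest_mass = base[~orders.isin(targeted)].sum()
    rest_target = 1.0 - sum(targets.values())
    for order, target in targets.items():
        mask = orders == order
        current = base[mask].sum()
        if current <= 0:
            raise ValueError(
                f"cannot target group {order!r}: no pool ASVs belong to it"
            )
        out[mask] = base[mask] * (target / current)
    mask_rest = ~orders.isin(targeted)
    if rest_mass > 0:
        out[mask_rest] = base[mask_rest] * (rest_target / rest_mass)
    return out / out.sum()


def generate_dataset(
    cfg: SimConfig,
) -> tuple[FeatureTable, FeatureTable, TaxonomyMap, SampleMetadata, SyntheticTruth]:
    """Draw one complete dataset: (DNA table, RNA table, taxonomy, metadata, truth).

    The same seed gives bit-identical outputs.  Randomness is organized
    into per-component substreams (farm pools, each animal, controls) so
    e.g. adding animals does not perturb the pool draws.
    """
    cfg.validate()
    root = cfg.seed
    farms = [f"farm{i + 1}" for i in range(cfg.n_farms)]

    # cross-farm ASVs drawn once, from their own stream
    cross_rng = np.random.default_rng(np.random.SeedSequence([root, 7]))
    cross_seqs = _random_sequences(cross_rng, cfg.n_cross_farm)

    lineages: dict[str, Lineage] = {}
    pools: dict[str, dict[str, list[str]]] = {}
    base_abund: dict[str, dict[str, pd.Series]] = {}
    asv_order: dict[str, str] = {}
    asv_family: dict[str, str] = {}

    pool_total = cfg.n_shared + cfg.n_nasal_only + cfg.n_rectal_only
    for fi, farm in enumerate(farms):
        pool_rng = np.random.default_rng(np.random.SeedSequence([root, 1, fi]))
        n_new = pool_total - cfg.n_cross_farm
        seqs = list(cross_seqs) + _random_sequences(pool_rng, n_new)
        taxa = _assign_taxa(pool_rng, cfg.taxonomy, pool_total)
        for asv, spec in zip(seqs, taxa):
            # a cross-farm ASV keeps the lineage of its first assignment
            if asv not in lineages:
                lineages[asv] = _lineage_for(spec)
                asv_order[asv] = spec.order
                asv_family[asv] = spec.family
        shared = seqs[: cfg.n_shared]
        nasal_only = seqs[cfg.n_shared : cfg.n_shared + cfg.n_nasal_only]
        rectal_only = seqs[cfg.n_shared + cfg.n_nasal_only :]
        pools[farm] = {
            "shared": shared,
            "nasal_only": nasal_only,
            "rectal_only": rectal_only,
        }
        # one log-normal draw per pool ASV: a shared ASV keeps the same
        # (boosted) base weight in both sites, so its cross-site ranks
        # are consistent and planted top-k sharing is recoverable
        draws = pool_rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, pool_total)
        if cfg.plant_shared_on_top and cfg.n_shared > 0:
            draws = np.sort(draws)[::-1]  # shared ids come first in seqs
        weights = pd.Series(draws, index=seqs)
        weights[shared] *= cfg.shared_abundance_boost
        base_abund[farm] = {}
        for site in SITES:
            site_pool = shared + (nasal_only if site == "nasal" else rectal_only)
            base = weights[site_pool].copy()
            base /= base.sum()
            if cfg.target_order_fractions is not None:
                base = _apply_group_targets(
                    base, asv_order, cfg.target_order_fractions
                )
            elif cfg.target_family_fractions is not None:
                base = _apply_group_targets(
                    base, asv_family, cfg.target_family_fractions
                )
            base_abund[farm][site] = base

    # contaminants: disjoint namespace, own stream
    contam_rng = np.random.default_rng(np.random.SeedSequence([root, 2]))
    contaminants: dict[str, list[str]] = {}
    for mol, n_c in (("DNA", cfg.n_contam_dna), ("RNA", cfg.n_contam_rna)):
        ids = _random_sequences(contam_rng, n_c)
        contaminants[mol] = ids
        for j, asv in enumerate(ids):
            spec = cfg.taxonomy[j % len(cfg.taxonomy)]
            lineages[asv] = _lineage_for(spec)
            asv_order[asv] = spec.order
            asv_family[asv] = spec.family

    all_asvs = list(dict.fromkeys(
        [a for farm in farms for key in ("shared", "nasal_only", "rectal_only")
         for a in pools[farm][key]]
        + contaminants["DNA"] + contaminants["RNA"]
    ))
    col_index = {a: j for j, a in enumerate(all_asvs)}

    factor_by_family = {
        normalize_taxon(f): a for f, a in cfg.activity_factors.items()
    }

    dna_rows: list[np.ndarray] = []
    rna_rows: list[np.ndarray] = []
    dna_ids: list[str] = []
    rna_ids: list[str] = []
    meta_rows: list[dict] = []

    for fi, farm in enumerate(farms):
        for ai in range(cfg.animals_per_farm_per_site):
            animal = f"{farm}_pig{ai + 1:02d}"
            animal_rng = np.random.default_rng(
                np.random.SeedSequence([root, 3, fi, ai])
            )
            for site in SITES:
                base = base_abund[farm][site]
                alpha = cfg.dirichlet_concentration * base.to_numpy()
                props = animal_rng.dirichlet(alpha)
                factors = np.array(
                    [factor_by_family.get(normalize_taxon(asv_family[a]), 1.0)
                     for a in base.index]
                )
                rna_props = props * factors
                rna_props /= rna_props.sum()
                for mol, p in (("DNA", props), ("RNA", rna_props)):
                    p_full = np.zeros(len(all_asvs))
                    idx = [col_index[a] for a in base.index]
                    p_full[idx] = p
                    if cfg.contaminant_leak > 0 and contaminants[mol]:
                        leak_each = cfg.contaminant_leak / len(contaminants[mol])
                        p_full *= 1.0 - cfg.contaminant_leak
                        for c in contaminants[mol]:
                            p_full[col_index[c]] += leak_each
                    depth = _depth_draw(animal_rng, cfg.depth, cfg.depth_cv)
                    counts = animal_rng.multinomial(depth, p_full)
                    sid = f"{animal}_{site}_{mol}"
                    (dna_rows if mol == "DNA" else rna_rows).append(counts)
                    (dna_ids if mol == "DNA" else rna_ids).append(sid)
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "animal_id": animal,
                            "farm": farm,
                            "body_site": site,
                            "nasal_site": "standard" if site == "nasal" else "not-applicable",
                            "molecule": mol,
                            "is_control": False,
                        }
                    )

    # one blank per molecule, containing only that molecule's contaminants
    for mol in ("DNA", "RNA"):
        if not contaminants[mol]:
            continue
        counts = np.zeros(len(all_asvs), dtype=np.int64)
        for c in contaminants[mol]:
            # conditioned >= 1 so every planted contaminant is detectable
            counts[col_index[c]] = max(1, contam_rng.poisson(cfg.contam_lambda))
        sid = f"control_{mol}"
        (dna_rows if mol == "DNA" else rna_rows).append(counts)
        (dna_ids if mol == "DNA" else rna_ids).append(sid)
        meta_rows.append(
            {
                "sample_id": sid,
                "animal_id": "control",
                "farm": farms[0],
                "body_site": "nasal",
                "nasal_site": "standard",
                "molecule": mol,
                "is_control": True,
            }
        )

    table_dna = FeatureTable(dna_ids, list(all_asvs), np.vstack(dna_rows))
    table_rna = FeatureTable(rna_ids, list(all_asvs), np.vstack(rna_rows))
    tax = TaxonomyMap({a: lineages[a] for a in all_asvs})
    meta = SampleMetadata(pd.DataFrame(meta_rows))

    expected_orders = {
        farm: {
            site: _order_fractions(base_abund[farm][site], asv_order)
            for site in SITES
        }
        for farm in farms
    }
    truth = SyntheticTruth(
        farms=farms,
        pools=pools,
        lineages={a: lin.to_string() for a, lin in lineages.items()},
        base_abundance={
            farm: {site: dict(base_abund[farm][site]) for site in SITES}
            for farm in farms
        },
        expected_order_fractions=expected_orders,
        activity_factors=dict(cfg.activity_factors),
        contaminants=contaminants,
        cross_farm=list(cross_seqs),
        seed=cfg.seed,
    )
    return table_dna, table_rna, tax, meta, truth


def _order_fractions(base: pd.Series, asv_order: Mapping[str, str]) -> dict[str, float]:
    totals: dict[str, float] = {}
    for asv, v in base.items():
        totals[asv_order[asv]] = totals.get(asv_order[asv], 0.0) + float(v)
    return totals


def expected_activity_ratio(
    truth: SyntheticTruth, family: str, site: str = "nasal"
) -> float:
    """Noiseless ratio-of-means RNA/DNA target for one family.

    Relative abundances are compositional, so reweighting family f by an
    activity factor a_f yields a measured ratio a_f / sum_j a_j p_j, not
    a_f itself: boosting one family necessarily dilutes the rest.  This
    computes that closed-composition expectation from the planted base
    abundances, averaged over farms, and is the proper recovery target
    for :func:`nasogut.activity.taxon_activity` estimates.
    """
    fam_norm = normalize_taxon(family)
    factors = {
        normalize_taxon(f): a for f, a in truth.activity_factors.items()
    }
    mean_dna, mean_rna = [], []
    for farm in truth.farms:
        base = truth.base_abundance[farm][site]
        p_f, denom = 0.0, 0.0
        for asv, p in base.items():
            f_a = normalize_taxon(Lineage.from_string(truth.lineages[asv]).family)
            a = factors.get(f_a, 1.0)
            denom += a * p
            if f_a == fam_norm:
                p_f += p
        mean_dna.append(p_f)
        mean_rna.append(factors.get(fam_norm, 1.0) * p_f / denom)
    md = float(np.mean(mean_dna))
    if md == 0:
        raise ValueError(f"family {family!r} absent from planted base abundances")
    return float(np.mean(mean_rna)) / md


def expected_overlap(
    truth: SyntheticTruth,
    group: TaxonGroupFilter,
    n: int,
    denominator: str = "union",
    farm: str | None = None,
) -> float | dict[str, float]:
    """Noiseless shared percentage by the exact top-N rule on base abundances.

    Serves as the recovery target for overlap estimates on sampled data.
    Returns one percentage for a given ``farm``, or a farm -> percentage
    dict when ``farm`` is None.
    """
    from .overlap import classify_overlap

    def one_farm(f: str) -> float:
        tops = {}
        for site in SITES:
            base = truth.base_abundance[f][site]
            matching = [
                a for a in base
                if group.matches(Lineage.from_string(truth.lineages[a]))
            ]
            if not matching:
                raise ValueError(f"no ASV matches group {group.name!r} in farm {f}")
            ranked = sorted(matching, key=lambda a: (-base[a], a))[:n]
            tops[site] = [(a, base[a]) for a in ranked]
        return classify_overlap(
            tops["nasal"], tops["rectal"], denominator=denominator, farm=f,
            group=group.name,
        ).shared_pct

    if farm is not None:
        return one_farm(farm)
    return {f: one_farm(f) for f in truth.farms}
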