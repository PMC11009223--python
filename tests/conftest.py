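import numpy as np
import pandas as pd
import pytest

from nasogut.iotab import FeatureTable, Lineage, SampleMetadata, TaxonomyMap


def make_table(counts, sample_ids=None, asv_ids=None) -> FeatureTable:
    counts = np.asarray(counts)
    n_s, n_a = counts.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n_s)]
    asv_ids = asv_ids or [f"asv{j+1}" for j in range(n_a)]
    return FeatureTable(sample_ids, asv_ids, counts)


def lineage(order="Bacteroidales", family="Prevotellaceae", genus="Prevotella",
            kingdom="Bacteria", phylum="Bacteroidetes", cls="Bacteroidia",
            species="") -> Lineage:
    return Lineage((kingdom, phylum, cls, order, family, genus, species))


def make_tax(asv_ids, lineages=None) -> TaxonomyMap:
    if lineages is None:
        lineages = [lineage() for _ in asv_ids]
    return TaxonomyMap(dict(zip(asv_ids, lineages)))


def make_meta(rows) -> SampleMetadata:
    """rows: (sample_id, animal, farm, body_site, nasal_site, molecule, is_control)"""
    return SampleMetadata(
        pd.DataFrame(
            rows,
            columns=[
                "sample_id", "animal_id", "farm", "body_site", "nasal_site",
                "molecule", "is_control",
            ],
        )
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset reused across read-only tests."""
    from nasogut.synthetic_data import SimConfig, generate_dataset

    cfg = SimConfig(
        seed=7, n_farms=2, animals_per_farm_per_site=4,
        n_shared=15, n_nasal_only=10, n_rectal_only=10,
        depth=5e3, n_contam_dna=3, n_contam_rna=4,
    )
    return generate_dataset(cfg)
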