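"""DNA/RNA pairing, activity ratios and ratio-distribution comparison."""

import numpy as np
import pandas as pd
import pytest

from conftest import lineage, make_meta, make_table, make_tax
from nasogut.activity import (
    compare_ratio_distributions,
    default_epsilon,
    group_activity,
    match_dna_rna,
    per_animal_family_ratios,
    taxon_activity,
)
from nasogut.composition import gut_fraction, to_relative
from nasogut.synthetic_data import (
    SimConfig,
    expected_activity_ratio,
    generate_dataset,
)


class TestMatching:
    def test_matched_pair(self):
        meta = make_meta([
            ("d1", "pig01", "F1", "nasal", "standard", "DNA", "false"),
            ("r1", "pig01", "F1", "nasal", "standard", "RNA", "false"),
        ])
        pairs, unpaired = match_dna_rna(meta)
        assert pairs == [("d1", "r1")] and unpaired == []

    def test_dna_only_animal_reported_unpaired(self):
        meta = make_meta([
            ("d1", "pig01", "F1", "nasal", "standard", "DNA", "false"),
        ])
        pairs, unpaired = match_dna_rna(meta)
        assert pairs == [] and unpaired == ["d1"]

    def test_different_nasal_sites_do_not_pair(self):
        meta = make_meta([
            ("d1", "pig01", "F1", "nasal", "deep", "DNA", "false"),
            ("r1", "pig01", "F1", "nasal", "middle", "RNA", "false"),
        ])
        pairs, unpaired = match_dna_rna(meta)
        assert pairs == [] and set(unpaired) == {"d1", "r1"}

    def test_full_cohort_pairs_completely(self, small_dataset):
        _, _, _, meta, _ = small_dataset
        pairs, unpaired = match_dna_rna(meta)
        # 2 farms x 4 animals x 2 sites
        assert len(pairs) == 16 and unpaired == []


def _paired_rel(dna_counts, rna_counts, asv_ids, lineages):
    tax = make_tax(asv_ids, lineages)
    rel_d = to_relative(make_table(
        dna_counts, sample_ids=[f"d{i}" for i in range(len(dna_counts))],
        asv_ids=asv_ids))
    rel_r = to_relative(make_table(
        rna_counts, sample_ids=[f"r{i}" for i in range(len(rna_counts))],
        asv_ids=asv_ids))
    return rel_d, rel_r, tax


class TestTaxonActivity:
    def test_ratio_of_means(self):
        rel_d, rel_r, tax = _paired_rel(
            [[10, 90]], [[20, 80]], ["a", "b"],
            [lineage(genus="G1"), lineage(genus="G2")],
        )
        recs = {r.taxon: r for r in taxon_activity(rel_d, rel_r, tax, "genus")}
        assert recs["G1"].ratio == pytest.approx(2.0)
        assert recs["G1"].mean_dna == pytest.approx(0.10)

    def test_zero_dna_mean_keeps_record_with_undefined_ratio(self):
        rel_d, rel_r, tax = _paired_rel(
            [[0, 10]], [[5, 5]], ["a", "b"],
            [lineage(genus="G1"), lineage(genus="G2")],
        )
        recs = {r.taxon: r for r in taxon_activity(rel_d, rel_r, tax, "genus")}
        assert recs["G1"].ratio is None and recs["G1"].mean_rna == 0.5

    def test_mismatched_animal_counts_rejected(self):
        rel_d, rel_r, tax = _paired_rel(
            [[1, 1], [1, 1]], [[1, 1]], ["a", "b"],
            [lineage(genus="G1"), lineage(genus="G2")],
        )
        with pytest.raises(ValueError, match="matched"):
            taxon_activity(rel_d, rel_r, tax)

    def test_scale_free_in_sequencing_depth(self):
        # multiplying every RNA library's depth by a constant leaves
        # relative abundances, hence ratios, unchanged
        dna = [[10, 90], [30, 70]]
        rna = np.array([[20, 80], [10, 90]])
        lin = [lineage(genus="G1"), lineage(genus="G2")]
        rel_d, rel_r, tax = _paired_rel(dna, rna, ["a", "b"], lin)
        rel_d2, rel_r2, _ = _paired_rel(dna, rna * 13, ["a", "b"], lin)
        r1 = {r.taxon: r.ratio for r in taxon_activity(rel_d, rel_r, tax, "genus")}
        r2 = {r.taxon: r.ratio for r in taxon_activity(rel_d2, rel_r2, tax, "genus")}
        assert r1 == pytest.approx(r2)

    def test_planted_activity_factor_recovered(self):
        cfg = SimConfig(seed=3, depth=1e5,
                        activity_factors={"Clostridiaceae": 3.0})
        tdna, trna, tax, meta, truth = generate_dataset(cfg)
        pairs, _ = match_dna_rna(meta)
        pairs = [(d, r) for d, r in pairs if meta.row(d)["body_site"] == "nasal"]
        rel_d = to_relative(tdna.select_samples([d for d, _ in pairs]))
        rel_r = to_relative(trna.select_samples([r for _, r in pairs]))
        recs = {r.taxon: r for r in taxon_activity(rel_d, rel_r, tax, "family")}
        expected = expected_activity_ratio(truth, "Clostridiaceae")
        assert recs["Clostridiaceae"].ratio == pytest.approx(expected, rel=0.1)


class TestGroupActivity:
    def _meta_for(self, sample_ids):
        rows = []
        for i, sid in enumerate(sample_ids):
            rows.append((sid, f"pig{i}", "F1", "nasal", "standard",
                         "DNA" if sid.startswith("d") else "RNA", "false"))
        return make_meta(rows)

    def test_pure_colonizer_animal(self):
        rel_d, rel_r, tax = _paired_rel(
            [[10]], [[10]], ["a"], [lineage("Pseudomonadales", "Moraxellaceae",
                                           "Moraxella")],
        )
        meta = make_meta([
            ("d0", "pig0", "F1", "nasal", "standard", "DNA", "false"),
            ("r0", "pig0", "F1", "nasal", "standard", "RNA", "false"),
        ])
        points = group_activity(rel_d, rel_r, tax, meta)
        by_group = {p.group: p for p in points}
        assert by_group["nasal_colonizers"].dna_sum == 1.0
        assert by_group["nasal_colonizers"].rna_sum == 1.0
        assert by_group["Bacteroidales"].dna_sum == 0.0

    def test_empty_colonizer_set_rejected(self):
        rel_d, rel_r, tax = _paired_rel([[1]], [[1]], ["a"], [lineage()])
        meta = make_meta([
            ("d0", "pig0", "F1", "nasal", "standard", "DNA", "false"),
        ])
        with pytest.raises(ValueError):
            group_activity(rel_d, rel_r, tax, meta, colonizer_families=())

    def test_sums_bounded_and_dna_matches_gut_fraction(self, small_dataset):
        tdna, trna, tax, meta, _ = small_dataset
        pairs, _ = match_dna_rna(meta)
        rel_d = to_relative(tdna.select_samples([d for d, _ in pairs]))
        rel_r = to_relative(trna.select_samples([r for _, r in pairs]))
        points = group_activity(rel_d, rel_r, tax, meta)
        assert all(0.0 <= p.dna_sum <= 1.0 and 0.0 <= p.rna_sum <= 1.0
                   for p in points)
        frac = gut_fraction(rel_d, tax)
        for i, (d, _) in enumerate(pairs):
            animal = meta.row(d)["animal_id"]
            got = {p.group: p.dna_sum for p in points
                   if p.animal_id == animal}
            # one nasal + one rectal point per animal share the id; check sums exist
        bact = [p.dna_sum for p in points if p.group == "Bacteroidales"]
        assert np.allclose(sorted(bact), sorted(frac["bacteroidales"]), atol=1e-9)


class TestRatioComparison:
    def test_identical_distributions_not_significant(self):
        ratios = {"GutFam": [1.0, 1.1, 0.9, 1.05] * 6,
                  "Moraxellaceae": [1.0, 1.1, 0.9, 1.05] * 6}
        res = compare_ratio_distributions(ratios)
        assert res.loc[0, "p_adj"] > 0.9
        assert not res.loc[0, "significant"]

    def test_tenfold_shift_detected(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(0, 0.3, 24)
        ratios = {"GutFam": list(base * 10), "Moraxellaceae": list(base)}
        res = compare_ratio_distributions(ratios)
        assert res.loc[0, "significant"]

    def test_adjusted_p_never_below_raw_p(self):
        rng = np.random.default_rng(2)
        ratios = {f"Fam{i}": list(rng.lognormal(0, 0.5, 10)) for i in range(6)}
        ratios["Moraxellaceae"] = list(rng.lognormal(0, 0.5, 10))
        res = compare_ratio_distributions(ratios)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_small_families_excluded_with_warning(self):
        ratios = {"Tiny": [1.0, 2.0], "Moraxellaceae": [1.0] * 10}
        with pytest.warns(UserWarning, match="Tiny"):
            res = compare_ratio_distributions(ratios)
        assert "Tiny" not in set(res["family"])

    def test_default_epsilon_is_half_min_nonzero(self):
        rel_d, rel_r, _ = _paired_rel(
            [[1, 99]], [[50, 50]], ["a", "b"],
            [lineage(genus="G1"), lineage(genus="G2")],
        )
        assert default_epsilon(rel_d, rel_r) == pytest.approx(0.005)

    def test_per_animal_ratios_shape(self, small_dataset):
        tdna, trna, tax, meta, _ = small_dataset
        pairs, _ = match_dna_rna(meta)
        rel_d = to_relative(tdna.select_samples([d for d, _ in pairs]))
        rel_r = to_relative(trna.select_samples([r for _, r in pairs]))
        ratios = per_animal_family_ratios(rel_d, rel_r, tax)
        assert all(len(v) == len(pairs) for v in ratios.values())
        assert all(np.isfinite(v).all() and (np.asarray(v) > 0).all()
                   for v in ratios.values())
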