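"""KO assignment, gene/category abundance, species contributions."""

import numpy as np
import pandas as pd
import pytest

from magprof import functions as fn
from magprof import synthetic
from magprof.abundance import AbundanceMatrix


def hit(ko="K00001", e=1e-20, cov=0.7, gene="g1"):
    return fn.GeneHit(gene, ko, e, cov)


class TestAssignKO:
    def test_passing_hit_assigned(self):
        assert fn.assign_ko([hit(e=1e-12, cov=0.6)]) == "K00001"

    def test_evalue_failure_unassigned(self):
        assert fn.assign_ko([hit(e=1e-9, cov=0.9)]) is None

    def test_coverage_failure_unassigned(self):
        assert fn.assign_ko([hit(e=1e-20, cov=0.5)]) is None

    def test_min_evalue_wins(self):
        hits = [hit("K1", 1e-20, 0.6), hit("K2", 1e-30, 0.55)]
        assert fn.assign_ko(hits) == "K2"

    def test_evalue_tie_broken_by_coverage_then_ko(self):
        assert fn.assign_ko([hit("K1", 1e-20, 0.6), hit("K2", 1e-20, 0.8)]) == "K2"
        assert fn.assign_ko([hit("K2", 1e-20, 0.6), hit("K1", 1e-20, 0.6)]) == "K1"

    def test_vectorised_matches_per_gene(self):
        """assign_kos agrees with per-gene assign_ko on a random hit table."""
        rng = np.random.default_rng(0)
        rows = []
        for g in range(200):
            for _ in range(rng.integers(1, 4)):
                rows.append((f"g{g}", f"K{rng.integers(5):05d}",
                             10.0 ** rng.uniform(-30, -5),
                             float(rng.uniform(0.2, 1.0))))
        hits = pd.DataFrame(rows, columns=["gene_id", "ko", "e_value", "coverage"])
        vec = fn.assign_kos(hits)
        for gene, sub in hits.groupby("gene_id"):
            expected = fn.assign_ko(
                [fn.GeneHit(gene, r.ko, r.e_value, r.coverage)
                 for r in sub.itertuples()]
            )
            assert vec.get(gene) == expected or (expected is None and gene not in vec)


class TestGeneAbundance:
    @pytest.fixture
    def species_matrix(self):
        return AbundanceMatrix(
            pd.DataFrame({"spA": [0.4, 0.0], "spB": [0.6, 1.0]}, index=["s1", "s2"])
        )

    def test_single_copy_equals_species_abundance(self, species_matrix):
        cat = pd.DataFrame({"gene_id": ["g1"], "species_id": ["spA"], "copy": [1]})
        out = fn.gene_abundance(species_matrix, cat)
        assert out.loc["s1", "g1"] == pytest.approx(0.4)

    def test_two_copies_double(self, species_matrix):
        cat = pd.DataFrame({"gene_id": ["g1"], "species_id": ["spA"], "copy": [2]})
        assert fn.gene_abundance(species_matrix, cat).loc["s1", "g1"] == pytest.approx(0.8)

    def test_absent_species_gives_zero(self, species_matrix):
        cat = pd.DataFrame({"gene_id": ["g1"], "species_id": ["spA"], "copy": [1]})
        assert fn.gene_abundance(species_matrix, cat).loc["s2", "g1"] == 0.0

    def test_orphan_gene_listed_in_error(self, species_matrix):
        cat = pd.DataFrame({"gene_id": ["gX"], "species_id": ["spZ"], "copy": [1]})
        with pytest.raises(KeyError, match="gX"):
            fn.gene_abundance(species_matrix, cat)


class TestCategoryAbundance:
    @pytest.fixture
    def gene_ab(self):
        return pd.DataFrame({"g1": [0.1, 0.2], "g2": [0.3, 0.1], "g3": [0.05, 0.0]},
                            index=["s1", "s2"])

    @pytest.fixture
    def assignments(self):
        return pd.Series({"g1": "K1", "g2": "K2", "g3": "K1"}, name="ko")

    def test_single_gene_category_equals_gene_row(self, gene_ab, assignments):
        cats = pd.DataFrame({"category_id": ["M1"], "ko": ["K2"]})
        out = fn.category_abundance(gene_ab, assignments, cats)
        assert list(out.data["M1"]) == [pytest.approx(0.3), pytest.approx(0.1)]

    def test_module_sums_member_kos(self, gene_ab, assignments):
        cats = pd.DataFrame({"category_id": ["M1", "M1"], "ko": ["K1", "K2"]})
        out = fn.category_abundance(gene_ab, assignments, cats)
        assert out.data.loc["s1", "M1"] == pytest.approx(0.1 + 0.3 + 0.05)

    def test_overlapping_categories_double_count(self, gene_ab, assignments):
        cats = pd.DataFrame({"category_id": ["M1", "M1", "M2"],
                             "ko": ["K1", "K2", "K2"]})
        out = fn.category_abundance(gene_ab, assignments, cats)
        # K2's gene g2 contributes to both M1 and M2
        assert out.data.loc["s1", "M1"] + out.data.loc["s1", "M2"] == pytest.approx(
            0.45 + 0.3
        )

    def test_empty_category_warns_and_is_zero(self, gene_ab, assignments):
        cats = pd.DataFrame({"category_id": ["M9"], "ko": ["K9"]})
        with pytest.warns(UserWarning, match="M9"):
            out = fn.category_abundance(gene_ab, assignments, cats)
        assert (out.data["M9"] == 0).all()

    def test_linearity(self, gene_ab, assignments):
        cats = pd.DataFrame({"category_id": ["M1", "M1"], "ko": ["K1", "K2"]})
        once = fn.category_abundance(gene_ab, assignments, cats)
        twice = fn.category_abundance(2 * gene_ab, assignments, cats)
        pd.testing.assert_frame_equal(twice.data, 2 * once.data)


class TestSpeciesContribution:
    @pytest.fixture
    def setup(self):
        gene_ab = pd.DataFrame({"gA": [0.3], "gB": [0.1]}, index=["s1"])
        assignments = pd.Series({"gA": "K1", "gB": "K1"}, name="ko")
        species_of = {"gA": "spA", "gB": "spB"}
        return gene_ab, assignments, species_of

    def test_single_species_contribution_is_one(self):
        gene_ab = pd.DataFrame({"gA": [0.2]}, index=["s1"])
        res = fn.species_contribution({"K1"}, gene_ab,
                                      pd.Series({"gA": "K1"}), {"gA": "spA"})
        assert res.per_sample.loc["spA", "s1"] == pytest.approx(1.0)

    def test_proportional_split(self, setup):
        res = fn.species_contribution({"K1"}, *setup)
        assert res.per_sample.loc["spA", "s1"] == pytest.approx(0.75)
        assert res.per_sample.loc["spB", "s1"] == pytest.approx(0.25)

    def test_subset_rows_sum_below_one(self, setup):
        res = fn.species_contribution({"K1"}, *setup, species_subset=["spA"])
        assert res.per_sample.sum(axis=0).iloc[0] == pytest.approx(0.75)

    def test_unrestricted_contributions_sum_to_one(self, setup):
        res = fn.species_contribution({"K1"}, *setup)
        assert res.per_sample.sum(axis=0).iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_category_everywhere_raises(self):
        gene_ab = pd.DataFrame({"gA": [0.0]}, index=["s1"])
        with pytest.raises(ValueError):
            fn.species_contribution({"K1"}, gene_ab, pd.Series({"gA": "K1"}),
                                    {"gA": "spA"})

    def test_zero_sample_flagged(self):
        gene_ab = pd.DataFrame({"gA": [0.2, 0.0]}, index=["s1", "s2"])
        res = fn.species_contribution({"K1"}, gene_ab, pd.Series({"gA": "K1"}),
                                      {"gA": "spA"})
        assert res.zero_samples == ["s2"]
        assert res.per_sample.loc["spA", "s2"] == 0.0


class TestPlantedKOSignal:
    def test_pe_only_ko_shows_positive_log2_ratio(self, rel_matrix, small_cohort):
        """A KO carried only by the PE-planted species inherits its enrichment."""
        catalog = synthetic.generate_gene_catalog(
            list(rel_matrix.feature_ids), n_kos=30, genes_per_genome=10,
            rng_seed=5, planted_kos={"K77777": ["s0"]},  # s0 planted +2 in PE
            frac_subthreshold=0.0,
        )
        assignments = fn.assign_kos(catalog.hits)
        gene_ab = fn.gene_abundance(rel_matrix, catalog.genes)
        ko_ab = fn.category_abundance(
            gene_ab, assignments, fn.ko_categories(["K77777"]), level="ko"
        )
        pe = ko_ab.data.loc[small_cohort.labels == "PE", "K77777"].mean()
        hc = ko_ab.data.loc[small_cohort.labels == "HC", "K77777"].mean()
        assert pe > 0 and hc > 0
        assert 1.0 <= np.log2(pe / hc) <= 3.0
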