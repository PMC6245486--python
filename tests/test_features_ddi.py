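import numpy as np
import pytest

from phipred.corpus import Corpus
from phipred.features_ddi import (
    CONFIG_ALIASES,
    DatasetConfig,
    HistogramConfig,
    PairScoreVector,
    build_ddi_dataset,
    histogram_featurize,
    pair_score_vector,
    ppi_score,
    resolve_config,
    standard_config_grid,
)
from phipred.io_formats import BACTERIUM, PHAGE, DDITable, InteractionRecord

from conftest import make_proteome, random_proteome


def brute_force_ppi_score(phage_domains, bact_domains, table):
    """Independent oracle: explicit double loop over the domain-pair grid."""
    total = 0.0
    for dp in phage_domains:
        for db in bact_domains:
            total += table.lookup(dp, db)
    return total


def vec(scores):
    return PairScoreVector("P", "B", np.asarray(scores, dtype=float))


class TestPpiScore:
    def test_single_pair(self):
        table = DDITable()
        table.add("A", "B", 0.5)
        assert ppi_score(["A"], ["B"], table) == 0.5

    def test_multiplicity_counts(self):
        table = DDITable()
        table.add("A", "B", 0.5)
        assert ppi_score(["A", "A"], ["B"], table) == pytest.approx(1.0)
        assert ppi_score(["A", "A"], ["B"], table, unique_domains=True) == 0.5

    def test_empty_list_scores_zero(self):
        table = DDITable()
        table.add("A", "B", 0.5)
        assert ppi_score([], ["B"], table) == 0.0
        assert ppi_score(["A"], [], table) == 0.0

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(42)
        vocab = [f"D{i}" for i in range(8)]
        for _ in range(200):
            table = DDITable()
            for _ in range(rng.integers(0, 10)):
                a, b = rng.choice(vocab, size=2)
                table.add(a, b, float(rng.uniform(0, 2)))
            phage_doms = list(rng.choice(vocab, size=rng.integers(0, 5)))
            bact_doms = list(rng.choice(vocab, size=rng.integers(0, 5)))
            assert ppi_score(phage_doms, bact_doms, table) == pytest.approx(
                brute_force_ppi_score(phage_doms, bact_doms, table)
            )

    def test_monotone_in_table_entries(self):
        rng = np.random.default_rng(3)
        vocab = [f"D{i}" for i in range(5)]
        phage_doms = ["D0", "D1", "D2"]
        bact_doms = ["D3", "D4", "D0"]
        table = DDITable()
        prev = ppi_score(phage_doms, bact_doms, table)
        for _ in range(20):
            a, b = rng.choice(vocab, size=2)
            table.add(a, b, float(rng.uniform(0, 1)))
            now = ppi_score(phage_doms, bact_doms, table)
            assert now >= prev - 1e-12
            prev = now


class TestPairScoreVector:
    def test_length_is_grid_product(self, tiny_phage, tiny_bacterium, tiny_ddi_table):
        v = pair_score_vector(tiny_phage, tiny_bacterium, {}, tiny_ddi_table)
        assert len(v.scores) == len(tiny_phage) * len(tiny_bacterium)

    def test_full_scale_grid_cardinality(self):
        # 74-protein phage x 3417-protein bacterium -> 252,858 PPIs
        phage = make_proteome("P", PHAGE, ["MA"] * 74)
        bact = make_proteome("B", BACTERIUM, ["KV"] * 3417)
        table = DDITable()
        v = pair_score_vector(phage, bact, {}, table)
        assert len(v.scores) == 74 * 3417 == 252858

    def test_1x1_no_ddi(self):
        phage = make_proteome("P", PHAGE, ["MA"])
        bact = make_proteome("B", BACTERIUM, ["KV"])
        v = pair_score_vector(phage, bact, {}, DDITable())
        assert v.scores.tolist() == [0.0]

    def test_2x2_single_hit_at_expected_index(self):
        phage = make_proteome("P", PHAGE, ["MA", "KV"])
        bact = make_proteome("B", BACTERIUM, ["GG", "WW"])
        annotations = {"P_p1": ["DA"], "B_p0": ["DB"]}
        table = DDITable()
        table.add("DA", "DB", 0.75)
        v = pair_score_vector(phage, bact, annotations, table)
        # phage-protein-major: index = 1 * n_bact + 0
        assert v.scores.tolist() == [0.0, 0.0, 0.75, 0.0]

    def test_matches_per_cell_oracle_randomized(self, tiny_ddi_table):
        rng = np.random.default_rng(9)
        vocab = [f"PF0000{i}" for i in range(1, 6)]
        for trial in range(50):
            phage = random_proteome(rng, "P", PHAGE, int(rng.integers(1, 5)))
            bact = random_proteome(rng, "B", BACTERIUM, int(rng.integers(1, 5)))
            annotations = {
                p.protein_id: list(rng.choice(vocab, size=rng.integers(0, 4)))
                for p in phage.proteins + bact.proteins
            }
            v = pair_score_vector(phage, bact, annotations, tiny_ddi_table)
            idx = 0
            for pp in phage.proteins:
                for bp in bact.proteins:
                    expected = brute_force_ppi_score(
                        annotations.get(pp.protein_id, []),
                        annotations.get(bp.protein_id, []),
                        tiny_ddi_table,
                    )
                    assert v.scores[idx] == pytest.approx(expected)
                    idx += 1


class TestHistogramFeaturize:
    def test_fixed_number_normalized_example(self):
        # bins [0,1),[1,2] over [0, max=2]: counts {3,1}, / 4
        h = HistogramConfig("fixed_number", 2, normalized=True)
        out = histogram_featurize(vec([0, 0, 1, 2]), h)
        assert out.tolist() == [0.75, 0.25]

    def test_normalized_sums_to_one(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 5, size=100)
        for h in (
            HistogramConfig("fixed_number", 7, normalized=True),
            HistogramConfig("fixed_size", 0.5, normalized=True, upper_bound=3.0),
        ):
            assert histogram_featurize(vec(scores), h).sum() == pytest.approx(1.0, abs=1e-12)

    def test_unnormalized_sums_to_count(self):
        scores = np.arange(20, dtype=float)
        h = HistogramConfig("fixed_number", 4, normalized=False)
        assert histogram_featurize(vec(scores), h).sum() == 20

    def test_overflow_bin(self):
        h = HistogramConfig("fixed_size", 1.0, normalized=False, upper_bound=3.0)
        out = histogram_featurize(vec([5.0]), h)
        assert len(out) == 4  # ceil(3/1) + overflow
        assert out.tolist() == [0, 0, 0, 1]

    def test_fixed_size_requires_upper_bound(self):
        h = HistogramConfig("fixed_size", 1.0)
        with pytest.raises(ValueError, match="upper_bound"):
            histogram_featurize(vec([1.0]), h)

    def test_all_zero_scores_span_unit_interval(self):
        h = HistogramConfig("fixed_number", 4, normalized=False)
        out = histogram_featurize(vec([0.0, 0.0]), h)
        assert out.tolist() == [2, 0, 0, 0]

    def test_zero_exclusion(self):
        h = HistogramConfig("fixed_number", 2, normalized=True,
                            include_zero_scores=False)
        out = histogram_featurize(vec([0, 0, 1, 2]), h)
        assert out.tolist() == [0.5, 0.5]

    def test_zero_exclusion_empties_vector(self):
        h = HistogramConfig("fixed_number", 3, normalized=True,
                            include_zero_scores=False)
        out = histogram_featurize(vec([0.0, 0.0]), h)
        assert out.tolist() == [0.0, 0.0, 0.0]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 3, size=50)
        h = HistogramConfig("fixed_number", 6, normalized=True)
        a = histogram_featurize(vec(scores), h)
        b = histogram_featurize(vec(rng.permutation(scores)), h)
        assert np.array_equal(a, b)

    def test_last_bin_right_closed(self):
        h = HistogramConfig("fixed_number", 2, normalized=False)
        out = histogram_featurize(vec([1.0, 2.0]), h)
        assert out.tolist() == [1, 1]  # max lands in the last bin

    def test_integer_bin_count_enforced(self):
        with pytest.raises(ValueError):
            HistogramConfig("fixed_number", 2.5)


class TestStandardGrid:
    def test_nineteen_configs(self):
        grid = standard_config_grid()
        assert len(grid) == 19
        assert sum(1 for c in grid if c.featurizer == "ddi_histogram") == 18

    def test_names_unique(self):
        names = [c.name for c in standard_config_grid()]
        assert len(names) == len(set(names))

    def test_nbn50_is_50_normalized_bins(self):
        cfg = resolve_config("NBN50")
        assert cfg.histogram.mode == "fixed_number"
        assert cfg.histogram.value == 50
        assert cfg.histogram.normalized

    def test_aliases_resolve(self):
        for alias in CONFIG_ALIASES:
            assert resolve_config(alias).name == "SB1e-06"

    def test_config_serialization_round_trip(self):
        for cfg in standard_config_grid():
            assert DatasetConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            resolve_config("NBN51")


class TestBuildDdiDataset:
    def _toy(self):
        phage1 = make_proteome("P1", PHAGE, ["MA", "KV"])
        phage2 = make_proteome("P2", PHAGE, ["GG"])
        bact1 = make_proteome("B1", BACTERIUM, ["WW", "CC"])
        bact2 = make_proteome("B2", BACTERIUM, ["YY"])
        proteomes = {p.organism_id: p for p in (phage1, phage2, bact1, bact2)}
        annotations = {"P1_p0": ["DA"], "B1_p0": ["DB"], "P2_p0": ["DC"]}
        table = DDITable()
        table.add("DA", "DB", 0.6)
        table.add("DC", "DB", 1.4)
        train = [
            InteractionRecord("P1", "B1", "s1", "f1", "positive"),
            InteractionRecord("P2", "B2", "s2", "f1", "negative"),
            InteractionRecord("P2", "B1", "s1", "f1", "negative"),
        ]
        test = [InteractionRecord("P1", "B2", "s2", "f1", "positive")]
        corpus = Corpus(train=train, test=test)
        return corpus, proteomes, annotations, table

    def test_row_counts_and_length(self):
        corpus, proteomes, annotations, table = self._toy()
        cfg = resolve_config("NBN50")
        train_rows, test_rows, _ = build_ddi_dataset(
            corpus, proteomes, annotations, table, cfg
        )
        assert len(train_rows) == 3 and len(test_rows) == 1
        assert all(len(r.values) == 50 for r in train_rows + test_rows)

    def test_determinism(self):
        corpus, proteomes, annotations, table = self._toy()
        cfg = resolve_config("NB10")
        a = build_ddi_dataset(corpus, proteomes, annotations, table, cfg)
        b = build_ddi_dataset(corpus, proteomes, annotations, table, cfg)
        for ra, rb in zip(a[0] + a[1], b[0] + b[1]):
            assert np.array_equal(ra.values, rb.values)

    def test_replicates_repeat_rows(self):
        corpus, proteomes, annotations, table = self._toy()
        corpus.train = corpus.train + [corpus.train[0]]
        cfg = resolve_config("NBN5")
        train_rows, _, _ = build_ddi_dataset(corpus, proteomes, annotations, table, cfg)
        assert np.array_equal(train_rows[0].values, train_rows[-1].values)

    def test_fixed_size_upper_bound_from_train(self):
        corpus, proteomes, annotations, table = self._toy()
        cfg = DatasetConfig(
            "SBtest", "ddi_histogram",
            HistogramConfig("fixed_size", 0.5, normalized=False),
        )
        _, _, manifest = build_ddi_dataset(corpus, proteomes, annotations, table, cfg)
        # max train PPI score is the P2xB1 hit at 1.4
        assert manifest["config"]["histogram"]["upper_bound"] == pytest.approx(1.4)

    def test_missing_proteome_names_organism(self):
        corpus, proteomes, annotations, table = self._toy()
        del proteomes["B2"]
        with pytest.raises(KeyError, match="B2"):
            build_ddi_dataset(corpus, proteomes, annotations, table,
                              resolve_config("NBN5"))
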