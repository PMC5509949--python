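import math

import edlib
import numpy as np
import pytest

import emrminer as em
from emrminer.synthetic_corpus import CategorySpec, DEFAULT_CATEGORIES

from oracles import osa_distance


def small_config(**overrides):
    defaults = dict(n_patients=20, seed=11)
    defaults.update(overrides)
    return em.SimConfig(**defaults)


class TestGenerate:
    def test_identical_seeds_identical_output(self):
        a = em.generate(small_config())
        b = em.generate(small_config())
        assert [r for r in a.corpus.rows] == [r for r in b.corpus.rows]
        assert a.gold.labels == b.gold.labels
        assert a.true_dictionaries == b.true_dictionaries

    def test_different_seeds_differ(self):
        a = em.generate(small_config(seed=1))
        b = em.generate(small_config(seed=2))
        assert [r.text for r in a.corpus.rows] != [r.text for r in b.corpus.rows]

    def test_zero_prevalence_gives_all_negative_gold(self):
        cats = tuple(CategorySpec(c.name, 0.0, c.vocabulary) for c in DEFAULT_CATEGORIES)
        bundle = em.generate(small_config(categories=cats))
        assert all(tags == frozenset() for tags in bundle.gold.labels.values())

    def test_rows_per_patient_heavy_tailed(self):
        bundle = em.generate(em.SimConfig(n_patients=300, seed=3))
        counts = {}
        for row in bundle.corpus:
            counts[row.patient_id] = counts.get(row.patient_id, 0) + 1
        values = sorted(counts.values())
        mean = sum(values) / len(values)
        median = values[len(values) // 2]
        assert median < mean  # right skew
        assert 5 <= median <= 40 and 25 <= mean <= 110

    def test_prevalence_within_three_binomial_standard_errors(self):
        prev = 0.013
        cats = (CategorySpec("colic", prev, ("colic", "colicky", "impaction")),)
        bundle = em.generate(small_config(n_patients=200, categories=cats, seed=5))
        n = bundle.corpus.n_rows
        observed = len(bundle.gold.positives("colic")) / n
        se = math.sqrt(prev * (1 - prev) / n)
        assert abs(observed - prev) <= 3 * se

    def test_empty_vocabulary_with_positive_prevalence_rejected(self):
        cats = (CategorySpec("colic", 0.01, ()),)
        with pytest.raises(em.ConfigurationError, match="vocabulary"):
            em.generate(small_config(categories=cats))

    def test_gold_positive_rows_mention_category_vocabulary(self):
        bundle = em.generate(small_config())
        for name, ds in bundle.true_dictionaries.items():
            inclusion_words = {t.tokens[0] for t in ds.inclusion.terms}
            for row_id in bundle.gold.positives(name):
                tokens = set(em.tokenize(bundle.corpus[row_id].text))
                assert tokens & inclusion_words

    def test_no_variants_when_rates_zero(self):
        bundle = em.generate(small_config(misspelling_rate=0.0, abbreviation_rate=0.0))
        canon = {w for c in bundle.config.categories for w in c.vocabulary}
        for ds in bundle.true_dictionaries.values():
            assert {t.raw for t in ds.inclusion.terms} <= canon


class TestPerturbWord:
    def test_result_is_one_edit_away(self):
        """One edit under optimal string alignment (a transposition counts as
        a single edit); at most two under plain Levenshtein, confirmed with an
        independent aligner."""
        rng = np.random.default_rng(0)
        for word in ("flunixin", "colic", "phenylbutazone", "ab"):
            for _ in range(50):
                variant = em.perturb_word(word, rng)
                assert variant != word
                assert osa_distance(variant, word) == 1
                assert 1 <= edlib.align(variant, word)["editDistance"] <= 2

    def test_deterministic_under_fixed_rng_state(self):
        a = em.perturb_word("flunixin", np.random.default_rng(99))
        b = em.perturb_word("flunixin", np.random.default_rng(99))
        assert a == b

    def test_short_words_rejected(self):
        with pytest.raises(ValueError):
            em.perturb_word("a", np.random.default_rng(0))


class TestEndToEndRecovery:
    def test_true_dictionaries_reproduce_gold_exactly(self, small_bundle):
        corpus, gold = small_bundle.corpus, small_bundle.gold
        for name, ds in small_bundle.true_dictionaries.items():
            result = em.classify(corpus, ds)
            ct = em.confusion(result.final, gold, name, corpus.n_rows)
            assert (ct.fp, ct.fn) == (0, 0)

    def test_ablation_monotonicity(self, small_bundle):
        """Dropping exclusion can only add false positives; dropping
        reinclusion can only add false negatives."""
        corpus, gold = small_bundle.corpus, small_bundle.gold
        for name, ds in small_bundle.true_dictionaries.items():
            empty = lambda stage: em.StageDictionary(name, stage, ())
            full_ct = em.confusion(
                em.classify(corpus, ds).final, gold, name, corpus.n_rows
            )
            no_exc = em.CategoryDictionarySet(
                category=name, inclusion=ds.inclusion,
                exclusion=empty("exclusion"), reinclusion=empty("reinclusion"),
            )
            ct = em.confusion(em.classify(corpus, no_exc).final, gold, name, corpus.n_rows)
            assert ct.fp >= full_ct.fp and ct.fn <= full_ct.fn
            no_rein = em.CategoryDictionarySet(
                category=name, inclusion=ds.inclusion,
                exclusion=ds.exclusion, reinclusion=empty("reinclusion"),
            )
            ct = em.confusion(em.classify(corpus, no_rein).final, gold, name, corpus.n_rows)
            assert ct.fn >= full_ct.fn and ct.fp <= full_ct.fp


class TestWriteBundle:
    def test_files_round_trip_through_the_io_layer(self, small_bundle, tmp_path):
        paths = em.write_bundle(small_bundle, tmp_path)
        corpus = em.read_corpus(paths["corpus"], em.WRITTEN_DIALECT)
        assert [r.text for r in corpus] == [r.text for r in small_bundle.corpus]
        gold = em.read_gold_labels(paths["gold"], small_bundle.gold.categories)
        assert gold.labels == small_bundle.gold.labels
        for name, ds in small_bundle.true_dictionaries.items():
            loaded = em.load_dictionary_set(paths["dict_config"], name)
            assert loaded.inclusion.terms == ds.inclusion.terms
            assert loaded.exclusion.terms == ds.exclusion.terms
            assert loaded.reinclusion.terms == ds.reinclusion.terms
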