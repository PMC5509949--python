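import pytest

import emrminer as em
from emrminer.case_detection import stage_cases, combine

from conftest import make_corpus, make_dict_set


def case_set(ids, category="nsaid", stage="final"):
    return em.CaseSet(category=category, stage=stage, row_ids=frozenset(ids))


class TestStageCases:
    def test_empty_dictionary_matches_nothing(self, toy_corpus):
        sd = em.StageDictionary(category="nsaid", stage="exclusion", terms=())
        cs, match = stage_cases(toy_corpus, sd)
        assert (len(cs), match.n_times) == (0, 0)

    def test_times_and_cases_on_toy_corpus(self):
        corpus = make_corpus(["x", "colic", "y", "colic then colic again", "z"])
        sd = make_dict_set("colic", inclusion=["colic"]).inclusion
        cs, match = stage_cases(corpus, sd)
        assert sorted(cs.row_ids) == [2, 4]
        assert (match.n_times, match.n_cases) == (3, 2)

    def test_scope_restricts_search(self):
        corpus = make_corpus(["x", "colic", "y", "colic then colic again", "z"])
        sd = make_dict_set("colic", inclusion=["colic"]).inclusion
        cs, match = stage_cases(corpus, sd, scope=case_set([2], "colic"))
        assert sorted(cs.row_ids) == [2] and match.n_times == 1

    def test_scope_outside_corpus_is_integrity_error(self, toy_corpus):
        sd = make_dict_set("colic", inclusion=["colic"]).inclusion
        with pytest.raises(em.IntegrityError):
            stage_cases(toy_corpus, sd, scope=case_set([99], "colic"))


class TestCombine:
    def test_forced_set_algebra(self):
        final = combine(case_set({1, 2, 3}, stage="inclusion"),
                        case_set({2, 3}, stage="exclusion"),
                        case_set({3}, stage="reinclusion"))
        assert sorted(final.row_ids) == [1, 3]
        assert final.stage == "final"

    def test_identity_with_empty_exclusion_and_reinclusion(self):
        final = combine(case_set({1, 2, 3}, stage="inclusion"),
                        case_set(set(), stage="exclusion"),
                        case_set(set(), stage="reinclusion"))
        assert final.row_ids == frozenset({1, 2, 3})

    def test_category_mismatch_rejected(self):
        with pytest.raises(ValueError, match="category"):
            combine(case_set({1}), case_set(set(), category="colic"), case_set(set()))

    def test_reinclusion_outside_exclusion_warns(self):
        with pytest.warns(UserWarning, match="never excluded"):
            final = combine(case_set({1}, stage="inclusion"),
                            case_set(set(), stage="exclusion"),
                            case_set({5}, stage="reinclusion"))
        assert final.row_ids == frozenset({1, 5})

    @pytest.mark.parametrize(
        "n_inc, n_exc, n_rein, expected",
        [(1181, 112, 78, 1147), (291, 57, 5, 239), (23, 1, 0, 22), (7, 0, 0, 7)],
    )
    def test_stage_count_identity_chains(self, n_inc, n_exc, n_rein, expected):
        """|final| = |I| - |E| + |R| whenever E ⊆ I and R ⊆ E with R ∩ (I∖E) = ∅."""
        inc = set(range(n_inc))
        exc = set(range(n_exc))  # E ⊆ I
        rein = set(range(n_rein))  # R ⊆ E
        final = combine(case_set(inc, stage="inclusion"),
                        case_set(exc, stage="exclusion"),
                        case_set(rein, stage="reinclusion"))
        assert len(final) == expected


class TestClassify:
    def test_no_inclusion_hits_gives_empty_final(self, toy_corpus):
        ds = make_dict_set("nsaid", inclusion=["zzz"])
        result = em.classify(toy_corpus, ds)
        assert len(result.final) == 0
        assert result.summary.inclusion.n_times == 0

    def test_worked_three_row_example(self, toy_corpus, toy_dict_set):
        result = em.classify(toy_corpus, toy_dict_set)
        assert sorted(result.stage_sets["inclusion"].row_ids) == [1, 2, 3]
        assert sorted(result.stage_sets["exclusion"].row_ids) == [2, 3]
        assert sorted(result.stage_sets["reinclusion"].row_ids) == [3]
        assert sorted(result.final.row_ids) == [1, 3]

    def test_reinclusion_scope_defaults_to_exclusion_rows(self, toy_dict_set):
        # "but danilon" also present in a row the exclusion stage never touched
        corpus = make_corpus(
            ["bute given", "no bute given", "no bute given but danilon dispensed",
             "anything but danilon today"]
        )
        scoped = em.classify(corpus, toy_dict_set, reinclusion_scope="exclusion")
        assert sorted(scoped.stage_sets["reinclusion"].row_ids) == [3]
        with pytest.warns(UserWarning, match="never excluded"):
            full = em.classify(corpus, toy_dict_set, reinclusion_scope="full")
        assert sorted(full.stage_sets["reinclusion"].row_ids) == [3, 4]

    def test_final_set_invariants(self, small_bundle):
        corpus = small_bundle.corpus
        for name, ds in small_bundle.true_dictionaries.items():
            r = em.classify(corpus, ds)
            inc, exc, rein = (r.stage_sets[s].row_ids for s in ("inclusion", "exclusion", "reinclusion"))
            assert r.final.row_ids <= inc | rein
            assert (inc - exc) <= r.final.row_ids
            assert r.summary.final_cases == len(r.final)

    def test_adding_inclusion_term_never_shrinks_final(self, small_bundle):
        corpus = small_bundle.corpus
        ds = small_bundle.true_dictionaries["colic"]
        base = em.classify(corpus, ds).final.row_ids
        for extra in ("recheck", "zzznever"):
            grown = em.StageDictionary(
                category="colic", stage="inclusion",
                terms=ds.inclusion.terms + (em.Term.from_string(extra),),
            )
            ds2 = em.CategoryDictionarySet(
                category="colic", inclusion=grown,
                exclusion=ds.exclusion, reinclusion=ds.reinclusion,
            )
            assert em.classify(corpus, ds2).final.row_ids >= base

    def test_classification_is_deterministic(self, small_bundle):
        ds = small_bundle.true_dictionaries["nsaid"]
        r1 = em.classify(small_bundle.corpus, ds)
        r2 = em.classify(small_bundle.corpus, ds)
        assert r1.final == r2.final and r1.summary == r2.summary

    def test_unknown_reinclusion_scope_rejected(self, toy_corpus, toy_dict_set):
        with pytest.raises(ValueError, match="scope"):
            em.classify(toy_corpus, toy_dict_set, reinclusion_scope="sometimes")
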