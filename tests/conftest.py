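import pytest
from hypothesis import HealthCheck, settings

import emrminer as em

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_corpus(texts, patient_id="P1"):
    """Build an in-memory corpus from bare note texts, rows numbered from 1."""
    return em.Corpus(
        em.EmrRow(row_id=i, patient_id=patient_id, date=None, text=t)
        for i, t in enumerate(texts, start=1)
    )


def make_dict_set(category, inclusion, exclusion=(), reinclusion=()):
    def stage(name, terms):
        return em.StageDictionary(
            category=category, stage=name, terms=tuple(em.Term.from_string(t) for t in terms)
        )

    return em.CategoryDictionarySet(
        category=category,
        inclusion=stage("inclusion", inclusion),
        exclusion=stage("exclusion", exclusion),
        reinclusion=stage("reinclusion", reinclusion),
    )


@pytest.fixture
def toy_corpus():
    """The worked three-row example: plain positive, negated, negated-then-rescued."""
    return make_corpus(
        ["bute given", "no bute given", "no bute given but danilon dispensed"]
    )


@pytest.fixture
def toy_dict_set():
    return make_dict_set(
        "nsaid",
        inclusion=["bute", "danilon"],
        exclusion=["no bute"],
        reinclusion=["but danilon"],
    )


@pytest.fixture(scope="session")
def small_bundle():
    return em.generate(em.SimConfig(n_patients=40, seed=7))
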