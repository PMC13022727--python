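import dataclasses

import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")

from retrostrat.corpus import (  # noqa: E402
    CorpusSpec,
    UNAMBIGUOUS_FAMILIES,
    generate_corpus,
    make_buyables,
)
from retrostrat.pipeline import curate, train_pipeline  # noqa: E402
from retrostrat.planner import BuyablesCatalog  # noqa: E402
from retrostrat.relevance import TrainConfig  # noqa: E402


@dataclasses.dataclass
class World:
    """A small synthetic corpus with both pipelines trained on it."""

    corpus: object
    records: list
    higher: object  # CurationResult
    original: object
    trained_higher: object  # TrainResult
    trained_original: object
    stock_exact: BuyablesCatalog
    stock_variant: BuyablesCatalog


@pytest.fixture(scope="session")
def world() -> World:
    corpus = generate_corpus(CorpusSpec(n_documents=40, p_tactical=0.4, seed=21))
    records = list(corpus.iter_records())
    higher = curate(records, space="higher")
    original = curate(records, space="original")
    cfg = TrainConfig(seed=3, max_epochs=300)
    return World(
        corpus=corpus,
        records=records,
        higher=higher,
        original=original,
        trained_higher=train_pipeline(higher.dataset, seed=3, config=cfg),
        trained_original=train_pipeline(original.dataset, seed=3, config=cfg),
        stock_exact=BuyablesCatalog.from_smiles(make_buyables(corpus, False)),
        stock_variant=BuyablesCatalog.from_smiles(make_buyables(corpus, True)),
    )


@pytest.fixture(scope="session")
def model_world():
    """Ten-family corpus at the scale used for model-recovery checks."""
    corpus = generate_corpus(
        CorpusSpec(
            n_documents=700, p_tactical=0.3, seed=42, families=UNAMBIGUOUS_FAMILIES
        )
    )
    higher = curate(list(corpus.iter_records()), space="higher")
    trained = train_pipeline(
        higher.dataset, seed=5, config=TrainConfig(seed=5, max_epochs=300)
    )
    return corpus, higher, trained


@pytest.fixture(scope="session")
def provenance_corpus():
    """Every route carries one planted tactical detour."""
    return generate_corpus(CorpusSpec(n_documents=110, p_tactical=1.0, seed=7))
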