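import numpy as np
import pytest

from bgcn_screen.instruments import (
    AnswerMatrix,
    InstrumentBank,
    ItemSpec,
    default_item_bank,
)


@pytest.fixture(scope="session")
def bank106():
    return default_item_bank()


@pytest.fixture
def tiny_bank():
    """3-item bank: one 4-level ordinal item and two binary items."""
    return InstrumentBank(
        items=(
            ItemSpec(item_id="mood", kind="ordinal", n_levels=4),
            ItemSpec(item_id="sleep", kind="binary", n_levels=2),
            ItemSpec(item_id="worry", kind="binary", n_levels=2, subscale="N"),
        ),
        name="tiny",
    )


@pytest.fixture
def tiny_answers(tiny_bank):
    codes = np.array([[0, 0, 1], [3, 1, 0], [2, 1, 1], [1, 0, 0]])
    return AnswerMatrix(
        codes=codes, respondent_ids=["a", "b", "c", "d"], bank=tiny_bank
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
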