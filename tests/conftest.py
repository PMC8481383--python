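import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_rt_dataset() -> pd.DataFrame:
    """Three participants x two trials in one condition, fully enumerable."""
    return pd.DataFrame(
        {
            "participant_id": ["a", "a", "b", "b", "c", "c"],
            "display": "multicolor",
            "response": "negative",
            "rt_ms": [300.0, 400.0, 350.0, 500.0, 280.0, 600.0],
            "correct": True,
        }
    )


def make_rt_frame(values_by_pid: dict, display="multicolor", response="negative"):
    rows = []
    for pid, vals in values_by_pid.items():
        for v in vals:
            rows.append(
                {
                    "participant_id": pid,
                    "display": display,
                    "response": response,
                    "rt_ms": float(v),
                    "correct": True,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def small_corpus():
    """A small synthetic corpus with its ground truth."""
    from turntimes.synthetic import CorpusGenSpec, gen_conversation_corpus

    spec = CorpusGenSpec(
        n_conversations={2: 3, 3: 3}, minutes=2.0, seed=42
    )
    return gen_conversation_corpus(spec)
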