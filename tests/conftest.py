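import numpy as np
import pytest

from coopnet import (
    build_coop_network,
    build_vocabulary,
    generate_population,
    planted_three_group_config,
)
from coopnet.io import EMOTION_LABELS, ResponseRecord


def make_record(rid, associations, labels=None, scores=None):
    """Pad a short association list into a full 5-slot record."""
    assoc = tuple(associations) + ("",) * (5 - len(associations))
    if labels is None:
        labels = tuple(
            ("interest", "hope") if a else () for a in assoc
        )
    return ResponseRecord(
        respondent_id=rid,
        associations=assoc,
        emotion_labels=tuple(labels),
        attitude_scores=scores or {},
    )


@pytest.fixture(scope="session")
def planted_population():
    """500-respondent, 3-group planted sample with ground truth."""
    cfg = planted_three_group_config(n_respondents=500)
    records, truth = generate_population(cfg, seed=20205)
    return cfg, records, truth


@pytest.fixture(scope="session")
def planted_network(planted_population):
    _, records, _ = planted_population
    vocab = build_vocabulary(records, 3)
    return records, vocab, build_coop_network(records, vocab)


@pytest.fixture
def rng():
    return np.random.default_rng(77)


@pytest.fixture
def small_records():
    """Ten respondents over a tiny fixed vocabulary."""
    labs = list(EMOTION_LABELS)
    recs = []
    base = ["war", "refugee", "help", "fear", "border"]
    extra = ["camp", "family", "crisis", "home", "work"]
    for r in range(10):
        assoc = [base[(r + k) % 5] for k in range(3)] + [
            extra[r % 5],
            extra[(r + 2) % 5],
        ]
        labels = tuple(
            (labs[(r + k) % 20], labs[(r + k + 1) % 20]) for k in range(5)
        )
        recs.append(
            ResponseRecord(
                respondent_id=f"r{r}",
                associations=tuple(assoc),
                emotion_labels=labels,
                attitude_scores={"pot": 1.0 + (r % 5)},
            )
        )
    return recs
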