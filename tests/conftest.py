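import numpy as np
import pandas as pd
import pytest

from cbrl.synth import GeneratorConfig, generate_behavior_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small paired dataset (4 pairs x 3 repetitions, both conditions)."""
    cfg = GeneratorConfig(n_pairs=4, repetitions=3, seed=7)
    table, manifest = generate_behavior_dataset(cfg)
    return table, manifest, cfg


@pytest.fixture(scope="session")
def clean_small_dataset(small_dataset):
    from cbrl.behavior import filter_aborts

    table, _, cfg = small_dataset
    clean, frac = filter_aborts(table)
    return clean, frac, cfg


def make_session_frame(outcomes, chosen=None, rts=None, phase="learning",
                       correct_action=None):
    """Hand-built single-session trial frame from outcome labels."""
    n = len(outcomes)
    if rts is None:
        rts = [500.0 if o != "abort" else np.nan for o in outcomes]
    if chosen is None:
        chosen = [0 if o != "abort" else None for o in outcomes]
    if correct_action is None:
        correct_action = [c if o == "correct" else (1 - c if c is not None else -1)
                          for o, c in zip(outcomes, chosen)]
    return pd.DataFrame({
        "phase": phase,
        "trial_index": np.arange(1, n + 1),
        "symbol": "0",
        "correct_action": correct_action,
        "chosen_action": chosen,
        "outcome": outcomes,
        "rt": rts,
    })
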