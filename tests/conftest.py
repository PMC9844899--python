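import numpy as np
import pytest

from minresp.synthetic_data import (
    GeneratorConfig,
    generate_corpus,
    generate_session,
    render_audio,
    truth_to_window_table,
)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_dyads=2, sessions_per_dyad=2, session_length=120.0, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_session(small_config, 0, 0)


@pytest.fixture(scope="session")
def small_audio(small_config, small_truth):
    return render_audio(small_truth, small_config)


@pytest.fixture(scope="session")
def bypass_corpus():
    """Moderate ground-truth corpus for statistical tests (no audio)."""
    cfg = GeneratorConfig(n_dyads=8, sessions_per_dyad=12, session_length=1500.0, seed=42)
    truths, manifest = generate_corpus(cfg)
    return cfg, truths, manifest


@pytest.fixture(scope="session")
def bypass_windows(bypass_corpus):
    import pandas as pd

    _, truths, _ = bypass_corpus
    return pd.concat([truth_to_window_table(t) for t in truths], ignore_index=True)
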