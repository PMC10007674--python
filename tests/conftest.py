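import numpy as np
import pytest

from choqfuse import SimulationConfig, ViewScoreMatrix, simulate_batch


@pytest.fixture
def rng():
    return np.random.default_rng(20230238)


@pytest.fixture
def small_batch():
    """Tiny degraded-regime batch shared across consensus/metrics tests."""
    cfg = SimulationConfig(n_captures=40, C=5, K=3, regime="degraded", seed=7)
    return simulate_batch(cfg)


def make_matrix(scores, capture_id="cap0", **kw):
    scores = np.asarray(scores, dtype=float)
    C, K = scores.shape
    return ViewScoreMatrix(
        scores=scores,
        class_labels=[f"class_{c:02d}" for c in range(C)],
        view_ids=[f"cam{k}" for k in range(K)],
        capture_id=capture_id,
        **kw,
    )
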