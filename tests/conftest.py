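import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg():
    from rorqualrisk.ioutils import default_config

    return default_config()


@pytest.fixture(scope="session")
def small_trace():
    """One 6 h deployment with 50 embedded lunges, plus its ground truth."""
    from rorqualrisk.synthetic import TraceSpec, gen_tag_trace

    return gen_tag_trace(TraceSpec(n_lunges=50, duration=6.0, seed=7))


@pytest.fixture(scope="session")
def tiny_scenario_config(default_cfg):
    """Blue-krill + humpback-fish scenario config at reduced replicate count."""
    from rorqualrisk.pipeline import build_scenario_config

    return build_scenario_config(
        default_cfg,
        seed=11,
        n_replicates=200,
        combinations=[("blue", "krill"), ("humpback", "fish")],
    )


def match_events(detected_s: np.ndarray, truth_s: np.ndarray, tol: float = 5.0):
    """Greedy matching of detected to true event times within ``tol`` seconds.

    Returns (n_matched, n_false_positive).
    """
    detected_s = np.sort(np.asarray(detected_s))
    truth_s = np.sort(np.asarray(truth_s))
    used = np.zeros(len(detected_s), dtype=bool)
    matched = 0
    for t in truth_s:
        if len(detected_s) == 0:
            break
        i = int(np.argmin(np.where(used, np.inf, np.abs(detected_s - t))))
        if not used[i] and abs(detected_s[i] - t) <= tol:
            used[i] = True
            matched += 1
    return matched, int((~used).sum())
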