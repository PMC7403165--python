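import numpy as np
import pandas as pd
import pytest

from gpcmix import SimulationProfile, english_preset, german_preset, simulate_study


@pytest.fixture(scope="session")
def english():
    return english_preset()


@pytest.fixture(scope="session")
def german():
    return german_preset()


@pytest.fixture
def make_records():
    """Build a validated-shape response table from compact row tuples
    (participant, grade, item, condition, category, consonant_correct,
    is_error[, session])."""

    def _make(rows):
        out = []
        for r in rows:
            session = r[7] if len(r) > 7 else 1
            out.append(
                {
                    "participant_id": r[0],
                    "grade": r[1],
                    "item_id": r[2],
                    "condition": r[3],
                    "session": session,
                    "response_category": r[4],
                    "consonant_correct": r[5],
                    "is_error": r[6],
                }
            )
        return pd.DataFrame(out)

    return _make


@pytest.fixture(scope="session")
def simulated_english(english):
    """A mid-sized noise-free English-style cohort with known weights."""
    design, probs = english
    profile = SimulationProfile(
        n_participants_per_grade={2: 10, 3: 10},
        true_beta=(0.2, 0.7, 0.1),
        lapse_rate=0.0,
        consonant_error_rate=0.0,
        seed=123,
        items_per_condition={c: 40 for c in design.conditions},
    )
    return simulate_study(profile, design, probs), (0.2, 0.7, 0.1)


def simplex_grid(step=0.01):
    """All weight vectors on the 3-simplex at the given resolution."""
    n = int(round(1.0 / step))
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i / n, j / n, (n - i - j) / n))
    return np.array(pts)
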