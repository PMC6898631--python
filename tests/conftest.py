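import numpy as np
import pandas as pd
import pytest

from reprodyn.io import PWM, CountMatrix, SampleSheet


@pytest.fixture
def near_consensus_acgt() -> PWM:
    """Length-4 PWM with 0.97 on the consensus word ACGT."""
    m = np.full((4, 4), 0.01)
    m[np.arange(4), [0, 1, 2, 3]] = 0.97
    return PWM("acgt", m)


@pytest.fixture
def uniform_pwm() -> PWM:
    return PWM("uniform", np.full((4, 4), 0.25))


def make_design(
    counts: np.ndarray,
    times=(0.0, 24.0),
    conditions=("dox",),
    replicates=2,
    features=None,
) -> tuple[CountMatrix, SampleSheet]:
    """Wrap a (features x samples) array in CountMatrix + SampleSheet.

    Samples are ordered condition-major, then time, then replicate.
    """
    rows = []
    for cond in conditions:
        for t in times:
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_t{t:g}_r{rep}",
                        "condition": cond,
                        "time_h": t,
                        "replicate": rep,
                    }
                )
    sheet = SampleSheet(pd.DataFrame(rows))
    if features is None:
        features = [f"g{i}" for i in range(counts.shape[0])]
    cm = CountMatrix(features, sheet.sample_ids, counts)
    return cm, sheet


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
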