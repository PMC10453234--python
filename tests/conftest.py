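import numpy as np
import pytest

from tabgra.detection_io import DetectionMatrix, IndicatorSpec


@pytest.fixture
def two_indicator_matrix() -> DetectionMatrix:
    specs = [
        IndicatorSpec("lead", 0.5, 0.05, "mg/kg"),
        IndicatorSpec("chromium", 1.0, 0.03, "mg/kg"),
    ]
    values = np.array([[0.0425, 0.357], [0.127, 0.052], [0.08, 0.418]])
    return DetectionMatrix(["1", "2", "3"], specs, values)


def random_detection_matrix(rng: np.random.Generator, m: int, n: int) -> DetectionMatrix:
    specs = [IndicatorSpec(f"ind{i}", float(rng.uniform(0.5, 20)), None, "mg/kg")
             for i in range(m)]
    values = rng.uniform(0.0, 10.0, size=(n, m))
    return DetectionMatrix([str(k) for k in range(n)], specs, values)
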