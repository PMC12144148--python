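import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gaze_csv(tmp_path):
    """Factory writing a small gaze table and returning its path."""

    def make(rows, header="time_ms,x_px,y_px", name="gaze.csv"):
        path = tmp_path / name
        lines = [header] + [",".join(str(v) for v in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return make


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function w.r.t. array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = x[idx]
        x[idx] = old + eps
        f1 = f()
        x[idx] = old - eps
        f2 = f()
        x[idx] = old
        g[idx] = (f1 - f2) / (2 * eps)
    return g
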