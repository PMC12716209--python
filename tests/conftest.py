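import numpy as np
import pandas as pd
import pytest

from lamscreen import PopulationSpec, SceneSpec, render_scene, simulate_population


@pytest.fixture
def control_spec():
    """Control population whose model R^2 exceeds 0.95 (no trimming)."""
    return PopulationSpec(n_cells=2000, frac_senescent=0.0, resid_sd=3.0, seed=11)


@pytest.fixture
def control_table(control_spec):
    return simulate_population(control_spec)


@pytest.fixture
def small_scene():
    truth = simulate_population(PopulationSpec(n_cells=25, seed=3))
    spec = SceneSpec(
        image_shape=(512, 512), min_center_distance=30.0, noise_sd=0.0, seed=3
    )
    return render_scene(truth, spec)


def make_line_control(n=50, slope=0.8, intercept=5.0, a_lo=50.0, a_hi=150.0):
    """Control cells lying exactly on a line (zero residual)."""
    a = np.linspace(a_lo, a_hi, n)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "condition": "control",
            "well": "A1",
            "timepoint_h": 0.0,
            "true_label": "non_senescent",
            "lamin_a": a,
            "lamin_b1": slope * a + intercept,
        }
    )
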