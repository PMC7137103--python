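import numpy as np
import pandas as pd
import pytest

from xtalscale.reflection_data import SweepMetadata, _init_derived, map_to_asu
from xtalscale.synthetic import GroundTruth, generate_sweeps

SMALL = dict(cell=(30.0, 35.0, 40.0, 90.0, 90.0, 90.0), d_min=2.5,
             multiplicity=4.0, mean_I=1200.0)


def make_table(h, k, l, I, var, phi=None, d=None, sweep_id="s"):
    """Hand-built reflection table with valid unit-vector geometry."""
    n = len(h)
    phi = np.zeros(n) if phi is None else np.asarray(phi, dtype=float)
    d = np.full(n, 2.5) if d is None else np.asarray(d, dtype=float)
    df = pd.DataFrame({
        "h": np.asarray(h, dtype=np.int64),
        "k": np.asarray(k, dtype=np.int64),
        "l": np.asarray(l, dtype=np.int64),
        "sweep_id": sweep_id,
        "I_prof": np.asarray(I, dtype=float),
        "var_prof": np.asarray(var, dtype=float),
        "I_sum": np.asarray(I, dtype=float),
        "var_sum": np.asarray(var, dtype=float),
        "phi": phi, "d": d,
        "x_det": np.full(n, 0.5), "y_det": np.full(n, 0.5),
        "s0cx": np.zeros(n), "s0cy": np.zeros(n), "s0cz": np.ones(n),
        "s1cx": np.ones(n), "s1cy": np.zeros(n), "s1cz": np.zeros(n)})
    return _init_derived(df)


def grouped_table(intensities_by_group, var=1.0, space_group="P 1"):
    """Table with explicit symmetry groups: one unique hkl per group."""
    h, k, l, I = [], [], [], []
    for gi, vals in enumerate(intensities_by_group):
        for v in vals:
            h.append(gi + 1)
            k.append(0)
            l.append(0)
            I.append(v)
    t = make_table(h, k, l, I, np.full(len(I), var))
    return map_to_asu(t, space_group)


@pytest.fixture(scope="session")
def sweep360():
    return SweepMetadata("s", 0.0, 360.0, 0.1)


@pytest.fixture(scope="session")
def sim_single_sweep():
    """Moderate-noise single sweep with smooth scale, decay and absorption."""
    truth = GroundTruth(sweep_width=60.0, scale_amplitude=0.2,
                        decay_B_final=3.0, absorption_amplitude=0.05,
                        absorption_lmax=2, **SMALL)
    table, sweeps, truth = generate_sweeps(truth, seed=101)
    return table, sweeps, truth


@pytest.fixture(scope="session")
def sim_error_model():
    """10^4 observations with variances inflated by (a, b) = (1.3, 0.04)."""
    truth = GroundTruth(scale_amplitude=0.0, error_a=1.3, error_b=0.04,
                        mean_I=2000.0, multiplicity=5.0,
                        cell=(40.0, 45.0, 50.0, 90.0, 90.0, 90.0),
                        d_min=2.2)
    table, sweeps, truth = generate_sweeps(truth, seed=7, n_obs=10000)
    table = map_to_asu(table, truth.space_group)
    return table, truth
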