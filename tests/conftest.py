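import numpy as np
import pandas as pd
import pytest

import salience_cpt as sc
from salience_cpt.pipeline import RECOVERY_MAP


@pytest.fixture(scope="session")
def default_sequence():
    return sc.generate_sequence(sc.TaskParams(rng_seed=0))


@pytest.fixture
def small_params():
    # 2 blocks x 40 trials: 10 NoGo + 4 SalientGo + 26 StandardGo per block
    return sc.TaskParams(n_blocks=2, trials_per_block=40, rng_seed=1)


@pytest.fixture(scope="session")
def small_sequence():
    return sc.generate_sequence(sc.TaskParams(n_blocks=2, trials_per_block=40, rng_seed=1))


@pytest.fixture(scope="session")
def quiet_model():
    """Noise-free forward model at 200 Hz."""
    return sc.default_forward_model(noise_scale=0.0)


def make_profile(**latent_overrides) -> sc.SubjectProfile:
    """A deterministic subject with editable latent parameters."""
    prof = sc.simulate_profiles(1, seed=123)[0]
    prof.latent.update(latent_overrides)
    return prof


@pytest.fixture
def profile():
    return make_profile()


@pytest.fixture
def frozen_profile():
    """No trial-to-trial variability in any component."""
    return make_profile(
        **{
            "inhibition_P3.amp_sd": 0.0,
            "inhibition_P3.lat_sd": 0.0,
            "salience_P3.amp_sd": 0.0,
            "salience_P3.lat_sd": 0.0,
            "salience_N2.amp_sd": 0.0,
            "salience_N2.lat_sd": 0.0,
        }
    )


def null_records(n: int, seed: int) -> pd.DataFrame:
    """Record-level null cohort: the latent parameters stand in directly for
    measured component values, with all injected correlations zero."""
    profiles = sc.simulate_profiles(n, sc.EffectConfig.null(), seed=seed)
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "adhd_index": p.adhd_index,
            "age": p.age,
            "sex": p.sex,
            "iq_raw": p.iq_raw,
        }
        for param, column in RECOVERY_MAP.items():
            row[column] = p.latent[param]
        rows.append(row)
    return pd.DataFrame(rows)


def brute_force_fractional_latency(times, wave, t_start, t_end, fraction=0.5,
                                   polarity="positive", step_ms=0.001):
    """Dense-grid oracle for the fractional-area latency.

    Linearly interpolates the waveform onto a fine grid, rectifies, and finds
    the first grid point at which the running cumulative trapezoid area
    reaches ``fraction`` of the window total.
    """
    grid = np.arange(t_start, t_end + step_ms / 2, step_ms)
    w = np.interp(grid, times, wave)
    if polarity == "negative":
        w = -w
    w = np.clip(w, 0.0, None)
    seg = 0.5 * (w[1:] + w[:-1]) * step_ms
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return float("nan")
    idx = int(np.searchsorted(cum, fraction * total))
    return float(grid[min(idx, len(grid) - 1)])


def partial_correlation_precision_oracle(x, y, covariates):
    """Pearson partial correlation via the precision matrix of (x, y, C)."""
    data = np.column_stack([x, y, np.atleast_2d(covariates)])
    prec = np.linalg.inv(np.cov(data, rowvar=False))
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))
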