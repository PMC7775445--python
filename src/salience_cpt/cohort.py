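"""Synthetic Salience-CPT cohort with known ground truth.

Emulates a community sample of school children performing the Salience CPT:

* per-subject covariates (age, sex, Raven SPM raw score) and a parent-rated
  ADHD Index sum score;
* latent neural parameters per ERP component (mean amplitude and latency of
  the inhibition-P3, salience-P3 and salience-N2 difference components, plus
  their trial-to-trial standard deviations);
* latent behavioral parameters (condition-wise RT mean/SD, miss and
  false-alarm probabilities).

Associations between the ADHD Index and the latent parameters are injected
through a single-factor Gaussian copula: every latent variable ``v`` is
constructed as ``rho_v * g + sqrt(1 - rho_v^2) * eps`` where ``g`` is the
standardized ADHD factor, so the population correlation between ``v`` and
the ADHD latent equals ``rho_v`` exactly and the implied correlation matrix
is positive-definite for any ``|rho_v| < 1``. Marginals are then mapped to
realistic scales (clipping/rounding where the real quantity is bounded or
integer-valued).

EEG epochs are produced by a linear forward model: each ERP component is a
Gaussian bump in time with a fixed scalp-weight map, added to 1/f plus white
noise. Per-trial component amplitude and latency are drawn around the
subject's latent means with the subject's latent trial-SDs, and the drawn
values are returned as ground truth so downstream recovery can be verified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import TrialSequence
from .preprocess import ContinuousEEG, EpochsSet

GO_CONDITIONS = ("StandardGo", "SalientGo")


class ConfigurationError(ValueError):
    """Invalid cohort/effect configuration."""


# ---------------------------------------------------------------------------
# Latent-parameter marginals
# ---------------------------------------------------------------------------

#: name -> (mean, between-subject SD, clip_lo, clip_hi)
#: Amplitudes in uV (peak of the Gaussian component), latencies/SDs in ms,
#: probabilities dimensionless.  Means/SDs emulate the published descriptives
#: (RT ~390/78 ms StandardGo, trial-SD ~160 ms, commission ~0.41, omission
#: ~0.04) and the printed component statistics (signed areas ~919/799/78
#: uV*ms with peaks near 460/455/300 ms).
DEFAULT_MARGINALS: dict = {
    "inhibition_P3.amp": (5.6, 1.8, 0.5, None),
    "inhibition_P3.lat": (460.0, 30.0, 330.0, 580.0),
    "inhibition_P3.amp_sd": (2.2, 0.7, 0.3, None),
    "inhibition_P3.lat_sd": (45.0, 15.0, 5.0, None),
    "salience_P3.amp": (5.0, 1.6, 0.5, None),
    "salience_P3.lat": (455.0, 30.0, 370.0, 580.0),
    "salience_P3.amp_sd": (2.2, 0.7, 0.3, None),
    "salience_P3.lat_sd": (45.0, 15.0, 5.0, None),
    "salience_N2.amp": (1.15, 0.4, 0.1, None),
    "salience_N2.lat": (300.0, 12.0, 262.0, 338.0),
    "salience_N2.amp_sd": (0.8, 0.25, 0.1, None),
    "salience_N2.lat_sd": (20.0, 7.0, 3.0, None),
    "rt_mean_standard": (390.0, 78.0, 250.0, 600.0),
    "rt_shift_salient": (33.0, 30.0, -60.0, 130.0),
    "rt_sd_standard": (160.0, 39.0, 50.0, None),
    "rt_sd_salient": (163.0, 48.0, 50.0, None),
    "fa_p": (0.41, 0.18, 0.02, 0.90),
}

#: Default injected (partial) correlations between the ADHD latent factor and
#: each latent parameter: the sign and magnitude pattern of the study's
#: correlation battery (salience-P3 amplitude -0.44; amplitude variability
#: -0.51 for both P3s; salience-P3 latency variability +0.46; null-range
#: values for the N2 and the behavioral measures).
DEFAULT_TARGET_CORRELATIONS: dict = {
    "inhibition_P3.amp": -0.34,
    "inhibition_P3.lat": 0.38,
    "inhibition_P3.amp_sd": -0.51,
    "inhibition_P3.lat_sd": 0.11,
    "salience_P3.amp": -0.44,
    "salience_P3.lat": 0.28,
    "salience_P3.amp_sd": -0.51,
    "salience_P3.lat_sd": 0.46,
    "salience_N2.amp": -0.02,
    "salience_N2.lat": -0.09,
    "salience_N2.amp_sd": 0.08,
    "salience_N2.lat_sd": 0.22,
    "rt_mean_standard": 0.01,
    "rt_shift_salient": -0.20,
    "rt_sd_standard": 0.12,
    "rt_sd_salient": 0.04,
    "fa_p": 0.15,
    "miss_p": 0.12,
}


@dataclass
class EffectConfig:
    """Injected ground-truth effect structure of the synthetic cohort.

    ``target_correlations`` maps latent-parameter names to their population
    correlation with the ADHD latent factor.  ``covariate_correlations``
    does the same for age, sex and SPM raw score (zero by default: the
    covariates are pure noise regressors unless configured otherwise).
    ``noise_scale`` multiplies the EEG noise amplitudes of the default
    forward model.
    """

    target_correlations: dict = field(
        default_factory=lambda: dict(DEFAULT_TARGET_CORRELATIONS)
    )
    covariate_correlations: dict = field(
        default_factory=lambda: {"age": 0.0, "sex": 0.0, "iq_raw": 0.0}
    )
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    sex_male_prob: float = 14 / 31
    noise_scale: float = 1.0

    def all_correlations(self) -> dict:
        out = dict(self.covariate_correlations)
        out.update(self.target_correlations)
        return out

    def validate(self) -> None:
        rhos = np.array(list(self.all_correlations().values()), dtype=float)
        if np.any(np.abs(rhos) >= 1):
            raise ConfigurationError("target correlations must lie in (-1, 1)")
        # one-factor correlation matrix; positive-definiteness check
        R = np.outer(rhos, rhos)
        np.fill_diagonal(R, 1.0)
        R = np.block(
            [[np.ones((1, 1)), rhos[None, :]], [rhos[:, None], R]]
        )
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise ConfigurationError(
                "implied correlation matrix is not positive-definite"
            ) from err

    @classmethod
    def null(cls, **kwargs) -> "EffectConfig":
        """All injected correlations zero (type-I / null cohort)."""
        cfg = cls(**kwargs)
        cfg.target_correlations = {k: 0.0 for k in cfg.target_correlations}
        cfg.covariate_correlations = {k: 0.0 for k in cfg.covariate_correlations}
        return cfg


@dataclass
class SubjectProfile:
    """Ground-truth description of one synthetic subject."""

    subject_id: str
    age: float
    sex: int  # 1 = male, 0 = female
    iq_raw: int
    adhd_index: int
    latent: dict  # parameter name -> true value (transformed scale)

    @property
    def miss_p(self) -> float:
        return self.latent["miss_p"]

    @property
    def fa_p(self) -> float:
        return self.latent["fa_p"]

    def rt_params(self, condition: str) -> tuple:
        """(mean ms, sd ms) of the RT distribution for a condition."""
        mu = self.latent["rt_mean_standard"]
        sd = self.latent["rt_sd_standard"]
        if condition == "SalientGo":
            mu = mu + self.latent["rt_shift_salient"]
            sd = self.latent["rt_sd_salient"]
        return mu, sd


def simulate_profiles(
    n_subjects: int,
    effects: EffectConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    return_latent: bool = False,
):
    """Draw a cohort of :class:`SubjectProfile` with injected effects.

    With ``return_latent=True`` additionally returns the underlying
    standardized Gaussian scores (one column per variable, including the
    ADHD factor) whose empirical correlations converge to the configured
    targets as ``n_subjects`` grows.
    """
    effects = effects or EffectConfig()
    effects.validate()
    rng = np.random.default_rng(seed)

    names = ["age", "sex", "iq_raw"] + list(effects.target_correlations)
    rhos = np.array([effects.all_correlations()[k] for k in names])

    g = rng.standard_normal(n_subjects)
    eps = rng.standard_normal((n_subjects, len(names)))
    z = rhos * g[:, None] + np.sqrt(1.0 - rhos**2) * eps

    latent_df = pd.DataFrame(z, columns=names)
    latent_df.insert(0, "adhd", g)

    def lin(zv, mean, sd, lo=None, hi=None):
        v = mean + sd * zv
        return np.clip(v, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)

    adhd_index = np.clip(np.round(5.32 + 4.36 * g), 0, 30).astype(int)
    age = lin(latent_df["age"].to_numpy(), 10.7, 0.53, 9.0, 11.9)
    sex = (latent_df["sex"].to_numpy() < sps.norm.ppf(effects.sex_male_prob)).astype(int)
    iq_raw = np.clip(np.round(40 + 7 * latent_df["iq_raw"].to_numpy()), 15, 58).astype(int)

    profiles = []
    for i in range(n_subjects):
        latent: dict = {}
        for name in effects.target_correlations:
            zv = latent_df.loc[i, name]
            if name == "miss_p":
                # right-skewed: median 0.02 emulating the observed 0.04 (0.05)
                latent[name] = float(np.clip(math.exp(math.log(0.02) + 1.0 * zv), 0.0, 0.30))
            else:
                mean, sd, lo, hi = effects.marginals[name]
                latent[name] = float(lin(zv, mean, sd, lo, hi))
        profiles.append(
            SubjectProfile(
                subject_id=f"sub-{i + 1:03d}",
                age=float(age[i]),
                sex=int(sex[i]),
                iq_raw=int(iq_raw[i]),
                adhd_index=int(adhd_index[i]),
                latent=latent,
            )
        )
    if return_latent:
        return profiles, latent_df
    return profiles


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """One ERP component: a Gaussian bump with a fixed scalp-weight map.

    If ``latent`` is set, per-trial amplitude (uV) and peak latency (ms) are
    drawn from the subject's latent means/trial-SDs under that key prefix;
    otherwise ``amp``/``peak_ms`` are used for every trial.  Negative
    components carry negative channel weights and a positive latent
    amplitude magnitude.
    """

    name: str
    conditions: tuple | None  # None = all conditions
    peak_ms: float
    sigma_ms: float
    amp: float
    weights: Mapping[str, float]
    latent: str | None = None
    lat_clip: tuple | None = None


@dataclass
class ERPForwardModel:
    sfreq: float
    channels: tuple
    components: tuple
    pink_sd: float = 6.0
    white_sd: float = 4.0
    pink_exponent: float = 1.0
    alpha_amp: float = 0.0
    alpha_freq: float = 10.0
    spatially_correlated_noise: bool = False

    def validate(self) -> None:
        for comp in self.components:
            if comp.sigma_ms <= 0:
                raise ConfigurationError(f"component {comp.name}: sigma must be > 0")
            unknown = set(comp.weights) - set(self.channels)
            if unknown:
                raise ConfigurationError(
                    f"component {comp.name}: unknown channels {sorted(unknown)}"
                )


P3_WEIGHTS = {"POz": 1.0, "Pz": 0.85, "Cz": 0.5, "Fz": 0.2, "O1": 0.4, "O2": 0.4}


def default_forward_model(sfreq: float = 200.0, noise_scale: float = 1.0) -> ERPForwardModel:
    """Forward model emulating the published grand averages.

    Posterior P1 at 100 ms, anterior NoGo-P2 at 200 ms, a standard parietal
    P3 at 400 ms common to all conditions, plus the three latent-driven
    difference components: inhibition-P3 (NoGo, ~460 ms, POz-max),
    salience-P3 (SalientGo, ~455 ms, POz-max) and salience-N2 (SalientGo,
    ~300 ms, Fz-max, negative).
    """
    comps = (
        Component("P1", None, 100.0, 25.0, 4.0,
                  {"O1": 1.0, "O2": 1.0, "POz": 0.6, "Pz": 0.3}),
        Component("P2_nogo", ("NoGo",), 200.0, 30.0, 2.0, {"Fz": 0.8, "Cz": 1.0}),
        Component("P3_standard", None, 400.0, 70.0, 3.0,
                  {"Pz": 1.0, "POz": 0.9, "Cz": 0.6, "Fz": 0.2, "O1": 0.3, "O2": 0.3}),
        Component("inhibition_P3", ("NoGo",), 460.0, 70.0, 0.0, P3_WEIGHTS,
                  latent="inhibition_P3", lat_clip=(330.0, 580.0)),
        Component("salience_P3", ("SalientGo",), 455.0, 70.0, 0.0, P3_WEIGHTS,
                  latent="salience_P3", lat_clip=(370.0, 580.0)),
        Component("salience_N2", ("SalientGo",), 300.0, 30.0, 0.0,
                  {"Fz": -1.0, "Cz": -0.7, "Pz": -0.15},
                  latent="salience_N2", lat_clip=(255.0, 345.0)),
    )
    return ERPForwardModel(
        sfreq=sfreq,
        channels=("Fz", "Cz", "Pz", "POz", "O1", "O2", "M1", "M2"),
        components=comps,
        pink_sd=6.0 * noise_scale,
        white_sd=4.0 * noise_scale,
    )


def gaussian_area(amp: float, lat: float, sigma: float, t_start: float, t_end: float) -> float:
    """Analytic area (uV*ms) of a Gaussian component inside a window."""
    return float(
        amp
        * sigma
        * math.sqrt(2 * math.pi)
        * (sps.norm.cdf((t_end - lat) / sigma) - sps.norm.cdf((t_start - lat) / sigma))
    )


def _pink_noise(rng: np.random.Generator, shape: tuple, sfreq: float, exponent: float) -> np.ndarray:
    """1/f^exponent noise via FFT spectral shaping, unit SD per row."""
    from scipy.fft import irfft, next_fast_len

    n = shape[-1]
    n_fft = next_fast_len(n)  # pad to a composite length, then truncate
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal(shape[:-1] + (freqs.size,))
        + 1j * rng.standard_normal(shape[:-1] + (freqs.size,))
    ) * scale
    x = irfft(spec, n=n_fft, axis=-1)[..., :n]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _trial_component_draws(
    rng: np.random.Generator,
    profile: SubjectProfile,
    comp: Component,
    n: int,
) -> tuple:
    """Per-trial (amplitude, latency) arrays for one varying component."""
    amp_mu = profile.latent[f"{comp.latent}.amp"]
    amp_sd = profile.latent[f"{comp.latent}.amp_sd"]
    lat_mu = profile.latent[f"{comp.latent}.lat"]
    lat_sd = profile.latent[f"{comp.latent}.lat_sd"]
    amps = np.clip(rng.normal(amp_mu, amp_sd, n), 0.0, None)
    lats = rng.normal(lat_mu, lat_sd, n)
    if comp.lat_clip is not None:
        lats = np.clip(lats, *comp.lat_clip)
    return amps, lats


def simulate_continuous(
    profile: SubjectProfile,
    seq: TrialSequence,
    model: ERPForwardModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    pad_start_ms: float = 500.0,
    pad_end_ms: float = 1000.0,
):
    """Simulate a continuous multichannel recording for one subject.

    Returns ``(continuous, events, ground_truth)`` where ``events`` are
    stimulus-onset sample indices aligned with ``seq.trials`` and
    ``ground_truth`` holds the per-trial true amplitude/latency of every
    latent-driven component (NaN on trials where the component is absent).
    """
    model = model or default_forward_model()
    model.validate()
    rng = np.random.default_rng(seed)
    sf = model.sfreq
    n_ch = len(model.channels)

    trial_dur = seq.params.trial_duration
    n_samples = int(round((pad_start_ms + len(seq) * trial_dur + pad_end_ms) / 1000.0 * sf))
    data = np.zeros((n_ch, n_samples))
    t_ms = np.arange(n_samples) / sf * 1000.0

    events = np.round((pad_start_ms + np.arange(len(seq)) * trial_dur) / 1000.0 * sf).astype(int)
    conditions = seq.conditions

    gt = pd.DataFrame({"trial": np.arange(len(seq)), "condition": conditions})

    ch_index = {ch: i for i, ch in enumerate(model.channels)}
    for comp in model.components:
        active = (
            np.ones(len(seq), bool)
            if comp.conditions is None
            else np.isin(conditions, comp.conditions)
        )
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            continue
        if comp.latent is not None:
            amps, lats = _trial_component_draws(rng, profile, comp, idx.size)
            gt[f"{comp.name}_amp"] = np.nan
            gt[f"{comp.name}_lat"] = np.nan
            gt.loc[idx, f"{comp.name}_amp"] = amps
            gt.loc[idx, f"{comp.name}_lat"] = lats
        else:
            amps = np.full(idx.size, comp.amp)
            lats = np.full(idx.size, comp.peak_ms)

        w = np.zeros(n_ch)
        for ch, wt in comp.weights.items():
            w[ch_index[ch]] = wt
        half = int(round(4 * comp.sigma_ms / 1000.0 * sf))
        for k, trial in enumerate(idx):
            center = events[trial] + lats[k] / 1000.0 * sf
            s0 = max(0, int(math.floor(center)) - half)
            s1 = min(n_samples, int(math.ceil(center)) + half + 1)
            tt = t_ms[s0:s1] - (t_ms[events[trial]] + lats[k])
            bump = amps[k] * np.exp(-0.5 * (tt / comp.sigma_ms) ** 2)
            data[:, s0:s1] += w[:, None] * bump[None, :]

    if model.pink_sd > 0:
        data += model.pink_sd * _pink_noise(rng, (n_ch, n_samples), sf, model.pink_exponent)
    if model.white_sd > 0:
        data += model.white_sd * rng.standard_normal((n_ch, n_samples))
    if model.alpha_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
        data += model.alpha_amp * np.sin(
            2 * np.pi * model.alpha_freq * t_ms[None, :] / 1000.0 + phase
        )

    cont = ContinuousEEG(data=data, sfreq=sf, ch_names=list(model.channels))
    return cont, events, gt


def simulate_epochs(
    profile: SubjectProfile,
    seq: TrialSequence,
    model: ERPForwardModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    tmin_ms: float = -200.0,
    tmax_ms: float = 900.0,
):
    """Simulate epochs directly (continuous simulation sliced around onsets).

    No filtering or baseline correction is applied; the returned
    :class:`EpochsSet` is the raw forward-model output.  Ground truth as in
    :func:`simulate_continuous`.
    """
    model = model or default_forward_model()
    cont, events, gt = simulate_continuous(profile, seq, model, seed)
    n_t = int(round((tmax_ms - tmin_ms) / 1000.0 * model.sfreq))
    offset = int(round(tmin_ms / 1000.0 * model.sfreq))
    starts = events + offset
    epochs = np.stack([cont.data[:, s : s + n_t] for s in starts])
    metadata = pd.DataFrame(
        {"trial": np.arange(len(seq)), "condition": seq.conditions}
    )
    es = EpochsSet(
        data=epochs,
        sfreq=model.sfreq,
        tmin_ms=tmin_ms,
        ch_names=list(model.channels),
        metadata=metadata,
    )
    return es, gt


def simulate_behavior(
    profile: SubjectProfile,
    seq: TrialSequence,
    seed: int | np.random.SeedSequence = 0,
    rt_shift_ms: float = 150.0,
):
    """Per-trial responses: Go trials answered with p = 1 - miss_p, NoGo
    trials answered (false alarms) with p = fa_p; RTs follow a shifted
    lognormal with the subject's condition mean/SD.  Tail responses outside
    the 200-1500 ms registration window occur naturally and exercise the
    response-window filter downstream.
    """
    rng = np.random.default_rng(seed)
    conditions = seq.conditions
    n = len(seq)
    responded = np.zeros(n, bool)
    rts = np.full(n, np.nan)

    for cond in ("StandardGo", "SalientGo", "NoGo"):
        idx = np.nonzero(conditions == cond)[0]
        if idx.size == 0:
            continue
        if cond == "NoGo":
            p_resp = profile.fa_p
            mu, sd = profile.rt_params("StandardGo")
        else:
            p_resp = 1.0 - profile.miss_p
            mu, sd = profile.rt_params(cond)
        answered = rng.random(idx.size) < p_resp
        m = max(mu - rt_shift_ms, 50.0)
        sigma2 = math.log(1.0 + (sd / m) ** 2)
        mu_log = math.log(m) - sigma2 / 2.0
        draw = rt_shift_ms + rng.lognormal(mu_log, math.sqrt(sigma2), idx.size)
        draw = np.minimum(draw, seq.params.trial_duration)  # respond within the trial
        responded[idx] = answered
        rts[idx[answered]] = draw[answered]

    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "condition": conditions,
            "responded": responded,
            "rt_ms": rts,
        }
    )
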