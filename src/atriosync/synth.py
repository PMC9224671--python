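"""Synthetic paired surface/coronary-sinus cohort generator.

Emulates the statistical structure that the downstream analysis assumes:
sinus-rhythm beat trains with autocorrelated inter-beat intervals (IBIs),
two channels (surface lead II and one bipolar CS channel) whose activation
fiducials carry independent per-channel timing jitter, activation durations
coupled *on the cycle-fraction scale*, ectopic beats at a small configurable
prevalence, and additive power-line / baseline-wander / broadband noise.

The central modelling choice is that cross-channel coupling lives on the
normalized-duration scale: for beat ``i`` on channel ``ch`` the measured
duration is ``D_ch,i = n_ch,i * IBI_ch,i / 1000`` where ``n_ch,i`` (an
"ms-at-1000-ms-cycle" equivalent) is drawn with cross-channel correlation
``rho_duration``.  Heart-rate adjustment with the channel's own IBI —
multiplying by ``sf_i = 1000 / IBI_i`` — is then the exact inverse of the
generative distortion, so HR fluctuation and fiducial jitter mask the latent
coupling in raw durations and the adjustment recovers it.  This is the
minimal model in which HR adjustment has something real to recover.

P-waves are rendered as nonnegative raised-cosine humps (maximum amplitude
equals peak-to-peak amplitude, as for positive lead-II P-waves); local
activation waves as biphasic derivative-of-Gaussian wavelets (first
deflection negative, so early slope rates are negative and peak-to-peak
exceeds the signed maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .records import CS, PHASES, SURFACE, AnnotatedRecording

__all__ = [
    "PhaseEffect",
    "CohortConfig",
    "GroundTruth",
    "generate_ibi_series",
    "generate_patient",
    "render_waveforms",
    "patient_seeds",
]

_MIN_IBI_MS = 200.0  # physiological floor for the AR(1) interval series


@dataclass
class PhaseEffect:
    """Multiplicative shifts a procedure phase applies to the generative scales.

    ``duration_scale`` and ``amplitude_scale`` multiply the normalized
    durations / amplitudes of *both* channels; ``ibi_scale`` shifts the mean
    heart period (radio-frequency application lowers heart rate, i.e. raises
    the IBI); ``arv_scale`` shifts the IBI spread and therefore every
    rate-variability summary.  Each ``*_sd`` is the standard deviation of a
    per-patient lognormal modulation of the corresponding shift, shared
    between channels, so ablation-induced variation differs across patients
    instead of collapsing to a cohort constant.  The heart-period shift is
    kept patient-constant by default (``ibi_sd = 0``): the heart period is
    common-mode across channels, so any patient spread in it would add
    shared variance to *raw* duration variation and obscure rather than
    express the masking that heart-rate adjustment corrects.
    """

    duration_scale: float = 1.0
    amplitude_scale: float = 1.0
    ibi_scale: float = 1.0
    arv_scale: float = 1.0
    duration_sd: float = 0.02
    amplitude_sd: float = 0.02
    ibi_sd: float = 0.0
    arv_sd: float = 0.10


def default_phase_effects() -> dict[str, PhaseEffect]:
    return {
        "pre": PhaseEffect(1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0),
        "lpvi": PhaseEffect(0.97, 0.95, 1.10, 1.30),
        "post": PhaseEffect(0.92, 0.90, 0.95, 0.80),
    }


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    Defaults describe a 40-patient paroxysmal-AF ablation cohort recorded at
    1 kHz: ~300 sinus beats per recording around an 800 ms mean cycle with
    AR(1) heart-period fluctuation, latent duration coupling 0.7, 40 ms
    per-channel fiducial jitter, and ectopic beats on 2% of beats (the
    clinical recordings showed at most 4%).
    """

    n_patients: int = 40
    n_beats: int = 300
    fs: float = 1000.0
    ibi_mean: float = 800.0           # ms
    ibi_sd: float = 50.0              # ms, stationary AR(1) sd
    ibi_ar1: float = 0.6
    rho_duration: float = 0.7         # latent cross-channel duration coupling
    channel_ibi_jitter_sd: float = 40.0   # ms, per-channel fiducial jitter
    ectopic_rate: float = 0.02        # fraction of beats, <= 0.04
    powerline_amp: float = 0.02       # mV
    powerline_freq: float = 50.0      # Hz
    wander_amp: float = 0.05          # mV
    noise_sd: float = 0.01            # mV broadband
    # morphology (normalized durations are ms-equivalents at a 1000 ms cycle)
    pwave_duration_mean: float = 120.0
    pwave_duration_sd: float = 12.0
    law_duration_mean: float = 80.0
    law_duration_sd: float = 8.0
    pwave_amp_mean: float = 0.15      # mV
    pwave_amp_sd: float = 0.015
    law_amp_mean: float = 0.50        # mV
    law_amp_sd: float = 0.05
    cs_delay_ms: float = 30.0         # constant conduction delay of the CS channel
    phase_effects: dict[str, PhaseEffect] = field(default_factory=default_phase_effects)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 10:
            raise ValueError("n_beats must be >= 10")
        if not 0.0 <= self.ectopic_rate <= 0.04:
            raise ValueError("ectopic_rate must lie in [0, 0.04]")
        if self.ibi_mean <= 0:
            raise ValueError("ibi_mean must be positive")
        if not -1.0 <= self.rho_duration <= 1.0:
            raise ValueError("rho_duration must lie in [-1, 1]")
        if not 0.0 <= self.ibi_ar1 < 1.0:
            raise ValueError("ibi_ar1 must lie in [0, 1)")
        if isinstance(self.phase_effects, dict):
            self.phase_effects = {
                k: (v if isinstance(v, PhaseEffect) else PhaseEffect(**v))
                for k, v in self.phase_effects.items()
            }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_effects"] = {k: asdict(v) for k, v in self.phase_effects.items()}
        return d


@dataclass
class GroundTruth:
    """Latent variables behind one generated patient-phase.

    ``normalized_durations`` are the coupled cycle-fraction durations
    (ms-equivalents at a 1000 ms cycle) actually used per channel, after
    phase and ectopic morphology effects.  ``latent_rho`` is their realized
    sample correlation over non-ectopic beats.
    """

    master_ibi: np.ndarray                 # ms; element 0 is NaN (undefined)
    normalized_durations: dict[str, np.ndarray]
    true_annotations: dict[str, np.ndarray]
    channel_ibi: dict[str, np.ndarray]     # ms, measured fiducial-to-fiducial
    ectopic_flags: np.ndarray
    latent_rho: float


def generate_ibi_series(
    n_beats: int,
    mean: float,
    sd: float,
    ar1: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Stationary AR(1) inter-beat-interval series in ms, floored at 200 ms.

    The innovation variance is ``sd**2 * (1 - ar1**2)`` so the marginal
    stationary standard deviation equals ``sd``; the first element is drawn
    from the stationary distribution.
    """
    if mean <= 0:
        raise ValueError("mean IBI must be positive")
    if n_beats < 2:
        raise ValueError("need at least two beats")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if not abs(ar1) < 1:
        raise ValueError("|ar1| must be < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.empty(n_beats)
    innov_sd = sd * np.sqrt(1.0 - ar1 * ar1)
    x[0] = mean + sd * rng.standard_normal()
    eps = innov_sd * rng.standard_normal(n_beats - 1)
    for i in range(1, n_beats):
        x[i] = mean + ar1 * (x[i - 1] - mean) + eps[i - 1]
    return np.maximum(x, _MIN_IBI_MS)


def patient_seeds(config: CohortConfig) -> np.ndarray:
    """Deterministic per-patient child seeds spawned from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    return ss.generate_state(config.n_patients).astype(np.int64)


def _phase_rng(patient_seed: int, phase: str,
               stream: int = 0) -> np.random.Generator:
    """Child generator for one patient-phase.

    ``stream`` separates the beat-schedule draws (0) from waveform-noise
    draws (1) so fiducial-level results are identical whether or not
    waveforms are rendered.
    """
    ss = np.random.SeedSequence(entropy=int(patient_seed),
                                spawn_key=(PHASES.index(phase), stream))
    return np.random.default_rng(ss)


def generate_patient(
    config: CohortConfig,
    phase: str,
    patient_seed: int,
    render: bool = True,
) -> tuple[AnnotatedRecording, AnnotatedRecording, GroundTruth]:
    """Generate one patient's paired recordings for one procedure phase.

    With ``render=False`` the recordings carry ground-truth annotations but
    no waveform samples; duration-, interval- and rate-variability analyses
    are unaffected and run orders of magnitude faster.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    rng = _phase_rng(patient_seed, phase)
    noise_rng = _phase_rng(patient_seed, phase, stream=1)
    eff = config.phase_effects.get(phase, PhaseEffect())

    # Per-patient modulation of the phase shifts, shared across channels.
    def mod(scale: float, sd: float) -> float:
        if sd <= 0:
            return scale
        return scale * float(np.exp(rng.normal(0.0, sd)))

    dur_scale = mod(eff.duration_scale, eff.duration_sd)
    amp_scale = mod(eff.amplitude_scale, eff.amplitude_sd)
    ibi_scale = mod(eff.ibi_scale, eff.ibi_sd)
    arv_scale = mod(eff.arv_scale, eff.arv_sd)

    n = config.n_beats
    phase_ibi_mean = config.ibi_mean * ibi_scale
    master_ibi = generate_ibi_series(n, phase_ibi_mean,
                                     config.ibi_sd * arv_scale,
                                     config.ibi_ar1, rng)

    t_master = np.empty(n)
    t_master[0] = 400.0  # leave room for the first activation's onset window
    t_master[1:] = 400.0 + np.cumsum(master_ibi[1:])

    # Ectopic beats: shorten the preceding interval by >= 30% and mark the
    # beat; morphology is attenuated below.  Never the first two or the last
    # beat, never two in a row; prevalence hard-capped at 4% of beats.
    ectopic = np.zeros(n, dtype=bool)
    candidates = rng.random(n) < config.ectopic_rate
    cap = int(np.floor(0.04 * n))
    for i in range(2, n - 1):
        if candidates[i] and not ectopic[i - 1] and ectopic.sum() < cap:
            ectopic[i] = True
            shift = (0.30 + 0.10 * rng.random()) * master_ibi[i]
            t_master[i] -= shift
    if not np.all(np.diff(t_master) > 0):
        raise RuntimeError("ectopic insertion broke beat ordering")

    # Coupled normalized durations (cycle-fraction scale).
    rho = config.rho_duration
    z_s = rng.standard_normal(n)
    z_c = rho * z_s + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    n_surf = (config.pwave_duration_mean + config.pwave_duration_sd * z_s) * dur_scale
    n_cs = (config.law_duration_mean + config.law_duration_sd * z_c) * dur_scale
    amp_surf = (config.pwave_amp_mean
                + config.pwave_amp_sd * rng.standard_normal(n)) * amp_scale
    amp_cs = (config.law_amp_mean
              + config.law_amp_sd * rng.standard_normal(n)) * amp_scale
    n_surf[ectopic] *= 0.7
    n_cs[ectopic] *= 0.7
    amp_surf[ectopic] *= 0.6
    amp_cs[ectopic] *= 0.6
    n_surf = np.clip(n_surf, 30.0, None)
    n_cs = np.clip(n_cs, 20.0, None)
    amp_surf = np.clip(amp_surf, 0.02, None)
    amp_cs = np.clip(amp_cs, 0.05, None)

    delays = {SURFACE: 0.0, CS: config.cs_delay_ms}
    ndur = {SURFACE: n_surf, CS: n_cs}
    amps = {SURFACE: amp_surf, CS: amp_cs}

    recordings: dict[str, AnnotatedRecording] = {}
    truth_ann: dict[str, np.ndarray] = {}
    channel_ibi: dict[str, np.ndarray] = {}
    total_ms = t_master[-1] + delays[CS] + 600.0

    for ch in (SURFACE, CS):
        jitter = rng.normal(0.0, config.channel_ibi_jitter_sd, n)
        peak_ms = t_master + delays[ch] + jitter
        # keep fiducials strictly increasing even at short ectopic couplings
        peak_ms = _enforce_min_spacing(peak_ms, 150.0)
        peak_idx = np.round(peak_ms * config.fs / 1000.0).astype(np.int64)
        ibi_ms = np.empty(n)
        ibi_ms[0] = np.nan
        ibi_ms[1:] = np.diff(peak_idx) / config.fs * 1000.0
        # measured duration: normalized duration times the channel's own cycle
        cycle = np.where(np.isnan(ibi_ms), phase_ibi_mean, ibi_ms)
        dur_ms = ndur[ch] * cycle / 1000.0
        ann = _schedule_annotations(peak_idx, dur_ms, config.fs, ch)
        truth_ann[ch] = ann
        channel_ibi[ch] = ibi_ms
        if render:
            samples = render_waveforms(
                ann, amps[ch], ch, config.fs, total_ms,
                powerline_amp=config.powerline_amp,
                powerline_freq=config.powerline_freq,
                wander_amp=config.wander_amp,
                noise_sd=config.noise_sd,
                rng=noise_rng,
            )
        else:
            samples = None
        recordings[ch] = AnnotatedRecording(
            samples=samples, fs=config.fs, channel_kind=ch,
            annotations=ann, ectopic_flags=ectopic.copy(),
        )

    master_ibi_out = master_ibi.copy()
    master_ibi_out[0] = np.nan
    keep = ~ectopic
    latent_rho = float(np.corrcoef(n_surf[keep], n_cs[keep])[0, 1])
    truth = GroundTruth(
        master_ibi=master_ibi_out,
        normalized_durations={SURFACE: n_surf, CS: n_cs},
        true_annotations=truth_ann,
        channel_ibi=channel_ibi,
        ectopic_flags=ectopic,
        latent_rho=latent_rho,
    )
    return recordings[SURFACE], recordings[CS], truth


def _enforce_min_spacing(times_ms: np.ndarray, min_gap: float) -> np.ndarray:
    out = times_ms.copy()
    for i in range(1, len(out)):
        if out[i] < out[i - 1] + min_gap:
            out[i] = out[i - 1] + min_gap
    return out


def _schedule_annotations(
    peak_idx: np.ndarray, dur_ms: np.ndarray, fs: float, channel_kind: str
) -> np.ndarray:
    """Onset/peak/offset sample indices for a beat schedule.

    Raised-cosine P-waves peak mid-window; derivative-of-Gaussian LAWs span
    ``[c - 3s, c + 3s]`` (``s`` the Gaussian scale, duration ``6 s``) with
    the signed maximum at ``c + s``, i.e. two-thirds of the way in.
    """
    dur = np.maximum(np.round(dur_ms * fs / 1000.0).astype(np.int64), 4)
    if channel_kind == SURFACE:
        onset = peak_idx - dur // 2
    else:
        onset = peak_idx - np.round(dur * 2.0 / 3.0).astype(np.int64)
    offset = onset + dur
    # inclusive windows: make sure onset < peak < offset strictly
    onset = np.minimum(onset, peak_idx - 1)
    offset = np.maximum(offset, peak_idx + 1)
    return np.column_stack([onset, peak_idx, offset])


def render_waveforms(
    annotations: np.ndarray,
    amplitudes: np.ndarray,
    channel_kind: str,
    fs: float,
    total_ms: float,
    *,
    powerline_amp: float = 0.0,
    powerline_freq: float = 50.0,
    wander_amp: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a sample sequence for an annotated beat schedule.

    P-waves (``channel_kind='surface'``) are nonnegative raised cosines, so
    the maximum amplitude equals the configured amplitude and equals the
    peak-to-peak amplitude.  Local activation waves (``'cs'``) are biphasic
    derivative-of-Gaussian wavelets normalized so the positive lobe reaches
    the configured amplitude; the negative lobe mirrors it, so peak-to-peak
    is twice the signed maximum.  Additive disturbances: a power-line
    sinusoid, slow sinusoidal-plus-random-walk baseline wander, and white
    noise.
    """
    annotations = np.asarray(annotations, dtype=np.int64)
    if len(annotations) > 1 and np.any(annotations[1:, 0] <= annotations[:-1, 2]):
        raise ValueError("overlapping activations cannot be rendered")
    if rng is None:
        rng = np.random.default_rng(0)
    n_samples = int(np.ceil(total_ms * fs / 1000.0))
    n_samples = max(n_samples, int(annotations[:, 2].max()) + 2)
    x = np.zeros(n_samples)

    for (onset, peak, offset), amp in zip(annotations, amplitudes):
        k = np.arange(onset, offset + 1)
        if channel_kind == SURFACE:
            u = (k - onset) / (offset - onset)
            x[onset:offset + 1] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        else:
            sigma = (offset - onset) / 6.0
            c = onset + 3.0 * sigma
            v = (k - c) / sigma
            x[onset:offset + 1] += amp * np.sqrt(np.e) * v * np.exp(-0.5 * v * v)

    t = np.arange(n_samples) / fs
    if powerline_amp > 0:
        x += powerline_amp * np.sin(2.0 * np.pi * powerline_freq * t
                                    + rng.uniform(0, 2 * np.pi))
    if wander_amp > 0:
        x += 0.7 * wander_amp * np.sin(2.0 * np.pi * 0.25 * t
                                       + rng.uniform(0, 2 * np.pi))
        walk = np.cumsum(rng.standard_normal(n_samples))
        x += 0.3 * wander_amp * walk / (np.std(walk) + 1e-12)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n_samples)
    return x
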