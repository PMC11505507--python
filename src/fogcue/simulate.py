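"""Synthetic 40 Hz multi-channel gait recordings with labeled freezing episodes.

Real freezing-of-gait (FoG) recordings from Parkinson's disease patients are
not publicly shareable, so every downstream stage (windowing, the classifier,
the streaming detector, evaluation) is exercised on simulated recordings that
reproduce the *statistical shape* of such datasets: recordings of tens of
thousands of samples at 40 Hz, 20 sensor channels, FoG prevalence between
roughly 1.5% and 15%, and a handful to dozens of discrete freezing episodes
interleaved with walking, standing and turning.

Channel layout (20 channels in 4 groups, two sensor units below the knee):

    0-5    ACC   accelerometer, 2 sensors x 3 axes
    6-11   GYRO  gyroscope, 2 sensors x 3 axes
    12-15  CF    complementary-filter fused angles
    16-19  MA    muscle-activity envelopes

Generative model per activity:

* walk  — 1 Hz locomotor fundamental plus 2nd and 3rd harmonics with fixed
  per-channel amplitude and phase, plus white Gaussian noise;
* stand — noise only;
* turn  — walking pattern plus a slow (0.1-0.3 Hz) offset drift on the
  gyroscope and angle channels;
* fog   — locomotor band strongly suppressed and a low-amplitude 3-8 Hz
  trembling band added on accelerometer/gyroscope channels, with elevated
  variance on the muscle-activity channels.  Trembling-in-place is the
  documented, spectrally detectable surrogate for the (unpublished) raw
  signal morphology of real freezing episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SimConfig",
    "GaitRecording",
    "Episode",
    "CHANNEL_NAMES",
    "CHANNEL_GROUPS",
    "make_activity_schedule",
    "synthesize_channels",
    "generate_recording",
]

N_CHANNELS = 20

CHANNEL_NAMES: tuple[str, ...] = tuple(
    [f"acc{s}_{ax}" for s in (1, 2) for ax in "xyz"]
    + [f"gyro{s}_{ax}" for s in (1, 2) for ax in "xyz"]
    + [f"cf{i}" for i in range(1, 5)]
    + [f"ma{i}" for i in range(1, 5)]
)

#: channel indices per sensor group (ACC/GYRO/CF/MA), used by the ablation harness
CHANNEL_GROUPS: dict[str, tuple[int, ...]] = {
    "ACC": tuple(range(0, 6)),
    "GYRO": tuple(range(6, 12)),
    "CF": tuple(range(12, 16)),
    "MA": tuple(range(16, 20)),
}

GAIT_FUNDAMENTAL_HZ = 1.0  # matches the 1 Hz cueing rhythm (approximate step rate)
TREMOR_BAND_HZ = (3.0, 8.0)
NON_FOG_ACTIVITIES = ("walk", "stand", "turn")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class Episode:
    """Half-open [start, end) run of one activity, in sample indices."""

    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid episode bounds [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic recording.

    Defaults describe a mid-sized personal training recording: ~8 minutes at
    40 Hz, a dozen freezing episodes of 2-6 s, 8% FoG prevalence — inside the
    observed per-patient range (1.5-15.4% prevalence, 4-86 episodes).
    """

    duration_s: float = 500.0
    sampling_rate_hz: float = 40.0
    fog_prevalence: float = 0.08
    n_fog_episodes: int = 12
    fog_duration_s_range: tuple[float, float] = (2.0, 6.0)
    activity_mix: dict[str, float] = field(
        default_factory=lambda: {"walk": 0.6, "stand": 0.2, "turn": 0.2}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"ACC": 0.30, "GYRO": 0.30, "CF": 0.10, "MA": 0.20}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ConfigurationError("duration_s and sampling_rate_hz must be positive")
        if not 0.0 <= self.fog_prevalence <= 0.5:
            raise ConfigurationError("fog_prevalence must be in [0, 0.5]")
        if self.n_fog_episodes < 0:
            raise ConfigurationError("n_fog_episodes must be non-negative")
        lo, hi = self.fog_duration_s_range
        if not (0 < lo <= hi):
            raise ConfigurationError("fog_duration_s_range must satisfy 0 < min <= max")
        if set(self.activity_mix) != set(NON_FOG_ACTIVITIES):
            raise ConfigurationError(f"activity_mix must cover {NON_FOG_ACTIVITIES}")
        if any(p < 0 for p in self.activity_mix.values()):
            raise ConfigurationError("activity_mix proportions must be non-negative")
        if abs(sum(self.activity_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("activity_mix proportions must sum to 1")
        if set(self.noise_sd) != set(CHANNEL_GROUPS):
            raise ConfigurationError(f"noise_sd must cover groups {tuple(CHANNEL_GROUPS)}")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ConfigurationError("noise_sd values must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fog_duration_s_range"] = list(self.fog_duration_s_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "fog_duration_s_range" in d:
            d["fog_duration_s_range"] = tuple(d["fog_duration_s_range"])
        return cls(**d)


@dataclass
class GaitRecording:
    """Fixed-rate 20-channel signal matrix with per-sample binary FoG labels."""

    signals: np.ndarray  # (T, 20) float32
    labels: np.ndarray  # (T,) uint8, 1 = FoG
    activity: np.ndarray  # (T,) of {walk, stand, turn, fog}
    sampling_rate_hz: float
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.activity = np.asarray(self.activity, dtype=object)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (samples x channels) matrix")
        t, c = self.signals.shape
        if c != len(self.channel_names):
            raise ValueError(
                f"expected {len(self.channel_names)} channels, got {c}"
            )
        if t < 1:
            raise ValueError("recording must contain at least one sample")
        if self.labels.shape != (t,) or self.activity.shape != (t,):
            raise ValueError("labels/activity must align with signals")
        if not np.isfinite(self.signals).all():
            raise ValueError("signals contain non-finite values")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if not ((self.activity == "fog") == (self.labels == 1)).all():
            raise ValueError("labels must be 1 exactly on fog activity samples")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]


def _split_nonfog_gap(start: int, end: int, mix: dict[str, float], fs: float,
                      rng: np.random.Generator) -> list[Episode]:
    """Chop one non-fog gap into 2-8 s activity segments drawn from the mix."""
    acts = np.array(NON_FOG_ACTIVITIES)
    probs = np.array([mix[a] for a in acts], dtype=float)
    if probs.sum() == 0:  # degenerate mix: fall back to walking
        probs = np.array([1.0, 0.0, 0.0])
    probs = probs / probs.sum()
    episodes: list[Episode] = []
    pos = start
    while pos < end:
        seg = int(round(rng.uniform(2.0, 8.0) * fs))
        seg = min(seg, end - pos)
        if end - pos - seg < int(fs):  # avoid a trailing sliver shorter than 1 s
            seg = end - pos
        kind = str(rng.choice(acts, p=probs))
        episodes.append(Episode(pos, pos + seg, kind))
        pos += seg
    return episodes


def make_activity_schedule(config: SimConfig) -> list[Episode]:
    """Tile [0, T) with activity episodes containing the configured FoG load.

    Exactly ``n_fog_episodes`` freezing episodes are placed, separated by at
    least 1 s of non-fog activity.  Episode durations are drawn uniformly from
    ``fog_duration_s_range`` and then rescaled so the total FoG share matches
    ``fog_prevalence`` (the episode count wins over the raw durations when the
    two are inconsistent).
    """
    fs = config.sampling_rate_hz
    total = config.n_samples
    rng = np.random.default_rng(config.seed)
    n_ep = config.n_fog_episodes

    if n_ep == 0 or config.fog_prevalence == 0.0:
        if n_ep > 0:
            raise ConfigurationError(
                "n_fog_episodes > 0 requires fog_prevalence > 0"
            )
        return _split_nonfog_gap(0, total, config.activity_mix, fs, rng)

    fog_total = int(round(config.fog_prevalence * total))
    min_gap = int(fs)  # >= 1 s separation between freezing episodes
    if fog_total + (n_ep + 1) * min_gap > total:
        raise ConfigurationError(
            f"cannot place {n_ep} fog episodes totalling {fog_total} samples "
            f"with >=1 s gaps inside {total} samples"
        )

    # draw durations, then rescale so the prevalence target is met exactly
    raw = rng.uniform(*config.fog_duration_s_range, size=n_ep)
    durations = np.maximum(1, np.round(raw / raw.sum() * fog_total).astype(int))
    durations[-1] += fog_total - durations.sum()
    durations = np.maximum(durations, 1)

    nonfog_total = total - int(durations.sum())
    # distribute the non-fog budget over n_ep + 1 gaps, each >= 1 s
    extra = nonfog_total - (n_ep + 1) * min_gap
    weights = rng.dirichlet(np.ones(n_ep + 1))
    gaps = min_gap + np.floor(weights * extra).astype(int)
    gaps[0] += extra - (gaps.sum() - (n_ep + 1) * min_gap)

    episodes: list[Episode] = []
    pos = 0
    for i in range(n_ep):
        g0, g1 = pos, pos + int(gaps[i])
        episodes.extend(_split_nonfog_gap(g0, g1, config.activity_mix, fs, rng))
        pos = g1
        episodes.append(Episode(pos, pos + int(durations[i]), "fog"))
        pos += int(durations[i])
    episodes.extend(_split_nonfog_gap(pos, total, config.activity_mix, fs, rng))

    assert episodes[0].start == 0 and episodes[-1].end == total
    return episodes


def _channel_profile(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel harmonic amplitudes (20 x 3) and phases for the gait pattern."""
    base = np.array([1.0, 0.45, 0.2])  # fundamental + 2 harmonics
    amp = base[None, :] * rng.uniform(0.6, 1.4, size=(N_CHANNELS, 3))
    amp[CHANNEL_GROUPS["MA"], :] *= 0.5  # muscle envelopes carry a weaker rhythm
    phase = rng.uniform(0, 2 * np.pi, size=(N_CHANNELS, 3))
    return amp, phase


def synthesize_channels(schedule: list[Episode], config: SimConfig) -> GaitRecording:
    """Render a schedule into a 20-channel single-precision signal matrix."""
    fs = config.sampling_rate_hz
    total = schedule[-1].end
    if schedule[0].start != 0 or any(
        schedule[i].end != schedule[i + 1].start for i in range(len(schedule) - 1)
    ):
        raise ValueError("schedule must contiguously tile [0, T)")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    amp, phase = _channel_profile(rng)
    t = np.arange(total, dtype=np.float64) / fs
    harmonics = GAIT_FUNDAMENTAL_HZ * np.array([1.0, 2.0, 3.0])
    # (T, 20): locomotor pattern shared by walk/turn segments, phase-continuous
    gait = np.zeros((total, N_CHANNELS), dtype=np.float64)
    for k in range(3):
        gait += amp[:, k][None, :] * np.sin(
            2 * np.pi * harmonics[k] * t[:, None] + phase[:, k][None, :]
        )

    noise_sd = np.empty(N_CHANNELS)
    for grp, idx in CHANNEL_GROUPS.items():
        noise_sd[list(idx)] = config.noise_sd[grp]
    signals = rng.normal(0.0, 1.0, size=(total, N_CHANNELS)) * noise_sd[None, :]

    # tremor carrier for freezing segments: a few sinusoids inside 3-8 Hz
    trem_freqs = rng.uniform(*TREMOR_BAND_HZ, size=4)
    trem_phase = rng.uniform(0, 2 * np.pi, size=(N_CHANNELS, 4))
    imu = list(CHANNEL_GROUPS["ACC"]) + list(CHANNEL_GROUPS["GYRO"])
    tremor = np.zeros((total, N_CHANNELS), dtype=np.float64)
    for k in range(4):
        tremor[:, imu] += np.sin(
            2 * np.pi * trem_freqs[k] * t[:, None] + trem_phase[imu, k][None, :]
        )
    tremor *= 0.35 / np.sqrt(4)

    drift_ch = list(CHANNEL_GROUPS["GYRO"]) + list(CHANNEL_GROUPS["CF"])
    ma_ch = list(CHANNEL_GROUPS["MA"])

    activity = np.empty(total, dtype=object)
    for ep in schedule:
        sl = slice(ep.start, ep.end)
        activity[sl] = ep.kind
        if ep.kind == "walk":
            signals[sl] += gait[sl]
        elif ep.kind == "turn":
            signals[sl] += gait[sl]
            f_drift = rng.uniform(0.1, 0.3)
            ph = rng.uniform(0, 2 * np.pi)
            drift = 0.8 * np.sin(2 * np.pi * f_drift * t[sl] + ph)
            signals[sl.start:sl.stop, drift_ch] += drift[:, None]
        elif ep.kind == "fog":
            signals[sl] += 0.1 * gait[sl]  # locomotor band suppressed
            signals[sl] += tremor[sl]
            # elevated muscle-activity variance during freezing
            signals[sl.start:sl.stop, ma_ch] += rng.normal(
                0.0, 2.0 * config.noise_sd["MA"], size=(ep.n_samples, len(ma_ch))
            )
        elif ep.kind != "stand":
            raise ValueError(f"unknown activity kind {ep.kind!r}")

    labels = np.fromiter(
        (1 if a == "fog" else 0 for a in activity), dtype=np.uint8, count=total
    )
    return GaitRecording(
        signals=signals.astype(np.float32),
        labels=labels,
        activity=activity,
        sampling_rate_hz=fs,
    )


def generate_recording(config: SimConfig) -> GaitRecording:
    """Schedule + render: one labeled synthetic recording, deterministic in seed."""
    return synthesize_channels(make_activity_schedule(config), config)
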