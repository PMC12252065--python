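"""Synthetic wearable-sensor streams and sliding-window segmentation.

The generator emulates the structure that label-efficient HAR methods assume:
each activity has a temporally *stationary* signature (a per-activity base
frequency, per-channel amplitude, phase and DC level), while the signal as
recorded also carries temporally *varying* components: a per-person affine
nuisance (gain/phase/offset around which short execution "episodes"
re-realize every few seconds — people shift pace and posture while the
activity's semantics stay fixed), a fast in-episode modulation at roughly the
window timescale, and additive i.i.d. Gaussian noise.  Streams are
concatenations of contiguous single-activity bouts, giving the temporal
continuity that the temporal-consistency objective exploits.

Activity base frequencies are deterministic (1.0 + 0.25*a Hz) so that
noiseless signals are exactly periodic at known periods; amplitudes, phases
and DC levels are drawn once per activity from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig", "SensorStream", "SensorWindow",
    "generate_streams", "segment_windows", "downsample",
    "write_streams_csv", "read_streams_csv",
    "save_windows", "load_windows", "windows_to_arrays",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults give 3 activities performed by 4 persons on 3 channels at 25 Hz,
    twelve 20 s bouts per person; with 2.56 s / 1.28 s windowing this yields
    672 single-activity windows.
    """

    n_persons: int = 4
    n_activities: int = 3
    n_channels: int = 3
    sampling_rate: float = 25.0
    bout_length: float = 25.6
    n_bouts_per_person: int = 9
    noise_sigma: float = 0.1
    person_effect_scale: float = 0.3
    episode_seconds: float = 3.84
    seed: int = 0

    def __post_init__(self):
        for name in ("n_persons", "n_activities", "n_channels", "n_bouts_per_person"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sigma < 0 or self.person_effect_scale < 0:
            raise ValueError("noise_sigma and person_effect_scale must be >= 0")
        if round(self.bout_length * self.sampling_rate) < 1:
            raise ValueError("bout shorter than one sample")


@dataclass
class SensorStream:
    """A raw multichannel series with per-sample activity and person labels."""

    values: np.ndarray          # (T, C)
    sampling_rate: float
    activity_label: np.ndarray  # (T,), int
    person_id: np.ndarray       # (T,), int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.activity_label = np.asarray(self.activity_label, dtype=np.int64)
        self.person_id = np.asarray(self.person_id, dtype=np.int64)
        t = self.values.shape[0]
        if self.activity_label.shape != (t,) or self.person_id.shape != (t,):
            raise ValueError("label vectors must have length T")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class SensorWindow:
    """A fixed-length single-activity, single-person segment of a stream."""

    values: np.ndarray  # (W, C)
    activity: int
    person: int
    t: int              # window ordinal within its source stream

    @property
    def W(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def _activity_signatures(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Per-activity stationary signatures, a function of the seed only."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    m, c = cfg.n_activities, cfg.n_channels
    return {
        "freq": 1.0 + 0.25 * np.arange(m),            # Hz, deterministic
        "amp": rng.uniform(0.5, 1.5, size=(m, c)),
        "phase": rng.uniform(0.0, 2 * np.pi, size=(m, c)),
        "dc": rng.uniform(-1.0, 1.0, size=(m, c)),
    }


def _person_effects(cfg: SynthConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    s = cfg.person_effect_scale
    p, c = cfg.n_persons, cfg.n_channels
    return {
        "gain": 1.0 + s * rng.standard_normal((p, c)),
        "offset": s * rng.standard_normal((p, c)),
        "phase": s * rng.standard_normal(p),
    }


def generate_streams(cfg: SynthConfig) -> list[SensorStream]:
    """Generate one labeled stream per person.

    Each stream is ``n_bouts_per_person`` contiguous bouts; bout activities
    are shuffled full cycles over the classes, so every class appears for
    every person whenever ``n_bouts_per_person >= n_activities``.
    """
    sig = _activity_signatures(cfg)
    pers = _person_effects(cfg)
    bout_samples = int(round(cfg.bout_length * cfg.sampling_rate))
    streams: list[SensorStream] = []
    for p in range(cfg.n_persons):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303, p]))
        # shuffled full cycles keep per-person class coverage
        n_cycles = -(-cfg.n_bouts_per_person // cfg.n_activities)
        bout_acts: list[int] = []
        for _ in range(n_cycles):
            cyc = np.arange(cfg.n_activities)
            rng.shuffle(cyc)
            bout_acts.extend(int(a) for a in cyc)
        bout_acts = bout_acts[: cfg.n_bouts_per_person]

        total = bout_samples * cfg.n_bouts_per_person
        tau = np.arange(total) / cfg.sampling_rate       # global time axis
        values = np.empty((total, cfg.n_channels))
        labels = np.empty(total, dtype=np.int64)
        s = cfg.person_effect_scale
        c = cfg.n_channels
        ep_samples = max(1, int(round(cfg.episode_seconds * cfg.sampling_rate)))
        for b, a in enumerate(bout_acts):
            sl = slice(b * bout_samples, (b + 1) * bout_samples)
            t = tau[sl][:, None]                         # (S, 1)
            bout = np.empty((bout_samples, c))
            # the person nuisance is a process, not a constant: within a bout
            # the execution state (affine gain/phase/offset around the
            # person's baseline) re-realizes every few seconds — people shift
            # posture and pace while the activity's semantics stay fixed
            for e0 in range(0, bout_samples, ep_samples):
                e1 = min(e0 + ep_samples, bout_samples)
                te = t[e0:e1]
                gain_e = pers["gain"][p] * (1 + s * rng.standard_normal(c))
                off_e = pers["offset"][p] + s * rng.standard_normal(c)
                phase_e = pers["phase"][p] + s * rng.standard_normal()
                # fast modulation at roughly the window timescale: the
                # temporally varying execution component that the
                # consistency objectives are meant to average away
                f_fg, f_fo = rng.uniform(0.3, 0.8, size=2)
                ph_fg, ph_fo = rng.uniform(0, 2 * np.pi, size=(2, c))
                mod_gain = 1 + 0.5 * s * np.sin(2 * np.pi * f_fg * te + ph_fg)
                mod_off = 0.5 * s * np.sin(2 * np.pi * f_fo * te + ph_fo)
                wave = np.sin(2 * np.pi * sig["freq"][a] * te
                              + sig["phase"][a][None, :] + phase_e)
                bout[e0:e1] = (gain_e * mod_gain * sig["amp"][a] * wave
                               + sig["dc"][a] + off_e + mod_off)
            values[sl] = bout
            labels[sl] = a
        values += cfg.noise_sigma * rng.standard_normal(values.shape)
        streams.append(SensorStream(values, cfg.sampling_rate, labels,
                                    np.full(total, p, dtype=np.int64)))
    return streams


def segment_windows(stream: SensorStream, window_seconds: float,
                    step_seconds: float) -> list[SensorWindow]:
    """Left-to-right sliding windows; windows spanning an activity or person
    change are dropped so every emitted window has a single label pair.

    ``W = round(window_seconds * rate)``, ``step = round(step_seconds * rate)``;
    the trailing partial window is discarded and ``t`` is assigned in temporal
    order after discarding.
    """
    w = int(round(window_seconds * stream.sampling_rate))
    step = int(round(step_seconds * stream.sampling_rate))
    if w < 1:
        raise ValueError("window shorter than one sample")
    if step_seconds <= 0 or step < 1:
        raise ValueError("step must be positive")
    out: list[SensorWindow] = []
    t = 0
    for start in range(0, stream.n_samples - w + 1, step):
        acts = stream.activity_label[start:start + w]
        persons = stream.person_id[start:start + w]
        if acts.min() != acts.max() or persons.min() != persons.max():
            continue  # mixed-label candidate: dropped
        out.append(SensorWindow(stream.values[start:start + w].copy(),
                                int(acts[0]), int(persons[0]), t))
        t += 1
    return out


def downsample(stream: SensorStream, factor: int) -> SensorStream:
    """Decimate by keeping every ``factor``-th sample (keep-first, no
    anti-alias filter); sampling rate is divided accordingly."""
    if not float(factor).is_integer():
        raise ValueError("downsample factor must be an integer")
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return SensorStream(stream.values[::factor].copy(),
                        stream.sampling_rate / factor,
                        stream.activity_label[::factor].copy(),
                        stream.person_id[::factor].copy())


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_streams_csv(streams: list[SensorStream], path: str | Path) -> None:
    """Long-format log: ``person,activity,sample_index,ch0..ch{C-1}``."""
    frames = []
    for s in streams:
        df = pd.DataFrame({
            "person": s.person_id,
            "activity": s.activity_label,
            "sample_index": np.arange(s.n_samples),
        })
        for c in range(s.n_channels):
            df[f"ch{c}"] = s.values[:, c]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_streams_csv(path: str | Path, sampling_rate: float) -> list[SensorStream]:
    df = pd.read_csv(path)
    channels = [c for c in df.columns if c.startswith("ch")]
    streams = []
    for person, grp in df.groupby("person", sort=True):
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(f"sample_index not contiguous for person {person}")
        streams.append(SensorStream(
            grp[channels].to_numpy(dtype=np.float64), sampling_rate,
            grp["activity"].to_numpy(dtype=np.int64),
            grp["person"].to_numpy(dtype=np.int64)))
    return streams


def save_windows(windows: list[SensorWindow], directory: str | Path,
                 sampling_rate: float | None = None) -> None:
    """Persist windows as two CSVs: ``meta.csv`` (one row per window, ordered
    by window id) and ``values.csv`` (one row per sample)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame({
        "window_id": np.arange(len(windows)),
        "person": [w.person for w in windows],
        "activity": [w.activity for w in windows],
        "t": [w.t for w in windows],
        "W": [w.W for w in windows],
        "C": [w.n_channels for w in windows],
    })
    if sampling_rate is not None:
        meta["sampling_rate"] = sampling_rate
    meta.to_csv(directory / "meta.csv", index=False)
    rows = []
    for i, w in enumerate(windows):
        df = pd.DataFrame(w.values, columns=[f"ch{c}" for c in range(w.n_channels)])
        df.insert(0, "k", np.arange(w.W))
        df.insert(0, "window_id", i)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(directory / "values.csv", index=False)


def load_windows(directory: str | Path) -> list[SensorWindow]:
    directory = Path(directory)
    meta = pd.read_csv(directory / "meta.csv").sort_values("window_id")
    values = pd.read_csv(directory / "values.csv")
    channels = [c for c in values.columns if c.startswith("ch")]
    grouped = dict(iter(values.groupby("window_id")))
    out = []
    for row in meta.itertuples(index=False):
        grp = grouped[row.window_id].sort_values("k")
        out.append(SensorWindow(grp[channels].to_numpy(dtype=np.float64),
                                int(row.activity), int(row.person), int(row.t)))
    return out


def windows_to_arrays(windows: list[SensorWindow]):
    """Stack windows into ``(X, y_act, y_pers, t)`` arrays; X is (N, W, C)."""
    x = np.stack([w.values for w in windows])
    y_act = np.array([w.activity for w in windows], dtype=np.int64)
    y_pers = np.array([w.person for w in windows], dtype=np.int64)
    t = np.array([w.t for w in windows], dtype=np.int64)
    return x, y_act, y_pers, t
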