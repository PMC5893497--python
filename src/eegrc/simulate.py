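"""Synthetic multichannel EEG with known autoregressive structure.

Each channel of a simulated session is one realization of a stable AR
process x(n) = -sum a_k x(n-k) + u(n) driven by white Gaussian noise, with
the class identity encoded in the per-channel dynamics.  Class models are
specified in reflection-coefficient space and converted to AR coefficients
by the step-up recursion, which guarantees stability by construction.  An
optional additive 60 Hz sinusoid emulates power-line interference.

This is deliberately not physiological EEG — no 1/f background, no evoked
activity, no within-session nonstationarity.  Its purpose is to give every
pipeline stage (notch, normalization, framing, ACF, Levinson-Durbin,
band power, LOOCV) inputs whose correct answers are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .io_preprocess import DEFAULT_HEMISPHERES, Recording
from .reflection import ARSpec, reflection_to_ar

__all__ = [
    "ClassModel",
    "DEFAULT_CHANNELS",
    "simulate_ar_process",
    "simulate_recording",
    "make_two_class_dataset",
]

DEFAULT_CHANNELS = ("C3", "P3", "O1", "C4", "P4", "O2")

#: samples generated and discarded before retaining output, so that the
#: zero-initial-condition transient never reaches the returned signal
BURN_IN = 1000


@dataclass(frozen=True)
class ClassModel:
    """Generative model of one mental-task class.

    ``channel_specs`` maps each channel label to a stable :class:`ARSpec`;
    ``line_amp`` is the amplitude of an additive 60 Hz sinusoid applied to
    every channel (0 disables it).
    """

    label: str
    channel_specs: dict[str, ARSpec]
    line_amp: float = 0.0
    line_freq: float = 60.0

    def __post_init__(self) -> None:
        if self.line_amp < 0:
            raise ValueError("line amplitude must be nonnegative")
        for ch, spec in self.channel_specs.items():
            if not spec.is_stable():
                raise ValueError(f"channel {ch}: unstable AR spec")

    @staticmethod
    def from_reflection(
        label: str,
        k_per_channel: dict[str, "list[float]"],
        noise_var: float = 1.0,
        line_amp: float = 0.0,
    ) -> "ClassModel":
        """Build a model from per-channel reflection coefficients (step-up)."""
        specs = {ch: reflection_to_ar(k, noise_var=noise_var)
                 for ch, k in k_per_channel.items()}
        return ClassModel(label=label, channel_specs=specs, line_amp=line_amp)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.channel_specs)


def simulate_ar_process(
    spec: ARSpec,
    n_samples: int,
    seed: int | np.random.Generator,
    burn_in: int = BURN_IN,
) -> np.ndarray:
    """One realization of a stable AR process after burn-in discard.

    The recursion is run as an all-pole filter over white Gaussian noise of
    variance ``noise_var``; the first ``burn_in`` output samples are dropped
    so the returned segment is (effectively) stationary.  Deterministic for
    a fixed integer seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not spec.is_stable():
        raise ValueError("unstable AR spec")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.normal(0.0, np.sqrt(spec.noise_var), size=n_samples + burn_in)
    # x(n) + sum a_k x(n-k) = u(n)  ->  denominator polynomial [1, a_1..a_p]
    x = _sig.lfilter([1.0], np.concatenate([[1.0], spec.coeffs]), u)
    return x[burn_in:]


def simulate_recording(
    model: ClassModel,
    fs: float = 250.0,
    duration: float = 10.0,
    seed: int | np.random.Generator = 0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    subject_id: str | None = None,
    session_id: str | None = None,
) -> Recording:
    """Simulate one labelled multichannel session.

    Channels are driven by independent noise streams (no cross-channel
    correlation); a channel absent from the model falls back to white noise.
    The optional line component is added coherently to all channels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(duration * fs))
    data = np.empty((len(channels), n_samples))
    for i, ch in enumerate(channels):
        spec = model.channel_specs.get(ch, ARSpec(coeffs=[0.0]))
        data[i] = simulate_ar_process(spec, n_samples, rng)
    if model.line_amp > 0:
        t = np.arange(n_samples) / fs
        data += model.line_amp * np.sin(2 * np.pi * model.line_freq * t)
    return Recording(
        data=data,
        fs=fs,
        channel_labels=channels,
        hemisphere_map={ch: DEFAULT_HEMISPHERES.get(ch, "unknown")
                        for ch in channels},
        task_label=model.label,
        subject_id=subject_id,
        session_id=session_id,
    )


def make_two_class_dataset(
    model_a: ClassModel,
    model_b: ClassModel,
    n_sessions_per_class: int = 10,
    fs: float = 250.0,
    duration: float = 10.0,
    seed: int = 0,
) -> list[Recording]:
    """Simulate a labelled two-class session collection.

    Returns ``2 * n_sessions_per_class`` recordings with distinct session
    ids ("<label><index>"); per-session seeds are spawned deterministically
    from ``seed`` so any one session can be regenerated independently.
    """
    if n_sessions_per_class < 1:
        raise ValueError("n_sessions_per_class must be >= 1")
    if model_a.label == model_b.label:
        raise ValueError("class models must carry distinct labels")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(2 * n_sessions_per_class)
    recordings = []
    for s in range(n_sessions_per_class):
        for offset, model in ((0, model_a), (1, model_b)):
            rng = np.random.default_rng(streams[2 * s + offset])
            recordings.append(simulate_recording(
                model, fs=fs, duration=duration, seed=rng,
                session_id=f"{model.label}{s}",
            ))
    return recordings
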