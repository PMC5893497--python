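"""Band-power and asymmetry-ratio baseline features (PAR4/PAR5/PAR6).

The baselines summarise each frame by the spectral power of a set of
classical EEG bands on every electrode, plus the inter-hemispheric
asymmetry ratio

    A(i, j) = (P(i) - P(j)) / (P(i) + P(j))

for every (left electrode i, right electrode j) pair and band, bounded in
[-1, 1].  With N_b bands, l electrodes, N_i left and N_j right, the feature
dimension is N_b*N_i*N_j + N_b*l: 60 / 75 / 90 columns for PAR4 / PAR5 /
PAR6 on the six-channel montage.

Band power is the raw periodogram of the frame summed over in-band bins
(edges inclusive).  The band table follows the convention delta < 4 Hz
(lower edge at the 0.1 Hz acquisition passband), theta 4-7, alpha 8-13,
beta 14-20, gamma 24-37, plus a broadband "high" band 40-100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .io_preprocess import FrameSet, Recording
from .reflection import FeatureMatrix

__all__ = [
    "BandDefinition",
    "STANDARD_BANDS",
    "PAR_VARIANTS",
    "band_power",
    "band_powers",
    "asymmetry_ratio",
    "assemble_par_features",
    "bandpass",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [f_lo, f_hi] in Hz with 0 <= f_lo < f_hi."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges [{self.f_lo}, {self.f_hi}]")

    def validate_against(self, fs: float) -> None:
        if self.f_hi > fs / 2:
            raise ValueError(
                f"band {self.name} [{self.f_lo}, {self.f_hi}] Hz exceeds "
                f"Nyquist {fs / 2} Hz"
            )


STANDARD_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.1, 4.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 14.0, 20.0),
    "gamma": BandDefinition("gamma", 24.0, 37.0),
    "high": BandDefinition("high", 40.0, 100.0),
}

#: band sets of the three baseline feature families
PAR_VARIANTS: dict[str, tuple[str, ...]] = {
    "PAR4": ("delta", "theta", "alpha", "beta"),
    "PAR5": ("delta", "theta", "alpha", "beta", "gamma"),
    "PAR6": ("delta", "theta", "alpha", "beta", "gamma", "high"),
}


def band_power(frame: np.ndarray, band: BandDefinition, fs: float) -> float:
    """Spectral power of one frame inside a band (periodogram bin sum).

    Uses the raw (boxcar) periodogram normalised so that the bins over
    [0, fs/2] sum to the frame's mean-square power; band edges inclusive.
    """
    band.validate_against(fs)
    freqs, pxx = _periodogram(np.asarray(frame, dtype=float), fs)
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    return float(pxx[mask].sum())


def _periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    # scipy's density spectrum integrates to power; convert to per-bin power
    # so that a disjoint partition of [0, fs/2] sums to sum(x^2)/N exactly.
    n = x.shape[-1]
    freqs, pxx = _sig.periodogram(x, fs=fs, window="boxcar",
                                  detrend=False, scaling="density")
    return freqs, pxx * fs / n


def band_powers(frames: FrameSet, bands: list[BandDefinition]) -> np.ndarray:
    """Powers per (frame, band, channel): shape (n_frames, n_bands, n_channels)."""
    for band in bands:
        band.validate_against(frames.fs)
    freqs, pxx = _periodogram(frames.frames, frames.fs)
    out = np.empty((frames.n_frames, len(bands), frames.n_channels))
    for b, band in enumerate(bands):
        mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
        out[:, b, :] = pxx[..., mask].sum(axis=-1)
    return out


def asymmetry_ratio(p_i: float, p_j: float) -> float:
    """(P_i - P_j) / (P_i + P_j) for a left/right electrode pair; in [-1, 1]."""
    if p_i < 0 or p_j < 0:
        raise ValueError("band powers must be nonnegative")
    total = p_i + p_j
    if total == 0:
        raise ValueError("asymmetry ratio undefined: both band powers are zero")
    return (p_i - p_j) / total


def assemble_par_features(
    frames: FrameSet,
    variant: str = "PAR6",
    bands: dict[str, BandDefinition] | None = None,
) -> FeatureMatrix:
    """Build the PAR4/PAR5/PAR6 feature matrix for a FrameSet.

    Column order: all band powers first (band-major, channel-minor,
    "pow_<band>_<ch>"), then all asymmetry ratios (band-major,
    left-electrode-major, "asym_<band>_<chL>_<chR>").
    """
    if variant not in PAR_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {list(PAR_VARIANTS)}")
    table = dict(STANDARD_BANDS)
    if bands:
        table.update(bands)
    band_list = [table[name] for name in PAR_VARIANTS[variant]]

    left = [ch for ch in frames.channel_labels
            if frames.hemisphere_map.get(ch) == "left"]
    right = [ch for ch in frames.channel_labels
             if frames.hemisphere_map.get(ch) == "right"]
    if not left or not right:
        raise ValueError(
            f"hemisphere map must provide electrodes on both sides "
            f"(left={left}, right={right})"
        )
    ch_index = {ch: i for i, ch in enumerate(frames.channel_labels)}

    P = band_powers(frames, band_list)  # (n_frames, n_bands, n_channels)
    pow_cols, pow_blocks = [], []
    for b, band in enumerate(band_list):
        for ch in frames.channel_labels:
            pow_cols.append(f"pow_{band.name}_{ch}")
            pow_blocks.append(P[:, b, ch_index[ch]])
    asym_cols, asym_blocks = [], []
    for b, band in enumerate(band_list):
        for chl in left:
            for chr_ in right:
                pi = P[:, b, ch_index[chl]]
                pj = P[:, b, ch_index[chr_]]
                total = pi + pj
                if np.any(total == 0):
                    raise ValueError(
                        f"asymmetry ratio undefined for band {band.name}, "
                        f"pair ({chl}, {chr_}): zero total power in some frame"
                    )
                asym_cols.append(f"asym_{band.name}_{chl}_{chr_}")
                asym_blocks.append((pi - pj) / total)
    features = pd.DataFrame(
        np.column_stack(pow_blocks + asym_blocks),
        columns=pow_cols + asym_cols,
    )
    return FeatureMatrix(
        features=features,
        labels=frames.frame_labels or (None,) * frames.n_frames,
        sessions=frames.session_ids,
    )


def bandpass(rec: Recording, band: BandDefinition, order: int = 4) -> Recording:
    """Zero-phase band-limited copy of a recording.

    A Butterworth band-pass (order ``order``) applied forward-backward,
    mirroring the notch filter's zero-phase choice.  A band whose lower edge
    is (numerically) zero degrades to a low-pass.
    """
    band.validate_against(rec.fs)
    nyq = rec.fs / 2
    if band.f_lo <= 0.0 or band.f_lo < 1e-9:
        sos = _sig.butter(order, band.f_hi / nyq, btype="lowpass", output="sos")
    elif band.f_hi >= nyq:
        sos = _sig.butter(order, band.f_lo / nyq, btype="highpass", output="sos")
    else:
        sos = _sig.butter(order, [band.f_lo / nyq, band.f_hi / nyq],
                          btype="bandpass", output="sos")
    filtered = _sig.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)
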