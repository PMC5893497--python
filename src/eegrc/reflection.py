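"""Reflection-coefficient features from the autocorrelation function.

A frame of EEG is modelled as the output of a causal stable AR(p) system

    x(n) = -sum_{k=1}^{p} a_k x(n-k) + u(n),        u ~ N(0, sigma_u^2).

Rather than estimating the AR parameters a_k (which are unbounded and need a
Toeplitz solve), the feature used here is the sequence of reflection
coefficients k_1..k_p, obtained directly from the biased autocorrelation
estimate

    r_x(m) = (1/N) * sum_{n=0}^{N-1-m} x(n) x(n+m)

by the Levinson-Durbin recursion:

    k_m     = ( r_x(m) - sum_{j<m} d_j^{(m-1)} r_x(m-j) ) / E^{(m-1)}
    d_j^{(m)} = d_j^{(m-1)} - k_m d_{m-j}^{(m-1)},   d_m^{(m)} = k_m
    E^{(m)} = (1 - k_m^2) E^{(m-1)},                 E^{(0)} = r_x(0)

For a stable system every |k_m| < 1, which makes the coefficients naturally
bounded features, and raising the order from p to p+1 changes only the new
highest-order coefficient.  The d_j are forward one-step predictor weights:
at full order d_j^{(p)} = -a_j.  Two coefficients per channel are the
default feature (2l features for l channels; 12 for the six-channel montage).

Step-up (k -> a) and step-down (a -> k) conversions are exact inverses of
the recursion and double as oracles and as the simulator's stability check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preprocess import FrameSet

__all__ = [
    "ACFSequence",
    "ReflectionSet",
    "ARSpec",
    "FeatureMatrix",
    "DegenerateSignalError",
    "autocorrelation",
    "levinson_reflection",
    "ar_to_reflection",
    "reflection_to_ar",
    "reflection_to_acf",
    "theoretical_acf",
    "extract_reflection_features",
]

#: relative residual-energy floor below which a frame counts as perfectly
#: predictable and the recursion is aborted
DEGENERACY_EPS = 1e-12


class DegenerateSignalError(ValueError):
    """Raised when a frame is (numerically) perfectly predictable or all-zero."""


@dataclass(frozen=True)
class ACFSequence:
    """Biased autocorrelation lags r_x(0..m_max) of one frame.

    ``n_samples`` is the N used in the 1/N estimator; 0 marks an ACF built
    analytically rather than from data.
    """

    values: np.ndarray
    n_samples: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("ACF must be a nonempty 1-D sequence")
        object.__setattr__(self, "values", vals)

    @property
    def max_lag(self) -> int:
        return self.values.size - 1

    def __getitem__(self, m: int) -> float:
        return float(self.values[m])


@dataclass(frozen=True)
class ReflectionSet:
    """Reflection coefficients k_1..k_p with residual energies E^(0)..E^(p).

    ``predictor`` holds the final-stage forward predictor weights d_j^{(p)}
    (d_j = -a_j at full order).  For any stable, non-degenerate input
    |k_m| < 1 and E^(0) >= E^(1) >= ... >= E^(p) >= 0.
    """

    k: np.ndarray
    residual_energies: np.ndarray
    predictor: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", np.asarray(self.k, dtype=float))
        object.__setattr__(self, "residual_energies",
                           np.asarray(self.residual_energies, dtype=float))
        object.__setattr__(self, "predictor", np.asarray(self.predictor, dtype=float))

    @property
    def order(self) -> int:
        return self.k.size


@dataclass(frozen=True)
class ARSpec:
    """AR(p) system x(n) = -sum a_k x(n-k) + u(n), with u ~ N(0, noise_var).

    Note the sign convention: ``coeffs`` are the a_k on the left-hand side of
    the difference equation, so the forward predictor weights are d_j = -a_j.
    """

    coeffs: np.ndarray
    noise_var: float = 1.0

    def __post_init__(self) -> None:
        coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if coeffs.ndim != 1:
            raise ValueError("AR coefficients must be one-dimensional")
        if not self.noise_var > 0:
            raise ValueError("noise variance must be positive")
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def order(self) -> int:
        return self.coeffs.size

    def is_stable(self) -> bool:
        try:
            ar_to_reflection(self)
        except ValueError:
            return False
        return True


@dataclass(frozen=True)
class FeatureMatrix:
    """Frames x features table with column provenance and per-frame labels."""

    features: pd.DataFrame
    labels: tuple
    sessions: tuple = ()

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.features):
            raise ValueError("one label per feature row required")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "sessions", tuple(self.sessions))

    @property
    def n_frames(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.features.to_numpy()

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out["label"] = self.labels
        if self.sessions:
            out["session"] = self.sessions
        out.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = tuple(df.pop("label"))
        sessions = tuple(df.pop("session")) if "session" in df.columns else ()
        return FeatureMatrix(features=df, labels=labels, sessions=sessions)


# ---------------------------------------------------------------------------
# Estimators and conversions

def autocorrelation(frame: np.ndarray, max_lag: int) -> ACFSequence:
    """Biased autocorrelation estimate, divisor N at every lag.

    The biased (1/N) estimator keeps the ACF sequence positive semidefinite,
    which in turn guarantees |k_m| <= 1 downstream; the unbiased 1/(N-m)
    variant does not.
    """
    x = np.asarray(frame, dtype=float).ravel()
    n = x.size
    if n == 0:
        raise ValueError("empty frame")
    if not 1 <= max_lag < n:
        raise ValueError(f"max_lag must satisfy 1 <= max_lag < N={n}, got {max_lag}")
    full = np.correlate(x, x, mode="full")  # lag 0 at index n-1
    values = full[n - 1: n + max_lag] / n
    return ACFSequence(values=values, n_samples=n)


def levinson_reflection(acf: ACFSequence, order: int) -> ReflectionSet:
    """Levinson-Durbin recursion: ACF lags -> reflection coefficients.

    Produces k_1..k_order together with the residual-energy ladder
    E^(m) = (1 - k_m^2) E^(m-1) and the final-stage predictor weights.
    Raises :class:`DegenerateSignalError` when r_x(0) is zero or the
    residual energy collapses below ``DEGENERACY_EPS * r_x(0)`` (a
    perfectly predictable frame).
    """
    r = acf.values
    if order < 1:
        raise ValueError("order must be >= 1")
    if order > acf.max_lag:
        raise ValueError(f"order {order} exceeds available lags {acf.max_lag}")
    r0 = r[0]
    if r0 <= 0:
        raise DegenerateSignalError("r_x(0) <= 0: zero or invalid frame")

    k = np.empty(order)
    energies = np.empty(order + 1)
    energies[0] = r0
    d = np.empty(0)
    for m in range(1, order + 1):
        e_prev = energies[m - 1]
        if e_prev <= DEGENERACY_EPS * r0:
            raise DegenerateSignalError(
                f"residual energy collapsed at order {m - 1} "
                "(perfectly predictable frame)"
            )
        # r_x(m) - sum_j d_j^{(m-1)} r_x(m-j)
        acc = r[m] - np.dot(d, r[m - 1:0:-1]) if m > 1 else r[1]
        km = acc / e_prev
        k[m - 1] = km
        d = np.concatenate([d - km * d[::-1], [km]])
        energies[m] = (1.0 - km * km) * e_prev
    return ReflectionSet(k=k, residual_energies=energies, predictor=d)


def ar_to_reflection(spec: ARSpec) -> ReflectionSet:
    """Step-down: AR coefficients -> reflection coefficients.

    Inverts the predictor update of the recursion order by order.  Rejects
    unstable systems (any |k_m| >= 1).  Residual energies are reported for a
    unit-power normalisation E^(0) = 1 scaled so that E^(p) = noise_var,
    matching the stationary AR process the spec describes.
    """
    d = -spec.coeffs  # forward predictor weights at full order
    p = d.size
    k = np.empty(p)
    for m in range(p, 0, -1):
        km = d[-1]
        k[m - 1] = km
        if abs(km) >= 1.0:
            raise ValueError(
                f"unstable AR system: |k_{m}| = {abs(km):.6g} >= 1"
            )
        prev = d[:-1]
        d = (prev + km * prev[::-1]) / (1.0 - km * km)
    gains = 1.0 - k ** 2
    # E^(p) = noise_var for the stationary process; back out the ladder
    energies = np.empty(p + 1)
    energies[p] = spec.noise_var
    for m in range(p, 0, -1):
        energies[m - 1] = energies[m] / gains[m - 1]
    return ReflectionSet(k=k, residual_energies=energies, predictor=-spec.coeffs)


def reflection_to_ar(k, noise_var: float = 1.0) -> ARSpec:
    """Step-up: reflection coefficients -> AR coefficients (exact inverse).

    Requires all |k_m| < 1; the resulting system is stable by construction.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(np.abs(k) >= 1.0):
        raise ValueError("all reflection coefficients must satisfy |k_m| < 1")
    d = np.empty(0)
    for km in k:
        d = np.concatenate([d - km * d[::-1], [km]])
    return ARSpec(coeffs=-d, noise_var=noise_var)


def reflection_to_acf(k, r0: float = 1.0) -> ACFSequence:
    """Run the recursion forward: (r0, k_1..k_p) -> ACF lags r_x(0..p).

    Exact inverse of :func:`levinson_reflection` on its k output; handy for
    generating valid (positive-definite) ACF sequences with known answers.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if not r0 > 0:
        raise ValueError("r0 must be positive")
    if np.any(np.abs(k) >= 1.0):
        raise ValueError("all reflection coefficients must satisfy |k_m| < 1")
    r = np.empty(k.size + 1)
    r[0] = r0
    e = r0
    d = np.empty(0)
    for m, km in enumerate(k, start=1):
        acc = np.dot(d, r[m - 1:0:-1]) if m > 1 else 0.0
        r[m] = km * e + acc
        d = np.concatenate([d - km * d[::-1], [km]])
        e *= 1.0 - km * km
    return ACFSequence(values=r, n_samples=0)


def theoretical_acf(spec: ARSpec, max_lag: int) -> ACFSequence:
    """Exact stationary ACF of an AR process via the Yule-Walker relations.

    Solves the linear system r(m) + sum_k a_k r(|m-k|) = noise_var * delta(m)
    for r(0..p), then extends recursively for m > p.
    """
    a = spec.coeffs
    p = a.size
    n_unknown = p + 1
    A = np.eye(n_unknown)
    for m in range(n_unknown):
        for j, ak in enumerate(a, start=1):
            A[m, abs(m - j)] += ak
    rhs = np.zeros(n_unknown)
    rhs[0] = spec.noise_var
    r = np.linalg.solve(A, rhs)
    if max_lag > p:
        r = np.concatenate([r, np.zeros(max_lag - p)])
        for m in range(p + 1, max_lag + 1):
            r[m] = -np.dot(a, r[m - 1:m - p - 1:-1] if p > 1 else r[m - 1:m])
    return ACFSequence(values=r[:max_lag + 1], n_samples=0)


# ---------------------------------------------------------------------------
# Feature assembly

def extract_reflection_features(frames: FrameSet, n_coeffs: int = 2) -> FeatureMatrix:
    """Per-frame reflection-coefficient features, one row per frame.

    Columns are channel-major, coefficient-minor ("C3_k1", "C3_k2", "P3_k1",
    ...), giving ``n_coeffs * n_channels`` features per frame (2 x 6 = 12 for
    the default montage and order).  Only ``n_coeffs`` ACF lags are computed
    per channel, which is the whole cost of the feature.
    """
    if n_coeffs < 1:
        raise ValueError("n_coeffs must be >= 1")
    if frames.frame_len <= n_coeffs:
        raise ValueError(
            f"frame length {frames.frame_len} too short for {n_coeffs} coefficients"
        )
    columns = [f"{ch}_k{m}" for ch in frames.channel_labels
               for m in range(1, n_coeffs + 1)]
    out = np.empty((frames.n_frames, len(columns)))
    for i in range(frames.n_frames):
        for c, ch in enumerate(frames.channel_labels):
            try:
                acf = autocorrelation(frames.frames[i, c], max_lag=n_coeffs)
                rset = levinson_reflection(acf, order=n_coeffs)
            except (DegenerateSignalError, ValueError) as exc:
                raise DegenerateSignalError(
                    f"frame {i}, channel {ch}: {exc}"
                ) from exc
            out[i, c * n_coeffs:(c + 1) * n_coeffs] = rset.k
    return FeatureMatrix(
        features=pd.DataFrame(out, columns=columns),
        labels=frames.frame_labels or (None,) * frames.n_frames,
        sessions=frames.session_ids,
    )
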