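"""Ablation experiments: channel subsets, PCA, order, bands, kernels, baselines.

Each experiment runs the full pipeline (preprocess -> features -> frame-level
LOOCV with a kernel SVM) on a two-class dataset — either a synthetic pair of
:class:`~eegrc.simulate.ClassModel` s or user-supplied labelled recordings —
while sweeping one design axis:

``channels``        named electrode subsets (left / right / central /
                    parietal / occipital / all)
``pca``             number of principal components retained
``n_coeffs``        number of reflection coefficients per channel (1..6)
``bands``           band-limited input signals (delta..high, wide bands,
                    or "full" for no band limitation)
``kernels``         SVM kernel (linear / quadratic / polynomial / rbf)
``par_comparison``  proposed reflection features vs PAR4/PAR5/PAR6

Reports are plain dicts (JSON-serializable) keyed by sweep value, each entry
carrying the LOOCV accuracy in percent and the feature dimension used, and
can be rendered as a human-readable table.  Deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from .bandpower import STANDARD_BANDS, BandDefinition, assemble_par_features, bandpass
from .classify import KernelSpec, loocv_classify
from .io_preprocess import FrameSet, Recording, frame_signal, normalize, notch_filter
from .reflection import FeatureMatrix, extract_reflection_features
from .simulate import ClassModel, make_two_class_dataset

__all__ = [
    "ExperimentConfig",
    "CHANNEL_SUBSETS",
    "TASK_PAIRS",
    "run_experiment",
    "preprocess_recordings",
    "format_report",
    "load_class_model",
]

EXPERIMENT_KINDS = ("channels", "pca", "n_coeffs", "bands", "kernels",
                    "par_comparison")

#: named electrode subsets of the six-channel montage
CHANNEL_SUBSETS: dict[str, tuple[str, ...]] = {
    "left": ("C3", "P3", "O1"),
    "right": ("C4", "P4", "O2"),
    "central": ("C3", "C4"),
    "parietal": ("P3", "P4"),
    "occipital": ("O1", "O2"),
    "all": ("C3", "P3", "O1", "C4", "P4", "O2"),
}

#: the ten pairwise combinations of the five mental tasks
TASK_PAIRS = ("MC", "MB", "ML", "MR", "CB", "CL", "CR", "BL", "BR", "LR")

#: wide bands used in the band-selection experiment alongside the classics
WIDE_BANDS: dict[str, BandDefinition] = {
    "4-37": BandDefinition("4-37", 4.0, 37.0),
    "40-100": BandDefinition("40-100", 40.0, 100.0),
}

DEFAULT_SWEEPS: dict[str, tuple] = {
    "channels": tuple(CHANNEL_SUBSETS),
    "pca": (2, 3, 4, 5, 6),
    "n_coeffs": (1, 2, 3, 4, 5, 6),
    "bands": ("delta", "theta", "alpha", "beta", "gamma", "high",
              "4-37", "40-100", "full"),
    "kernels": ("linear", "quadratic", "polynomial", "rbf"),
    "par_comparison": ("proposed", "PAR4", "PAR5", "PAR6"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: a dataset source, a sweep axis, and the fixed knobs."""

    kind: str
    model_a: ClassModel | None = None
    model_b: ClassModel | None = None
    recordings: Sequence[Recording] = ()
    sweep: tuple = ()
    kernel: KernelSpec = field(default_factory=KernelSpec)
    n_sessions_per_class: int = 10
    n_coeffs: int = 2
    fs: float = 250.0
    duration: float = 10.0
    frame_duration: float = 1.0
    frame_shift: float = 0.5
    apply_notch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        sweep = tuple(self.sweep) or DEFAULT_SWEEPS[self.kind]
        if not sweep:
            raise ValueError("empty sweep")
        if self.kind == "channels":
            for name in sweep:
                if name not in CHANNEL_SUBSETS:
                    raise ValueError(f"unknown channel subset {name!r}")
        if self.kind == "n_coeffs" and any(not 1 <= int(v) <= 6 for v in sweep):
            raise ValueError("n_coeffs sweep values must lie in 1..6")
        object.__setattr__(self, "sweep", sweep)

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for side in ("model_a", "model_b"):
            if side in raw and isinstance(raw[side], dict):
                raw[side] = load_class_model(raw[side])
        if "kernel" in raw and isinstance(raw["kernel"], dict):
            raw["kernel"] = KernelSpec(**raw["kernel"])
        return ExperimentConfig(**raw)


def load_class_model(entry: dict) -> ClassModel:
    """Build a ClassModel from its YAML/dict form (per-channel k lists)."""
    return ClassModel.from_reflection(
        label=entry["label"],
        k_per_channel={str(ch): list(map(float, ks))
                       for ch, ks in entry["k"].items()},
        noise_var=float(entry.get("noise_var", 1.0)),
        line_amp=float(entry.get("line_amp", 0.0)),
    )


def _dataset(cfg: ExperimentConfig) -> list[Recording]:
    if cfg.recordings:
        return list(cfg.recordings)
    if cfg.model_a is None or cfg.model_b is None:
        raise ValueError("config needs either recordings or a pair of class models")
    return make_two_class_dataset(
        cfg.model_a, cfg.model_b,
        n_sessions_per_class=cfg.n_sessions_per_class,
        fs=cfg.fs, duration=cfg.duration, seed=cfg.seed,
    )


def preprocess_recordings(
    recordings: Sequence[Recording],
    apply_notch: bool = True,
    band: BandDefinition | None = None,
    frame_duration: float = 1.0,
    frame_shift: float = 0.5,
) -> FrameSet:
    """notch -> optional band limitation -> normalize -> frame, all sessions."""
    framesets = []
    for rec in recordings:
        if apply_notch:
            rec = notch_filter(rec)
        if band is not None:
            rec = bandpass(rec, band)
        rec = normalize(rec)
        framesets.append(frame_signal(rec, frame_duration, frame_shift))
    return FrameSet.concatenate(framesets)


def _features_and_cv(frames: FrameSet, cfg: ExperimentConfig,
                     n_coeffs: int | None = None,
                     kernel: KernelSpec | None = None):
    t0 = time.perf_counter()
    feats = extract_reflection_features(frames, n_coeffs or cfg.n_coeffs)
    extract_s = time.perf_counter() - t0
    result = loocv_classify(feats, kernel or cfg.kernel)
    return feats, result, extract_s


def run_experiment(cfg: ExperimentConfig) -> dict[str, Any]:
    """Run one configured experiment; returns a JSON-serializable report."""
    recordings = _dataset(cfg)
    report: dict[str, Any] = {
        "kind": cfg.kind,
        "kernel": cfg.kernel.kind,
        "seed": cfg.seed,
        "n_sessions": len(recordings),
        "results": {},
    }
    results = report["results"]

    if cfg.kind == "bands":
        tables = dict(STANDARD_BANDS) | WIDE_BANDS
        for name in cfg.sweep:
            band = None if name == "full" else tables[str(name)]
            frames = preprocess_recordings(
                recordings, cfg.apply_notch, band,
                cfg.frame_duration, cfg.frame_shift)
            feats, cv, extract_s = _features_and_cv(frames, cfg)
            results[str(name)] = {
                "accuracy": cv.accuracy, "n_features": feats.n_features,
                "n_frames": cv.n_frames, "extract_seconds": extract_s,
            }
        return report

    frames_all = preprocess_recordings(
        recordings, cfg.apply_notch, None, cfg.frame_duration, cfg.frame_shift)

    if cfg.kind == "channels":
        ch_idx = {ch: i for i, ch in enumerate(frames_all.channel_labels)}
        for name in cfg.sweep:
            subset = CHANNEL_SUBSETS[str(name)]
            missing = [ch for ch in subset if ch not in ch_idx]
            if missing:
                raise ValueError(f"unknown channel labels {missing}")
            idx = [ch_idx[ch] for ch in subset]
            frames = FrameSet(
                frames=frames_all.frames[:, idx, :],
                frame_duration=frames_all.frame_duration,
                frame_shift=frames_all.frame_shift,
                fs=frames_all.fs,
                channel_labels=subset,
                hemisphere_map={ch: frames_all.hemisphere_map[ch] for ch in subset},
                frame_labels=frames_all.frame_labels,
                session_ids=frames_all.session_ids,
            )
            feats, cv, extract_s = _features_and_cv(frames, cfg)
            results[str(name)] = {
                "accuracy": cv.accuracy, "n_features": feats.n_features,
                "n_frames": cv.n_frames, "extract_seconds": extract_s,
            }
    elif cfg.kind == "pca":
        from .classify import pca_reduce

        feats, cv_full, _ = _features_and_cv(frames_all, cfg)
        for n_pc in cfg.sweep:
            reduced = pca_reduce(feats, int(n_pc))
            cv = loocv_classify(reduced, cfg.kernel)
            results[f"{int(n_pc)}pcs"] = {
                "accuracy": cv.accuracy, "n_features": int(n_pc),
                "n_frames": cv.n_frames,
            }
        results["all_features"] = {
            "accuracy": cv_full.accuracy, "n_features": feats.n_features,
            "n_frames": cv_full.n_frames,
        }
    elif cfg.kind == "n_coeffs":
        for n in cfg.sweep:
            feats, cv, extract_s = _features_and_cv(frames_all, cfg, n_coeffs=int(n))
            results[f"{int(n)}cfs"] = {
                "accuracy": cv.accuracy, "n_features": feats.n_features,
                "n_frames": cv.n_frames, "extract_seconds": extract_s,
            }
    elif cfg.kind == "kernels":
        for kind in cfg.sweep:
            kernel = KernelSpec(kind=str(kind), degree=cfg.kernel.degree,
                                C=cfg.kernel.C, gamma=cfg.kernel.gamma)
            feats, cv, extract_s = _features_and_cv(frames_all, cfg, kernel=kernel)
            results[str(kind)] = {
                "accuracy": cv.accuracy, "n_features": feats.n_features,
                "n_frames": cv.n_frames,
            }
    elif cfg.kind == "par_comparison":
        for method in cfg.sweep:
            t0 = time.perf_counter()
            if method == "proposed":
                feats: FeatureMatrix = extract_reflection_features(
                    frames_all, cfg.n_coeffs)
            else:
                feats = assemble_par_features(frames_all, variant=str(method))
            extract_s = time.perf_counter() - t0
            cv = loocv_classify(feats, cfg.kernel)
            results[str(method)] = {
                "accuracy": cv.accuracy, "n_features": feats.n_features,
                "n_frames": cv.n_frames, "extract_seconds": extract_s,
            }
    return report


def format_report(report: dict[str, Any]) -> str:
    """Render a report as an aligned text table (sweep rows, metric columns)."""
    rows = report["results"]
    headers = ["sweep", "accuracy (%)", "n_features", "n_frames"]
    lines = [f"experiment: {report['kind']}   kernel: {report['kernel']}   "
             f"seed: {report['seed']}"]
    widths = [max(len(headers[0]), *(len(k) for k in rows)), 12, 10, 8]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    lines.append(fmt.format(*headers))
    for key, entry in rows.items():
        lines.append(fmt.format(
            key, f"{entry['accuracy']:.2f}", entry["n_features"],
            entry["n_frames"]))
    return "\n".join(lines)


def save_report(report: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
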