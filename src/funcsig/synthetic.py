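"""Planted-structure and null fixtures for the detection pipeline.

The grouped-oscillator generator emulates circadian-like recordings: K groups
of units oscillate around group "master" phases, with per-unit phase jitter,
an optional strong global periodic trend shared by every unit, and additive
Gaussian noise.  A pure-noise generator provides the Wishart-bulk null.

Default benchmark
-----------------
``benchmark_config(with_trend=...)`` mirrors the 3 x 100 planted-module
benchmark: 300 units, T = 500, oscillator period 100 samples (5 cycles),
master phases {0, 2pi/3, 4pi/3}, phase jitter pi/6, noise sd 0.2.  The
with-trend variant adds a global mode of amplitude 8 (unit oscillator
amplitude) and period 108 — a strong common rhythm slightly detuned from the
cellular period, as in tissue where the ensemble rhythm and cell-autonomous
periods differ.  Under this trend every pairwise correlation is positive and
the group-contrast eigenvalues drop *below* the uncorrected Wishart edge, so
only the global-mode-corrected null recovers them; an independent-entry
signed-modularity null merges planted groups here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .timeseries import ActivityRecording, save_recording

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the grouped-oscillator generator.

    ``phase_spread`` is the full width (radians) of the uniform per-unit
    phase jitter around each group's master phase.  ``trend_amplitude`` is a
    multiple of the unit oscillator amplitude; 0 disables the global trend.
    """

    n_groups: int = 3
    group_sizes: tuple[int, ...] = (100, 100, 100)
    n_timepoints: int = 500
    base_period: float = 100.0
    phase_spread: float = np.pi / 6
    group_phase_offsets: tuple[float, ...] = (0.0, TWO_PI / 3, 2 * TWO_PI / 3)
    trend_amplitude: float = 0.0
    trend_period: float = 108.0
    noise_sd: float = 0.2
    seed: int = 0
    waveform: Callable[[np.ndarray], np.ndarray] = field(default=np.sin, repr=False)

    @property
    def n_units(self) -> int:
        return int(sum(self.group_sizes))

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if len(self.group_sizes) != self.n_groups:
            raise ConfigurationError(
                f"group_sizes has length {len(self.group_sizes)}, expected {self.n_groups}"
            )
        if any(int(s) != s or s < 1 for s in self.group_sizes):
            raise ConfigurationError("group_sizes must be positive integers")
        if len(self.group_phase_offsets) != self.n_groups:
            raise ConfigurationError("group_phase_offsets must match n_groups")
        if self.n_timepoints < 3:
            raise ConfigurationError("n_timepoints must be >= 3")
        if self.base_period <= 0 or self.trend_period <= 0:
            raise ConfigurationError("periods must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.trend_amplitude < 0:
            raise ConfigurationError("trend_amplitude must be >= 0")
        if self.phase_spread < 0:
            raise ConfigurationError("phase_spread must be >= 0")
        if self.n_timepoints <= self.n_units:
            warnings.warn(
                f"T={self.n_timepoints} <= N={self.n_units}: Q = T/N <= 1 makes the "
                "correlation matrix rank deficient; the Wishart null still applies "
                "but T > N is recommended",
                stacklevel=3,
            )

    def to_json(self, path: str | Path) -> None:
        d = {
            k: v for k, v in self.__dict__.items() if k != "waveform"
        }
        d["group_sizes"] = list(self.group_sizes)
        d["group_phase_offsets"] = list(self.group_phase_offsets)
        d["waveform"] = getattr(self.waveform, "__name__", "custom")
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


@dataclass
class GroundTruth:
    """Planted labels for a synthetic recording.

    ``sub_labels`` is populated only by :func:`generate_nested_groups`.
    """

    labels: np.ndarray
    master_phases: np.ndarray
    config: SyntheticConfig
    sub_labels: np.ndarray | None = None

    def save(self, path: str | Path, unit_ids: list[str] | None = None) -> None:
        n = len(self.labels)
        ids = unit_ids if unit_ids is not None else [f"u{i:04d}" for i in range(n)]
        df = pd.DataFrame({"unit_id": ids, "group_id": self.labels})
        if self.sub_labels is not None:
            df["subgroup_id"] = self.sub_labels
        df.to_csv(path, sep="\t", index=False)


def benchmark_config(with_trend: bool = False, seed: int = 0, **overrides) -> SyntheticConfig:
    """The default 3 x 100 planted-module benchmark (see module docstring)."""
    cfg = SyntheticConfig(trend_amplitude=8.0 if with_trend else 0.0, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def _render(
    config: SyntheticConfig, unit_phases: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Waveform + global trend + noise for given per-unit phases."""
    t = np.arange(config.n_timepoints, dtype=float)
    phase_t = TWO_PI * t / config.base_period
    values = config.waveform(phase_t[None, :] + unit_phases[:, None])
    if config.trend_amplitude > 0:
        trend = config.waveform(TWO_PI * t / config.trend_period)
        values = values + config.trend_amplitude * trend[None, :]
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    return values


def _as_recording(config: SyntheticConfig, values: np.ndarray) -> ActivityRecording:
    n = values.shape[0]
    return ActivityRecording(
        values=values,
        unit_ids=[f"u{i:04d}" for i in range(n)],
        time_stamps=np.arange(config.n_timepoints, dtype=float),
        sampling_interval=1.0,
    )


def generate_grouped_oscillators(
    config: SyntheticConfig,
) -> tuple[ActivityRecording, GroundTruth]:
    """Generate K groups of phase-shifted oscillators around master phases.

    Unit *i* in group *g* follows
    ``waveform(2*pi*t/base_period + phi_g + eps_i)
    + trend_amplitude * waveform(2*pi*t/trend_period) + noise`` with
    ``eps_i ~ Uniform(-phase_spread/2, +phase_spread/2)``.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = np.repeat(np.arange(config.n_groups), config.group_sizes)
    jitter = rng.uniform(-config.phase_spread / 2, config.phase_spread / 2, size=config.n_units)
    phases = np.asarray(config.group_phase_offsets, dtype=float)[labels] + jitter
    values = _render(config, phases, rng)
    gt = GroundTruth(
        labels=labels,
        master_phases=np.asarray(config.group_phase_offsets, dtype=float),
        config=config,
    )
    return _as_recording(config, values), gt


def generate_pure_noise(n_units: int, n_timepoints: int, seed: int = 0) -> ActivityRecording:
    """I.i.d. standard-Gaussian recording: the Wishart-bulk null fixture."""
    if n_units < 2 or n_timepoints < 3:
        raise ConfigurationError("need n_units >= 2 and n_timepoints >= 3")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_units, n_timepoints))
    cfg = SyntheticConfig(
        n_groups=1, group_sizes=(n_units,), n_timepoints=n_timepoints,
        group_phase_offsets=(0.0,), seed=seed,
    )
    return _as_recording(cfg, values)


def generate_nested_groups(
    config: SyntheticConfig, sub_phase_spread: float
) -> tuple[ActivityRecording, GroundTruth]:
    """Two-level hierarchy: each top group splits into two phase sub-groups.

    Sub-group masters sit at ``phi_g +/- sub_phase_spread/2``; units jitter
    around their sub-master by ``config.phase_spread`` as usual.  The
    sub-level offset must be smaller than every between-group master offset,
    so the top-level contrast dominates.  ``sub_phase_spread=0`` degenerates
    to :func:`generate_grouped_oscillators`.
    """
    config.validate()
    if sub_phase_spread < 0:
        raise ConfigurationError("sub_phase_spread must be >= 0")
    offsets = np.asarray(config.group_phase_offsets, dtype=float)
    if config.n_groups > 1:
        diffs = []
        for a in range(config.n_groups):
            for b in range(a + 1, config.n_groups):
                d = np.abs(np.angle(np.exp(1j * (offsets[a] - offsets[b]))))
                diffs.append(d)
        if sub_phase_spread >= min(diffs):
            raise ConfigurationError(
                "sub_phase_spread must be smaller than the smallest between-group "
                f"phase offset ({min(diffs):.3f} rad)"
            )
    rng = np.random.default_rng(config.seed)
    labels = np.repeat(np.arange(config.n_groups), config.group_sizes)
    sub_labels = np.empty_like(labels)
    phases = np.empty(config.n_units, dtype=float)
    start = 0
    for g, size in enumerate(config.group_sizes):
        half = size // 2
        side = np.zeros(size, dtype=int)
        side[half:] = 1
        sub_labels[start : start + size] = 2 * g + side
        phases[start : start + size] = offsets[g] + (side - 0.5) * sub_phase_spread
        start += size
    phases += rng.uniform(-config.phase_spread / 2, config.phase_spread / 2, config.n_units)
    values = _render(config, phases, rng)
    gt = GroundTruth(
        labels=labels, master_phases=offsets, config=config, sub_labels=sub_labels
    )
    return _as_recording(config, values), gt


def write_fixture(
    config: SyntheticConfig, out_dir: str | Path, *, nested_sub_phase_spread: float | None = None
) -> tuple[Path, Path, Path]:
    """Write recording, ground truth and config to ``out_dir``; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if nested_sub_phase_spread is None:
        rec, gt = generate_grouped_oscillators(config)
    else:
        rec, gt = generate_nested_groups(config, nested_sub_phase_spread)
    rec_path = out / "recording.csv"
    gt_path = out / "ground_truth.tsv"
    cfg_path = out / "config.json"
    save_recording(rec, rec_path)
    gt.save(gt_path, unit_ids=rec.unit_ids)
    config.to_json(cfg_path)
    return rec_path, gt_path, cfg_path
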