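"""Functional-signature statistics of a detected partition.

The *functional signature* is the partition plus the statistics of the
residual correlations — the entries of the filtered matrix ``C_filtered``,
i.e. the dependencies that survive noise- and trend-filtering.  Per module:
the mean residual correlation and the contrast ratio
``delta = N- / N+`` (count of negative over positive residual entries inside
the module — 0 for a perfectly sign-pure module); per module pair: the mean
residual correlation and ``delta = N+ / N-``.  Community mean signals and
global-subtracted residual signals summarize the temporal side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import Partition
from .errors import InputError
from .rmt import FilteredDecomposition
from .timeseries import ActivityRecording


@dataclass
class ModuleSignature:
    module: int
    size: int
    mean_residual: float  # C-bar of the module; NaN for singletons
    n_positive: int
    n_negative: int
    contrast_ratio: float  # N-/N+; inf when N+ = 0 (flagged), NaN for singletons
    undefined: bool  # singleton module: within statistics do not exist


@dataclass
class PairSignature:
    module_a: int
    module_b: int
    mean_residual: float
    n_positive: int
    n_negative: int
    contrast_ratio: float  # N+/N-; inf when N- = 0 (flagged)


@dataclass
class SignatureReport:
    """Within/between residual-correlation statistics of a partition."""

    modules: list[ModuleSignature]
    pairs: list[PairSignature]
    within_values: dict[int, np.ndarray]
    between_values: dict[tuple[int, int], np.ndarray]

    def modules_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.modules])

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])

    def save(self, path: str | Path) -> None:
        payload = {
            "modules": [
                {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in vars(m).items()}
                for m in self.modules
            ],
            "pairs": [
                {k: ("inf" if isinstance(v, float) and np.isinf(v) else v)
                 for k, v in vars(p).items()}
                for p in self.pairs
            ],
        }
        for m in payload["modules"]:
            if isinstance(m.get("contrast_ratio"), float) and np.isinf(m["contrast_ratio"]):
                m["contrast_ratio"] = "inf"
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class CommunitySignals:
    """Per-module mean (or residual) time series plus the global signal."""

    module_signals: np.ndarray  # (n_modules, T)
    global_signal: np.ndarray  # (T,)
    module_sizes: np.ndarray


def empirical_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted sample points and cumulative probabilities."""
    x = np.sort(np.asarray(values, dtype=float))
    return x, np.arange(1, len(x) + 1) / len(x)


def _ratio(num: int, den: int) -> float:
    if den == 0:
        return np.inf if num > 0 else np.nan
    return num / den


def signature_stats(filt: FilteredDecomposition, p: Partition) -> SignatureReport:
    """Within/between statistics of the filtered (residual) correlations.

    The within-module and between-pair entry multisets together partition
    the off-diagonal entries of ``C_filtered``.  Singleton modules have no
    within entries and are flagged ``undefined``.
    """
    b = filt.c_filtered
    n = b.shape[0]
    if len(p.labels) != n:
        raise InputError("partition does not match filtered matrix")
    modules: list[ModuleSignature] = []
    within_values: dict[int, np.ndarray] = {}
    for m in range(p.n_modules):
        members = p.module_members(m)
        size = len(members)
        if size < 2:
            modules.append(
                ModuleSignature(m, size, np.nan, 0, 0, np.nan, undefined=True)
            )
            within_values[m] = np.array([])
            continue
        block = b[np.ix_(members, members)]
        vals = block[~np.eye(size, dtype=bool)]
        n_pos = int((vals > 0).sum())
        n_neg = int((vals < 0).sum())
        modules.append(
            ModuleSignature(
                module=m,
                size=size,
                mean_residual=float(vals.mean()),
                n_positive=n_pos,
                n_negative=n_neg,
                contrast_ratio=_ratio(n_neg, n_pos),
                undefined=False,
            )
        )
        within_values[m] = vals
    pairs: list[PairSignature] = []
    between_values: dict[tuple[int, int], np.ndarray] = {}
    for a in range(p.n_modules):
        for c in range(a + 1, p.n_modules):
            vals = b[np.ix_(p.module_members(a), p.module_members(c))].ravel()
            n_pos = int((vals > 0).sum())
            n_neg = int((vals < 0).sum())
            pairs.append(
                PairSignature(
                    module_a=a,
                    module_b=c,
                    mean_residual=float(vals.mean()),
                    n_positive=n_pos,
                    n_negative=n_neg,
                    contrast_ratio=_ratio(n_pos, n_neg),
                )
            )
            between_values[(a, c)] = vals
    return SignatureReport(modules, pairs, within_values, between_values)


def community_signals(rec: ActivityRecording, p: Partition) -> CommunitySignals:
    """Arithmetic mean series per module, plus the whole-system mean."""
    if len(p.labels) != rec.n_units:
        raise InputError("partition does not match recording")
    sizes = np.bincount(p.labels, minlength=p.n_modules)
    sigs = np.stack(
        [rec.values[p.labels == m].mean(axis=0) for m in range(p.n_modules)]
    )
    return CommunitySignals(
        module_signals=sigs,
        global_signal=rec.values.mean(axis=0),
        module_sizes=sizes,
    )


def residual_signals(rec: ActivityRecording, p: Partition) -> CommunitySignals:
    """Module mean signals after global-signal subtraction.

    Each unit series is standardized (so bright units do not dominate), the
    mean standardized series of the whole system is subtracted, and module
    means are taken.  The size-weighted sum of the module residuals is the
    zero series by construction.
    """
    if len(p.labels) != rec.n_units:
        raise InputError("partition does not match recording")
    sd = rec.values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise InputError("zero-variance unit; run QC first")
    z = (rec.values - rec.values.mean(axis=1, keepdims=True)) / sd
    global_sig = z.mean(axis=0)
    sizes = np.bincount(p.labels, minlength=p.n_modules)
    sigs = np.stack(
        [z[p.labels == m].mean(axis=0) - global_sig for m in range(p.n_modules)]
    )
    return CommunitySignals(
        module_signals=sigs, global_signal=global_sig, module_sizes=sizes
    )


def save_signals(
    sig: CommunitySignals, time_stamps: np.ndarray, path: str | Path
) -> None:
    df = pd.DataFrame(
        sig.module_signals.T,
        index=time_stamps,
        columns=[f"module_{m}" for m in range(sig.module_signals.shape[0])],
    )
    df["global"] = sig.global_signal
    df.index.name = "time_h"
    df.to_csv(path, float_format="%.12g")
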