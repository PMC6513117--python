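"""End-to-end detection: correlation -> null-model filtering -> modules."""

from __future__ import annotations

from dataclasses import dataclass

from .detect import ModularityMatrix, Partition, optimize_partition
from .rmt import (
    FilteredDecomposition,
    RMTBounds,
    SpectralDecomposition,
    filter_correlation,
)
from .timeseries import ActivityRecording, CorrelationMatrix, pearson_correlation


@dataclass
class DetectionResult:
    """Everything the pipeline computed, stage by stage."""

    recording: ActivityRecording
    correlation: CorrelationMatrix
    decomposition: SpectralDecomposition
    bounds: RMTBounds
    filtered: FilteredDecomposition
    modularity_matrix: ModularityMatrix
    partition: Partition


def detect_modules(
    rec: ActivityRecording,
    *,
    mode: str = "auto",
    seed: int = 0,
    n_restarts: int = 100,
) -> DetectionResult:
    """Run the full threshold-free pipeline on a recording.

    Computes the Pearson correlation matrix, filters it against the
    (optionally global-mode-corrected) Wishart null, and optimizes the
    correlation-matrix modularity on the structural component.  When no
    eigenvalue deviates from the null the partition is a single module with
    ``significant=False``.
    """
    c = pearson_correlation(rec)
    filt, bounds, spec = filter_correlation(c, mode=mode)
    b = ModularityMatrix.from_filtered(filt, c)
    p = optimize_partition(b, seed=seed, n_restarts=n_restarts)
    return DetectionResult(
        recording=rec,
        correlation=c,
        decomposition=spec,
        bounds=bounds,
        filtered=filt,
        modularity_matrix=b,
        partition=p,
    )
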