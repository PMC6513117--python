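"""Global-mode-corrected Wishart null model and spectral filtering.

The null model for an ``N x T`` recording with no modular structure is a
Wishart (Marchenko-Pastur) random bulk, rescaled for the empirical global
mode.  Writing ``Q = T/N`` and ``lambda_max`` for the largest empirical
eigenvalue, the corrected bulk edges are::

    lambda_pm = (1 - lambda_max/N) * (1 +/- 1/sqrt(Q))**2

The higher the global mode, the further the bulk is left-shifted: a strong
common trend *lowers* the noise ceiling ``lambda_plus``, unveiling weak
structural eigenvalues that a plain Wishart bound would classify as noise.
Empirical eigenvalues strictly inside ``(lambda_plus, lambda_max)`` are the
structural set; the correlation matrix reconstructed from them alone is the
filtered matrix handed to module detection.

The global mode is a property of the data, not an assumption: it is declared
present only when the leading eigenvector is sign-uniform (a common trend
loads every unit with the same sign) and its eigenvalue exceeds the plain
Wishart edge.  Recordings without a common trend — including the pure-noise
null — are compared against the uncorrected bulk, with no eigenvalue removed
as global.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json
import warnings

import numpy as np
import pandas as pd

from .errors import InputError
from .timeseries import CorrelationMatrix

_BOUNDARY_TOL = 1e-12


@dataclass
class SpectralDecomposition:
    """Full eigensystem of a correlation matrix, eigenvalues descending.

    Eigenvector signs follow a deterministic convention (largest-magnitude
    component positive) so serialized outputs are bit-stable across runs.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # column k pairs with eigenvalues[k]
    source: CorrelationMatrix

    @property
    def n(self) -> int:
        return len(self.eigenvalues)


@dataclass
class RMTBounds:
    """Null-model bulk edges for an (N, T) correlation spectrum."""

    lambda_minus: float
    lambda_plus: float
    lambda_max: float
    q: float
    n_units: int
    n_timepoints: int
    corrected: bool

    def to_dict(self) -> dict:
        return {
            "lambda_minus": self.lambda_minus,
            "lambda_plus": self.lambda_plus,
            "lambda_max": self.lambda_max,
            "q": self.q,
            "n_units": self.n_units,
            "n_timepoints": self.n_timepoints,
            "corrected": self.corrected,
        }


@dataclass
class EigenvalueClassification:
    """Disjoint index sets partitioning the spectrum."""

    global_indices: np.ndarray
    structural_indices: np.ndarray
    random_indices: np.ndarray

    @property
    def has_structure(self) -> bool:
        return self.structural_indices.size > 0

    def to_dict(self) -> dict:
        return {
            "global_indices": self.global_indices.tolist(),
            "structural_indices": self.structural_indices.tolist(),
            "random_indices": self.random_indices.tolist(),
        }


@dataclass
class FilteredDecomposition:
    """Structural / global / random eigencomponents of a correlation matrix.

    ``c_filtered + c_global + c_random`` reconstructs the original matrix.
    """

    c_filtered: np.ndarray
    c_global: np.ndarray
    c_random: np.ndarray
    classification: EigenvalueClassification

    @property
    def has_structure(self) -> bool:
        return self.classification.has_structure


def decompose(c: CorrelationMatrix) -> SpectralDecomposition:
    """Symmetric eigendecomposition with deterministic eigenvector signs."""
    m = np.asarray(c.values, dtype=float)
    if np.max(np.abs(m - m.T)) > 1e-8:
        raise InputError("matrix is not symmetric within 1e-8")
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    flip = v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])] < 0
    v[:, flip] *= -1.0
    return SpectralDecomposition(eigenvalues=w, eigenvectors=v, source=c)


def wishart_bounds(n_units: int, n_timepoints: int) -> RMTBounds:
    """Plain Marchenko-Pastur bulk edges ``(1 +/- 1/sqrt(Q))**2``, Q = T/N."""
    if n_units <= 0 or n_timepoints <= 0:
        raise InputError("n_units and n_timepoints must be positive")
    q = n_timepoints / n_units
    lam_plus = (1.0 + 1.0 / np.sqrt(q)) ** 2
    lam_minus = (1.0 - 1.0 / np.sqrt(q)) ** 2
    if n_timepoints <= n_units:
        warnings.warn(
            f"T={n_timepoints} <= N={n_units}: correlation matrix is rank "
            "deficient; lambda_minus floored at 0",
            stacklevel=2,
        )
        lam_minus = 0.0
    return RMTBounds(
        lambda_minus=float(lam_minus),
        lambda_plus=float(lam_plus),
        lambda_max=0.0,
        q=q,
        n_units=n_units,
        n_timepoints=n_timepoints,
        corrected=False,
    )


def corrected_bounds(n_units: int, n_timepoints: int, lambda_max: float) -> RMTBounds:
    """Global-mode-corrected edges ``(1 - lambda_max/N) * (1 +/- 1/sqrt(Q))**2``.

    ``lambda_plus`` is affine and strictly decreasing in ``lambda_max``: the
    stronger the global mode, the lower the noise ceiling.  ``lambda_max``
    must be below N (a single mode cannot carry more than the total variance).
    """
    if lambda_max < 0:
        raise InputError("lambda_max must be >= 0")
    if lambda_max >= n_units:
        raise InputError(
            f"lambda_max={lambda_max} >= N={n_units}: the global mode cannot "
            "exceed the total variance"
        )
    base = wishart_bounds(n_units, n_timepoints)
    shift = 1.0 - lambda_max / n_units
    return RMTBounds(
        lambda_minus=float(base.lambda_minus * shift),
        lambda_plus=float(base.lambda_plus * shift),
        lambda_max=float(lambda_max),
        q=base.q,
        n_units=n_units,
        n_timepoints=n_timepoints,
        corrected=True,
    )


def null_density(bounds: RMTBounds, lam: float | np.ndarray) -> float | np.ndarray:
    """Null eigenvalue density at ``lam``.

    The bulk is the Marchenko-Pastur density dilated by
    ``m = 1 - lambda_max/N`` (the unique density consistent with the
    corrected edges and trace conservation)::

        rho(lam) = Q * sqrt((lam_plus - lam)(lam - lam_minus)) / (2 pi lam m)

    on ``[lambda_minus, lambda_plus]`` and 0 outside.  The global mode's
    point mass of weight 1/N at ``lambda_max`` is not part of the returned
    bulk density; it is reported separately by the classification.
    """
    lam_arr = np.asarray(lam, dtype=float)
    m = 1.0 - bounds.lambda_max / bounds.n_units if bounds.corrected else 1.0
    out = np.zeros_like(lam_arr)
    inside = (lam_arr > max(bounds.lambda_minus, 0.0)) & (lam_arr < bounds.lambda_plus)
    li = lam_arr[inside]
    out[inside] = (
        bounds.q
        * np.sqrt((bounds.lambda_plus - li) * (li - bounds.lambda_minus))
        / (2.0 * np.pi * li * m)
    )
    return out if np.ndim(lam) else float(out)


def has_global_mode(
    spec: SpectralDecomposition,
    *,
    sign_fraction: float = 0.9,
) -> bool:
    """Whether the leading eigenvector is a system-wide common mode.

    A global trend loads every unit with the same sign; the leading
    eigenvector of a trend-dominated correlation matrix is therefore
    sign-uniform (Perron-Frobenius when all correlations are positive),
    whereas leading eigenvectors of noise or of balanced group contrasts
    have mixed signs.  Requires additionally that ``lambda_max`` exceeds the
    plain Wishart edge, so noise alone never declares a global mode.
    """
    c = spec.source
    v1 = spec.eigenvectors[:, 0]
    nz = v1[v1 != 0]
    if nz.size == 0:
        return False
    frac = max(np.mean(nz > 0), np.mean(nz < 0))
    edge = wishart_bounds(c.n_units, c.n_timepoints).lambda_plus
    return bool(frac >= sign_fraction and spec.eigenvalues[0] > edge)


def classify_eigenvalues(
    spec: SpectralDecomposition, bounds: RMTBounds
) -> EigenvalueClassification:
    """Partition the spectrum into global / structural / random sets.

    With corrected bounds the largest eigenvalue is the global mode and the
    structural set is the open interval ``(lambda_plus, lambda_max)``; with
    uncorrected bounds there is no global mode and every eigenvalue above
    ``lambda_plus`` is structural.  Eigenvalues equal to a boundary within
    1e-12 are classified random.
    """
    w = spec.eigenvalues
    n = len(w)
    idx = np.arange(n)
    if bounds.corrected:
        global_idx = np.array([0], dtype=int)
        structural = idx[
            (idx > 0)
            & (w > bounds.lambda_plus + _BOUNDARY_TOL)
            & (w < w[0] - _BOUNDARY_TOL)
        ]
    else:
        global_idx = np.array([], dtype=int)
        structural = idx[w > bounds.lambda_plus + _BOUNDARY_TOL]
    mask = np.ones(n, dtype=bool)
    mask[global_idx] = False
    mask[structural] = False
    return EigenvalueClassification(
        global_indices=global_idx,
        structural_indices=structural,
        random_indices=idx[mask],
    )


def _component(spec: SpectralDecomposition, indices: np.ndarray) -> np.ndarray:
    if indices.size == 0:
        return np.zeros((spec.n, spec.n))
    v = spec.eigenvectors[:, indices]
    return (v * spec.eigenvalues[indices]) @ v.T


def filter_matrix(
    spec: SpectralDecomposition, cls: EigenvalueClassification
) -> FilteredDecomposition:
    """Reconstruct the structural, global and random eigencomponents."""
    return FilteredDecomposition(
        c_filtered=_component(spec, cls.structural_indices),
        c_global=_component(spec, cls.global_indices),
        c_random=_component(spec, cls.random_indices),
        classification=cls,
    )


def filter_correlation(
    c: CorrelationMatrix, mode: str = "auto"
) -> tuple[FilteredDecomposition, RMTBounds, SpectralDecomposition]:
    """Full null-model filtering of a correlation matrix.

    ``mode`` selects the null variant: ``"corrected"`` forces the
    global-mode-corrected bounds, ``"uncorrected"`` the plain Wishart bulk,
    and ``"auto"`` (default) applies the correction exactly when
    :func:`has_global_mode` detects a common trend.
    """
    if mode not in {"auto", "corrected", "uncorrected"}:
        raise InputError(f"unknown null-model mode {mode!r}")
    spec = decompose(c)
    use_corrected = mode == "corrected" or (mode == "auto" and has_global_mode(spec))
    if use_corrected:
        bounds = corrected_bounds(c.n_units, c.n_timepoints, float(spec.eigenvalues[0]))
    else:
        bounds = wishart_bounds(c.n_units, c.n_timepoints)
    cls = classify_eigenvalues(spec, bounds)
    return filter_matrix(spec, cls), bounds, spec


def save_spectrum_report(
    spec: SpectralDecomposition,
    bounds: RMTBounds,
    filt: FilteredDecomposition,
    out_dir: str | Path,
) -> None:
    """Serialize eigenvalues, classification, bounds and the filtered matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"eigenvalue": spec.eigenvalues}).to_csv(
        out / "eigenvalues.csv", index_label="rank", float_format="%.12g"
    )
    (out / "classification.json").write_text(
        json.dumps(filt.classification.to_dict(), indent=2, sort_keys=True)
    )
    (out / "bounds.json").write_text(json.dumps(bounds.to_dict(), indent=2, sort_keys=True))
    pd.DataFrame(
        filt.c_filtered, index=spec.source.unit_ids, columns=spec.source.unit_ids
    ).to_csv(out / "filtered_matrix.csv", index_label="unit_id", float_format="%.12g")
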