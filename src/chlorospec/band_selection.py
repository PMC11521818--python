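"""Chlorophyll-sensitive wavelength selection and collinearity screening.

Two complementary lines of evidence identify informative bands: principal
component analysis of the standardized reflectance matrix with a Varimax
rotation of the retained loadings (interior extrema of the first rotated
component mark bands that move most with pigment variation), and a relative
standard-deviation profile of reflectance within chlorophyll groups (the
profile peaks near the 670 nm chlorophyll absorption for high-chlorophyll
leaves).  The multicollinearity screen computes per-feature variance
inflation factors on the index table; VIF > 5 or tolerance < 0.1 flags a
feature as collinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .errors import DecompositionError, GroupingError, InputError, SelectionError
from .indices import FeatureTable
from .synthetic import SpectraSet

__all__ = [
    "LoadingsMatrix",
    "SDProfile",
    "WavelengthSet",
    "CollinearityReport",
    "pca_varimax",
    "sd_profile",
    "pick_wavelengths",
    "collinearity",
    "VIF_THRESHOLD",
    "TOLERANCE_THRESHOLD",
]

VIF_THRESHOLD = 5.0
TOLERANCE_THRESHOLD = 0.1


@dataclass
class LoadingsMatrix:
    """Rotated loadings: wavelengths x components, plus explained variance."""

    wavelengths: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    @property
    def components(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(
            self.loadings, columns=[f"component_{k + 1}" for k in range(self.components)]
        )
        frame.insert(0, "wavelength_nm", self.wavelengths)
        frame.to_csv(path, index=False, encoding="utf-8")


@dataclass
class SDProfile:
    """Per-wavelength relative SD (SD/mean) within chlorophyll groups."""

    wavelengths: np.ndarray
    group_bounds: list[tuple[float, float]]
    relative_sd: np.ndarray  # wavelengths x groups

    def peak_wavelength(self, group: int = -1) -> float:
        return float(self.wavelengths[int(np.argmax(self.relative_sd[:, group]))])


@dataclass
class WavelengthSet:
    """Selected loading-extremum wavelengths for index construction."""

    maxima: list[float]
    minima: list[float]

    def to_dict(self) -> dict:
        return {"maxima_nm": list(self.maxima), "minima_nm": list(self.minima)}


@dataclass
class CollinearityReport:
    """Tolerance/VIF diagnostics per feature; flag = collinearity suspected."""

    feature_names: list[str]
    tolerance: np.ndarray
    vif: np.ndarray
    flags: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "tolerance": self.tolerance,
                "vif": self.vif,
                "flagged": self.flags,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")


def _kaiser_varimax(loadings: np.ndarray, tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Varimax rotation with Kaiser row normalization."""
    h = np.sqrt((loadings**2).sum(axis=1))
    safe = np.where(h > 0, h, 1.0)
    rotated, _ = rotate_factors(loadings / safe[:, None], "varimax", tol, max_iter)
    return rotated * safe[:, None]


def pca_varimax(
    reflectance_matrix: np.ndarray,
    wavelengths: np.ndarray,
    retain: int | str = "kaiser",
) -> LoadingsMatrix:
    """Standardized PCA followed by a Kaiser-normalized Varimax rotation.

    Parameters
    ----------
    reflectance_matrix : ndarray, samples x wavelengths
    retain : "kaiser" or int
        Component retention rule: eigenvalue > 1 on the correlation matrix,
        or a forced component count.

    Returns the rotated loadings ordered by post-rotation explained variance
    (sum of squared loadings), each component signed so its largest-magnitude
    loading is positive.  An orthogonal rotation preserves per-wavelength
    communalities and total explained variance.
    """
    X = np.asarray(reflectance_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InputError("need at least 2 samples and 2 wavelengths")
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != X.shape[1]:
        raise InputError("wavelength grid does not match matrix columns")

    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DecompositionError("zero-variance wavelength column; cannot standardize")
    Z = (X - X.mean(axis=0)) / sd

    # Eigen-decomposition of the correlation matrix via SVD of Z.
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    if not np.isfinite(eigvals).all():
        raise DecompositionError("degenerate reflectance matrix")

    if retain == "kaiser":
        k = max(1, int((eigvals > 1.0).sum()))
    else:
        k = int(retain)
        if k < 1 or k > eigvals.size:
            raise InputError(f"cannot retain {k} components")

    loadings = Vt[:k].T * np.sqrt(eigvals[:k])
    if k > 1:
        loadings = _kaiser_varimax(loadings)

    ss = (loadings**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    loadings = loadings[:, order]
    ss = ss[order]
    # Sign convention: dominant loading of each component is positive.
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]

    return LoadingsMatrix(wavelengths=wavelengths, loadings=loadings, explained_variance=ss)


def sd_profile(spectra: SpectraSet, group_bounds: list[tuple[float, float]]) -> SDProfile:
    """Relative SD of reflectance per wavelength within chlorophyll groups.

    The default grouping used in reports follows the nested intervals
    (750-1500, 750-2500, 750-3500 ug/g); nested bounds simply mean the wider
    group is computed over the union sample set.
    """
    if not group_bounds:
        raise GroupingError("no groups given")
    R = spectra.reflectance_matrix()
    chl = spectra.chlorophyll()
    profiles = []
    for lo, hi in group_bounds:
        mask = (chl >= lo) & (chl <= hi)
        if mask.sum() < 2:
            raise GroupingError(f"group [{lo}, {hi}] has fewer than 2 samples")
        sub = R[mask]
        mean = sub.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(mean > 0, sub.std(axis=0, ddof=1) / mean, 0.0)
        profiles.append(rel)
    return SDProfile(
        wavelengths=spectra.wavelengths,
        group_bounds=[tuple(b) for b in group_bounds],
        relative_sd=np.column_stack(profiles),
    )


def _interior_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima."""
    left, mid, right = values[:-2], values[1:-1], values[2:]
    maxima = np.nonzero((mid > left) & (mid > right))[0] + 1
    minima = np.nonzero((mid < left) & (mid < right))[0] + 1
    return maxima, minima


def pick_wavelengths(
    loadings: LoadingsMatrix,
    sd: SDProfile | None = None,
    n_max: int = 2,
    n_min: int = 1,
) -> WavelengthSet:
    """Select index-construction wavelengths from first-component loadings.

    Takes the ``n_max`` interior local maxima of |component-1 loadings| with
    the largest values and the ``n_min`` interior local minima with the
    smallest values; ties break toward the shorter wavelength.  The SD
    profile, when given, is not used for the automatic choice -- it is the
    corroborating evidence reported alongside for human inspection.
    """
    if n_max < 1 or n_min < 1:
        raise InputError("n_max and n_min must be >= 1")
    curve = np.abs(loadings.loadings[:, 0])
    wl = loadings.wavelengths
    max_idx, min_idx = _interior_extrema(curve)
    if max_idx.size < n_max:
        raise SelectionError(f"only {max_idx.size} local maxima; {n_max} requested")
    if min_idx.size < n_min:
        raise SelectionError(f"only {min_idx.size} local minima; {n_min} requested")

    max_order = sorted(max_idx, key=lambda i: (-curve[i], wl[i]))
    min_order = sorted(min_idx, key=lambda i: (curve[i], wl[i]))
    return WavelengthSet(
        maxima=sorted(float(wl[i]) for i in max_order[:n_max]),
        minima=sorted(float(wl[i]) for i in min_order[:n_min]),
    )


def collinearity(features: FeatureTable) -> CollinearityReport:
    """Variance inflation factors and tolerances for each feature.

    For feature j, ``VIF_j = 1 / (1 - R2_j)`` where R2_j comes from an
    intercept-included least-squares regression of feature j on all other
    features; ``tolerance_j = 1 / VIF_j``.  A perfectly collinear feature is
    reported with infinite VIF (tolerance 0) and flagged rather than raising.
    """
    X = features.values
    n, p = X.shape
    if p < 2:
        raise InputError("need at least 2 features for a collinearity screen")
    if n < p + 2:
        raise InputError("need at least features + 2 samples")

    vif = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sst = ((y - y.mean()) ** 2).sum()
        if sst == 0:
            vif[j] = np.inf
            continue
        r2 = 1.0 - (resid**2).sum() / sst
        vif[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)

    with np.errstate(divide="ignore"):
        tolerance = np.where(np.isinf(vif), 0.0, 1.0 / vif)
    flags = (vif > VIF_THRESHOLD) | (tolerance < TOLERANCE_THRESHOLD)
    return CollinearityReport(
        feature_names=list(features.feature_names),
        tolerance=tolerance,
        vif=vif,
        flags=flags,
    )
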