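"""Spectral vegetation indices and the feature table.

Eleven chlorophyll-related indices are computed from leaf reflectance:
eight established ones (NDVI, REP, NDVI705, mSR705, mNDVI705, PRI, MCARI,
VREI2) and three chlorophyll indices (CHLI1-3) built from the 516, 551 and
763 nm bands identified by the band-selection stage:

    CHLI1 = (rho551 + rho763) / (rho763 - rho551)
    CHLI2 = (rho763 - rho516) / rho551
    CHLI3 = (rho516 + rho551) / rho763

All indices except REP and MCARI are pure band ratios and therefore
invariant to a positive rescaling of the reflectance (percent vs fraction);
REP is a wavelength (nm) and is likewise scale invariant; MCARI's bracketed
difference term scales linearly with reflectance.

Two printed-form peculiarities are kept as defaults and can be swapped for
their common literature variants via ``IndexCatalog(literature_variants=True)``:
mSR705's denominator uses ``rho705 + rho445`` (the Sims-Gamon simple ratio
uses a division by ``rho445``-corrected terms) and VREI2 is the 757/720
normalized difference rather than the four-band Vogelmann form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CatalogError, InputError, RangeError, UndefinedIndexError
from .synthetic import SpectraSet, SpectrumRecord

__all__ = [
    "IndexDefinition",
    "IndexCatalog",
    "FeatureTable",
    "band",
    "compute_index",
    "red_edge_position",
    "compute_feature_table",
    "INDEX_NAMES",
]

logger = logging.getLogger(__name__)

INDEX_NAMES = (
    "NDVI",
    "REP",
    "NDVI705",
    "mSR705",
    "mNDVI705",
    "PRI",
    "MCARI",
    "VREI2",
    "CHLI1",
    "CHLI2",
    "CHLI3",
)


def band(spectrum: SpectrumRecord, nominal: float) -> float:
    """Reflectance at a nominal wavelength, linearly interpolated on the grid."""
    wl = spectrum.wavelengths
    if nominal < wl[0] or nominal > wl[-1]:
        raise RangeError(f"{nominal} nm outside grid [{wl[0]}, {wl[-1]}]")
    return float(np.interp(nominal, wl, spectrum.reflectance))


@dataclass(frozen=True)
class IndexDefinition:
    """One catalog entry: the bands an index needs and how to combine them."""

    name: str
    required_bands: tuple[float, ...]
    formula_id: str


def _ratio(name: str, num: float, den: float) -> float:
    if den == 0:
        raise UndefinedIndexError(name)
    return num / den


class IndexCatalog:
    """The eleven-index catalog with configurable NDVI bands.

    Parameters
    ----------
    nir, red : float
        NDVI bands; the default 780/670 nm pair matches the band set used
        by the red-edge-position formula.
    literature_variants : bool
        Substitute the Sims-Gamon mSR705 (minus in the denominator) and the
        four-band Vogelmann red-edge index 2.
    """

    def __init__(self, nir: float = 780.0, red: float = 670.0, literature_variants: bool = False):
        self.nir = nir
        self.red = red
        self.literature_variants = literature_variants

    def definitions(self) -> list[IndexDefinition]:
        msr_bands = (445.0, 705.0, 750.0)
        vrei2_bands = (715.0, 720.0, 726.0, 734.0, 747.0, 757.0) if self.literature_variants else (720.0, 757.0)
        return [
            IndexDefinition("NDVI", (self.red, self.nir), "normalized_difference"),
            IndexDefinition("REP", (670.0, 700.0, 740.0, 780.0), "red_edge_position"),
            IndexDefinition("NDVI705", (705.0, 750.0), "normalized_difference"),
            IndexDefinition("mSR705", msr_bands, "modified_simple_ratio"),
            IndexDefinition("mNDVI705", (445.0, 705.0, 750.0), "modified_normalized_difference"),
            IndexDefinition("PRI", (531.0, 570.0), "normalized_difference"),
            IndexDefinition("MCARI", (550.0, 670.0, 700.0), "mcari"),
            IndexDefinition("VREI2", vrei2_bands, "vogelmann2"),
            IndexDefinition("CHLI1", (551.0, 763.0), "chli1"),
            IndexDefinition("CHLI2", (516.0, 551.0, 763.0), "chli2"),
            IndexDefinition("CHLI3", (516.0, 551.0, 763.0), "chli3"),
        ]

    def names(self) -> list[str]:
        return [d.name for d in self.definitions()]

    def compute(self, spectrum: SpectrumRecord, name: str) -> float:
        rho = lambda nm: band(spectrum, nm)  # noqa: E731
        if name == "NDVI":
            return _ratio(name, rho(self.nir) - rho(self.red), rho(self.nir) + rho(self.red))
        if name == "REP":
            return red_edge_position(spectrum)
        if name == "NDVI705":
            return _ratio(name, rho(750) - rho(705), rho(750) + rho(705))
        if name == "mSR705":
            if self.literature_variants:
                return _ratio(name, rho(750) - rho(445), rho(705) - rho(445))
            return _ratio(name, rho(750) - rho(445), rho(705) + rho(445))
        if name == "mNDVI705":
            return _ratio(name, rho(750) - rho(705), rho(750) + rho(705) - 2 * rho(445))
        if name == "PRI":
            return _ratio(name, rho(531) - rho(570), rho(531) + rho(570))
        if name == "MCARI":
            if rho(670) == 0:
                raise UndefinedIndexError(name)
            return ((rho(700) - rho(670)) - 0.2 * (rho(700) - rho(550))) * (rho(700) / rho(670))
        if name == "VREI2":
            if self.literature_variants:
                return _ratio(name, rho(734) - rho(747), rho(715) + rho(726))
            return _ratio(name, rho(757) - rho(720), rho(757) + rho(720))
        if name == "CHLI1":
            return _ratio(name, rho(551) + rho(763), rho(763) - rho(551))
        if name == "CHLI2":
            return _ratio(name, rho(763) - rho(516), rho(551))
        if name == "CHLI3":
            return _ratio(name, rho(516) + rho(551), rho(763))
        raise CatalogError(f"unknown index {name!r}")


_DEFAULT_CATALOG = IndexCatalog()


def compute_index(spectrum: SpectrumRecord, name: str, catalog: IndexCatalog | None = None) -> float:
    """One index value for one spectrum; raises UndefinedIndexError on a zero denominator."""
    return (catalog or _DEFAULT_CATALOG).compute(spectrum, name)


def red_edge_position(spectrum: SpectrumRecord) -> float:
    """Red edge position (nm) by four-band linear interpolation:

    ``REP = 700 + 40 * (((rho670 + rho780)/2 - rho700) / (rho740 - rho700))``
    """
    r670 = band(spectrum, 670)
    r700 = band(spectrum, 700)
    r740 = band(spectrum, 740)
    r780 = band(spectrum, 780)
    if r740 == r700:
        raise UndefinedIndexError("REP")
    return 700.0 + 40.0 * (((r670 + r780) / 2.0 - r700) / (r740 - r700))


@dataclass
class FeatureTable:
    """Samples x named index values, plus an optional chlorophyll target."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    target: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise InputError("values shape inconsistent with sample/feature lists")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InputError("duplicated feature names")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if self.target.shape != (len(self.sample_ids),):
                raise InputError("target length inconsistent with sample list")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select(self, names: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(list(self.sample_ids), list(names), self.values[:, idx], self.target)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "sample_id", self.sample_ids)
        if self.target is not None:
            frame["chlorophyll"] = self.target
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, encoding="utf-8")
        if "sample_id" not in frame.columns:
            raise InputError("feature CSV must have a sample_id column")
        target = frame.pop("chlorophyll").to_numpy() if "chlorophyll" in frame.columns else None
        ids = frame.pop("sample_id").astype(str).tolist()
        return cls(ids, list(frame.columns), frame.to_numpy(dtype=float), target)


def compute_feature_table(
    spectra: SpectraSet,
    catalog: IndexCatalog | list[str] | None = None,
    policy: str = "drop",
) -> FeatureTable:
    """Assemble the feature table for a spectra set.

    Parameters
    ----------
    catalog : IndexCatalog or list of names, optional
        Defaults to the full eleven-index catalog.
    policy : {"drop", "raise"}
        What to do with a sample for which some index is undefined: drop the
        row with a logged warning, or fail fast.
    """
    if policy not in ("drop", "raise"):
        raise InputError("policy must be 'drop' or 'raise'")
    if isinstance(catalog, list):
        names, cat = catalog, _DEFAULT_CATALOG
    else:
        cat = catalog or _DEFAULT_CATALOG
        names = cat.names()

    rows, ids, targets = [], [], []
    for rec in spectra:
        try:
            row = [cat.compute(rec, n) for n in names]
        except UndefinedIndexError as err:
            if policy == "raise":
                raise
            logger.warning("dropping sample %s: %s", rec.sample_id, err)
            continue
        rows.append(row)
        ids.append(rec.sample_id)
        targets.append(rec.chlorophyll if rec.chlorophyll is not None else np.nan)

    target = np.array(targets)
    return FeatureTable(
        sample_ids=ids,
        feature_names=list(names),
        values=np.array(rows).reshape(len(ids), len(names)),
        target=None if np.isnan(target).all() else target,
    )
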