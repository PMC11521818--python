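"""Spectrophotometric chlorophyll determination.

Total chlorophyll (a+b) in ug/g fresh weight is computed from the 644 nm
and 663 nm absorbances of an acetone extract:

    chl = (20.2 * A644 + 8.02 * A663) * V / w

with V the tissue-extract volume (ml) and w the fresh weight (g).  The
470 nm absorbance is carried as a carotenoid-related measurement but no
quantitative carotenoid formula is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError

__all__ = ["AbsorbanceSample", "arnon_chlorophyll", "read_absorbance_csv"]

CHL_A644_COEF = 20.2
CHL_A663_COEF = 8.02


@dataclass(frozen=True)
class AbsorbanceSample:
    """Spectrophotometer readings for one extract.

    Attributes
    ----------
    A470, A644, A663 : float
        Absorbances (dimensionless, >= 0).
    V : float
        Volume of tissue extract, ml (> 0).
    w : float
        Fresh weight of tissue, g (> 0).
    """

    A470: float
    A644: float
    A663: float
    V: float
    w: float
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.A470 < 0 or self.A644 < 0 or self.A663 < 0:
            raise DomainError("absorbances must be >= 0")
        if self.V <= 0:
            raise DomainError("extract volume V must be > 0")
        if self.w <= 0:
            raise DomainError("fresh weight w must be > 0")


def arnon_chlorophyll(sample: AbsorbanceSample) -> float:
    """Total chlorophyll (a+b), ug/g fresh weight.

    Linear in each absorbance (slopes ``20.2*V/w`` and ``8.02*V/w``), linear
    in V and inversely proportional to w.
    """
    return (CHL_A644_COEF * sample.A644 + CHL_A663_COEF * sample.A663) * sample.V / sample.w


def read_absorbance_csv(path) -> list[AbsorbanceSample]:
    """Read ``sample_id,A470,A644,A663,V_ml,w_g`` rows."""
    frame = pd.read_csv(path, encoding="utf-8")
    required = {"sample_id", "A470", "A644", "A663", "V_ml", "w_g"}
    missing = required - set(frame.columns)
    if missing:
        raise DomainError(f"absorbance CSV is missing columns: {sorted(missing)}")
    return [
        AbsorbanceSample(
            A470=float(row.A470),
            A644=float(row.A644),
            A663=float(row.A663),
            V=float(row.V_ml),
            w=float(row.w_g),
            sample_id=str(row.sample_id),
        )
        for row in frame.itertuples(index=False)
    ]
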