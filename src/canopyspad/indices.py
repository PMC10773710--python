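"""Chlorophyll-related vegetation indices from 5-band plot reflectance.

The bands are the MicaSense-Altum-style set — blue (475 nm), green
(560 nm), red (668 nm), red edge (717 nm) and NIR (842 nm) — expressed
as fractional reflectance in (0, 1).  Seventeen broad-band indices with
established chlorophyll sensitivity are computed:

    NDVI, NDCI, NDRE, GNDVI, PPR        normalized differences
    CCCI                                campaign min–max-rescaled NDRE
    MTCI, SR, CIred_edge, CIgreen       ratio indices
    TCARI, MCARI                        chlorophyll-absorption indices
    TVI, mTVI                           triangular indices
    mNDblue, EVI, DVI                   blue-corrected / difference

All formulas operate on fractional reflectance exactly as written (no
percent rescaling of the triangular/absorption indices).  mNDblue is
computed as (Rblue − Rre)/(Rblue + Rnir) — note some literature uses a
different denominator; this package follows the broad-band form above.

CCCI needs a normalization population: NDRE_min and NDRE_max are taken
over all plots of the same flight date / growth stage, so CCCI is only
defined relative to a campaign and is computed by
:func:`build_vi_table` (or :func:`compute_ccci`), not per single plot.

Zero denominators yield NaN markers (never ±inf); per-index NaN counts
are logged by :func:`build_vi_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PlotReflectance",
    "BANDS",
    "VI_NAMES",
    "RATIO_INVARIANT_VIS",
    "compute_vi",
    "compute_ccci",
    "build_vi_table",
]

log = logging.getLogger(__name__)

BANDS = ("blue", "green", "red", "red_edge", "nir")


@dataclass(frozen=True)
class PlotReflectance:
    """Mean fractional reflectance of one plot in the five bands."""

    plot_id: str
    stage: str
    blue: float
    green: float
    red: float
    red_edge: float
    nir: float

    def __post_init__(self):
        for band in BANDS:
            v = getattr(self, band)
            if not (0.0 < v < 1.0):
                raise ValueError(
                    f"plot {self.plot_id}: band {band}={v} outside (0, 1)"
                )

    def as_dict(self) -> dict[str, float]:
        return {band: getattr(self, band) for band in BANDS}


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0.0, np.nan, num / np.where(den == 0.0, 1.0, den))
    return out


# Each formula maps band arrays -> index values. CCCI is campaign-level
# and therefore absent here.
_FORMULAS: Mapping[str, Callable] = {
    "NDVI": lambda b, g, r, re, nir: _safe_div(nir - r, nir + r),
    "NDCI": lambda b, g, r, re, nir: _safe_div(re - r, re + r),
    "NDRE": lambda b, g, r, re, nir: _safe_div(nir - re, nir + re),
    "GNDVI": lambda b, g, r, re, nir: _safe_div(nir - g, nir + g),
    "PPR": lambda b, g, r, re, nir: _safe_div(g - b, g + b),
    "MTCI": lambda b, g, r, re, nir: _safe_div(nir - re, re - r),
    "SR": lambda b, g, r, re, nir: _safe_div(nir, r),
    "CIred_edge": lambda b, g, r, re, nir: _safe_div(nir, re) - 1.0,
    "CIgreen": lambda b, g, r, re, nir: _safe_div(nir, g) - 1.0,
    "TCARI": lambda b, g, r, re, nir: 3.0 * ((re - r) - 0.2 * (re - g) * _safe_div(re, r)),
    "TVI": lambda b, g, r, re, nir: 60.0 * (nir - g) - 100.0 * (r - g),
    "mTVI": lambda b, g, r, re, nir: 60.0 * (nir - g) - 100.0 * (re - g),
    "MCARI": lambda b, g, r, re, nir: (re - r) - 0.2 * (re - g) * _safe_div(re, r),
    "mNDblue": lambda b, g, r, re, nir: _safe_div(b - re, b + nir),
    "EVI": lambda b, g, r, re, nir: _safe_div(2.5 * (nir - r), nir + 6.0 * r - 7.5 * b + 1.0),
    "DVI": lambda b, g, r, re, nir: nir - r,
}

VI_NAMES: tuple[str, ...] = (
    "NDVI", "NDCI", "NDRE", "GNDVI", "PPR", "CCCI", "MTCI", "SR",
    "CIred_edge", "CIgreen", "TCARI", "TVI", "mTVI", "MCARI",
    "mNDblue", "EVI", "DVI",
)

#: Indices that are pure functions of band ratios, hence invariant to a
#: common rescaling of all bands.
RATIO_INVARIANT_VIS = (
    "NDVI", "NDRE", "NDCI", "GNDVI", "PPR", "SR",
    "CIred_edge", "CIgreen", "MTCI", "mNDblue",
)


def compute_vi(reflectance: PlotReflectance, name: str) -> float:
    """Compute one per-plot index value.

    CCCI cannot be computed for a single plot (it is normalized over a
    campaign); request it through :func:`build_vi_table` or
    :func:`compute_ccci`.
    """
    if name == "CCCI":
        raise ValueError(
            "CCCI is campaign-normalized; use compute_ccci/build_vi_table"
        )
    if name not in _FORMULAS:
        raise ValueError(
            f"unknown vegetation index {name!r}; supported: "
            + ", ".join(VI_NAMES)
        )
    b, g, r, re, nir = (getattr(reflectance, band) for band in BANDS)
    return float(_FORMULAS[name](b, g, r, re, nir))


def compute_ccci(ndre_values) -> np.ndarray:
    """Min–max rescale NDRE over one campaign/date to the [0, 1] CCCI.

    The plot at the campaign NDRE minimum maps to 0, the maximum to 1.
    Requires at least two distinct finite NDRE values.
    """
    ndre = np.asarray(ndre_values, dtype=float)
    finite = ndre[np.isfinite(ndre)]
    if finite.size < 2 or np.ptp(finite) == 0:
        raise ValueError(
            "CCCI normalization undefined: need >=2 distinct NDRE values"
        )
    return (ndre - finite.min()) / (finite.max() - finite.min())


def build_vi_table(
    reflectances: Iterable[PlotReflectance],
    stage: str | None = None,
) -> pd.DataFrame:
    """All 17 indices for every plot of one stage/date.

    CCCI is normalized within the supplied plot set (one flight date).
    With a single plot, CCCI is undefined and carried as NaN with a log
    warning.  Undefined values from zero denominators propagate as NaN;
    per-index counts are logged.
    """
    plots = list(reflectances)
    if not plots:
        raise ValueError("no reflectance records supplied")
    if stage is not None:
        bad = [p.plot_id for p in plots if p.stage != stage]
        if bad:
            raise ValueError(f"plots not in stage {stage!r}: {bad}")

    arrays = {band: np.array([getattr(p, band) for p in plots]) for band in BANDS}
    args = tuple(arrays[band] for band in BANDS)
    table = pd.DataFrame(
        {name: f(*args) for name, f in _FORMULAS.items()},
        index=pd.Index([p.plot_id for p in plots], name="plot_id"),
    )
    try:
        table["CCCI"] = compute_ccci(table["NDRE"].to_numpy())
    except ValueError as exc:
        log.warning("CCCI undefined for this campaign: %s", exc)
        table["CCCI"] = np.nan
    table = table[list(VI_NAMES)]
    table.insert(0, "stage", stage if stage is not None else plots[0].stage)

    nan_counts = table[list(VI_NAMES)].isna().sum()
    for name, count in nan_counts[nan_counts > 0].items():
        log.warning("index %s: %d undefined value(s)", name, int(count))
    return table
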