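"""Lorentz peak model of the vertical SPAD profile in a maize canopy.

Leaf chlorophyll (SPAD) in maize is not uniform with height: it rises
from the senescing bottom leaves to a peak in the mid-canopy and falls
again towards the expanding top leaves.  That bell shape is captured by
a three-parameter Lorentz (Cauchy-type) peak curve over leaf position
``n`` (counted from the bottom of the stem):

    SPAD(n) = spad_m / (1 + ((n - n_m) / b)^2)

where ``spad_m`` is the peak SPAD value, ``n_m`` the leaf position of
the peak, and ``b`` a width/slope coefficient (in leaf-position units;
at |n - n_m| = b the curve is at half its peak).  The model is even in
``b``; the positive representative is always reported.

This module evaluates the curve, fits it to single vertical profiles by
bounded nonlinear least squares, aggregates fits over a designed
campaign (one fit per nitrogen-treatment × growth-stage group, on the
leaf-position-wise mean profile), and validates a fitted parameter
table against an independent season's profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import metrics

__all__ = [
    "LorentzParams",
    "LeafSPADProfile",
    "FitResult",
    "InsufficientDataError",
    "DegenerateProfileError",
    "lorentz_evaluate",
    "fit_lorentz",
    "fit_campaign",
    "validate_fit",
    "mean_profile",
]

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer distinct leaf positions than the 3 fitted parameters need."""


class DegenerateProfileError(ValueError):
    """All SPAD values identical; the peak model is unidentifiable."""


@dataclass(frozen=True)
class LorentzParams:
    """Parameters of the Lorentz peak curve.

    spad_m : peak SPAD value (> 0, SPAD units)
    n_m    : leaf position of the peak (leaf-position units)
    b      : width/slope coefficient (> 0, leaf-position units)
    """

    spad_m: float
    n_m: float
    b: float

    def __post_init__(self):
        if not (self.spad_m > 0):
            raise ValueError(f"spad_m must be > 0, got {self.spad_m}")
        if not (self.b > 0):
            raise ValueError(f"b must be > 0, got {self.b}")
        if not math.isfinite(self.n_m):
            raise ValueError(f"n_m must be finite, got {self.n_m}")

    def __call__(self, n) -> np.ndarray | float:
        return lorentz_evaluate(self, n)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.spad_m, self.n_m, self.b)


@dataclass(frozen=True)
class LeafSPADProfile:
    """One plot × stage vertical profile: (leaf position, SPAD) pairs.

    Leaf positions must be strictly increasing; SPAD values must be
    non-negative.
    """

    plot_id: str
    stage: str
    n_treatment: str
    variety: str
    positions: tuple[int, ...]
    spad: tuple[float, ...]

    def __post_init__(self):
        if len(self.positions) != len(self.spad):
            raise ValueError("positions and spad must have equal length")
        if len(self.positions) == 0:
            raise ValueError("profile needs at least one observation")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("leaf positions must be strictly increasing")
        if any(s < 0 for s in self.spad):
            raise ValueError("SPAD values must be non-negative")

    @property
    def canopy_mean(self) -> float:
        """Mean SPAD over all measured leaves — the canopy SPAD value."""
        return float(np.mean(self.spad))


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares fit of the Lorentz peak curve."""

    params: LorentzParams
    r2: float
    rmse: float
    n_obs: int
    converged: bool
    sse: float = field(default=float("nan"))


def lorentz_evaluate(params: LorentzParams, n) -> np.ndarray | float:
    """Evaluate the Lorentz peak curve at leaf position(s) ``n``.

    Accepts scalars or arrays; the curve peaks at ``n = n_m`` with value
    ``spad_m`` and is symmetric about the peak.
    """
    if params.b == 0:
        raise ZeroDivisionError("Lorentz width b must be nonzero")
    n_arr = np.asarray(n, dtype=float)
    val = params.spad_m / (1.0 + ((n_arr - params.n_m) / params.b) ** 2)
    return float(val) if np.isscalar(n) or n_arr.ndim == 0 else val


def _fit_arrays(
    positions: np.ndarray,
    spad: np.ndarray,
    *,
    ftol: float = 1e-12,
    max_nfev: int = 2000,
) -> FitResult:
    if np.unique(positions).size < 3:
        raise InsufficientDataError(
            f"need >=3 distinct leaf positions to fit 3 parameters, "
            f"got {np.unique(positions).size}"
        )
    if np.ptp(spad) == 0:
        raise DegenerateProfileError("constant SPAD profile cannot be fitted")

    pos_range = float(positions.max() - positions.min())
    s_max = float(spad.max())
    lo = np.array([1e-9, positions.min() - 2.0, 0.1])
    hi = np.array([2.0 * s_max, positions.max() + 2.0, 3.0 * pos_range])

    def residuals(theta):
        sm, nm, b = theta
        return sm / (1.0 + ((positions - nm) / b) ** 2) - spad

    # start at the observed peak with width = half the position span;
    # a coarse grid presearch supplies a second start so short noisy
    # profiles do not strand the local optimizer in a side minimum
    starts = [np.array([s_max, float(positions[np.argmax(spad)]), pos_range / 2.0])]
    sm_g = np.linspace(max(s_max / 4, 1e-3), 2.0 * s_max, 16)
    nm_g = np.linspace(lo[1], hi[1], 24)
    b_g = np.geomspace(0.1, hi[2], 24)  # geometric: narrow peaks need fine b
    curves = sm_g[:, None, None, None] / (
        1.0
        + ((positions[None, None, None, :] - nm_g[None, :, None, None])
           / b_g[None, None, :, None]) ** 2
    )
    sse_grid = ((curves - spad) ** 2).sum(axis=-1)
    flat_order = np.argsort(sse_grid, axis=None)[:3]
    for flat in flat_order:
        i, j, k = np.unravel_index(flat, sse_grid.shape)
        starts.append(np.array([sm_g[i], nm_g[j], b_g[k]]))

    best = None
    for x0 in starts:
        sol = least_squares(
            residuals, np.clip(x0, lo + 1e-12, hi - 1e-12), bounds=(lo, hi),
            ftol=ftol, xtol=1e-14, gtol=1e-14, max_nfev=max_nfev,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    sol = best
    sm, nm, b = sol.x
    params = LorentzParams(spad_m=float(sm), n_m=float(nm), b=abs(float(b)))
    fitted = lorentz_evaluate(params, positions)
    sse = float(np.sum((spad - fitted) ** 2))
    return FitResult(
        params=params,
        r2=metrics.r_squared(spad, fitted),
        rmse=metrics.rmse(spad, fitted),
        n_obs=int(spad.size),
        converged=bool(sol.status > 0),
        sse=sse,
    )


def fit_lorentz(profile: LeafSPADProfile, **options) -> FitResult:
    """Fit the Lorentz peak curve to a single vertical profile.

    Bounded trust-region least squares: ``spad_m`` in (0, 2·max SPAD],
    ``n_m`` within the observed position range ±2 leaves, ``b`` in
    (0.1, 3·position range].  A profile with fewer than three distinct
    positions raises :class:`InsufficientDataError`; a flat profile
    raises :class:`DegenerateProfileError`.  Non-convergence is reported
    through ``converged=False``, never an exception.
    """
    return _fit_arrays(
        np.asarray(profile.positions, dtype=float),
        np.asarray(profile.spad, dtype=float),
        **options,
    )


def mean_profile(profiles: Sequence[LeafSPADProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Leaf-position-wise mean SPAD across plots.

    Positions missing from some plots (senesced leaves) enter the mean
    only where observed.
    """
    acc: dict[int, list[float]] = {}
    for p in profiles:
        for n, s in zip(p.positions, p.spad):
            acc.setdefault(int(n), []).append(float(s))
    positions = np.array(sorted(acc), dtype=float)
    means = np.array([np.mean(acc[int(n)]) for n in positions])
    return positions, means


def fit_campaign(
    profiles: Iterable[LeafSPADProfile],
    *,
    mode: Literal["mean", "pooled"] = "mean",
) -> pd.DataFrame:
    """Fit one Lorentz curve per (nitrogen treatment, stage) group.

    ``mode="mean"`` (default) first averages SPAD per leaf position
    across the group's plots and fits the mean profile — the protocol
    matching a single curve drawn through per-position means with error
    bars.  ``mode="pooled"`` fits all (position, SPAD) observations of
    the group jointly.

    Returns a table keyed by (n_treatment, stage) with columns
    ``spad_m, n_m, n_m_rounded, b, r2, rmse, n_obs, converged, error``.
    Groups whose fit fails carry the error message instead of crashing
    the campaign.
    """
    groups: dict[tuple[str, str], list[LeafSPADProfile]] = {}
    for p in profiles:
        groups.setdefault((p.n_treatment, p.stage), []).append(p)
    if not groups:
        raise ValueError("no profiles supplied")

    rows = []
    for (treatment, stage), members in sorted(groups.items()):
        row: dict[str, object] = {"n_treatment": treatment, "stage": stage}
        try:
            if mode == "mean":
                pos, spad = mean_profile(members)
            elif mode == "pooled":
                pos = np.array([n for m in members for n in m.positions], dtype=float)
                spad = np.array([s for m in members for s in m.spad], dtype=float)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            res = _fit_arrays(pos, spad)
        except (InsufficientDataError, DegenerateProfileError) as exc:
            log.warning("group (%s, %s) skipped: %s", treatment, stage, exc)
            row.update(error=str(exc))
            rows.append(row)
            continue
        row.update(
            spad_m=res.params.spad_m,
            n_m=res.params.n_m,
            n_m_rounded=int(round(res.params.n_m)),
            b=res.params.b,
            r2=res.r2,
            rmse=res.rmse,
            n_obs=res.n_obs,
            converged=res.converged,
            error="",
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index(["n_treatment", "stage"]).sort_index()


def validate_fit(
    params_by_group: Mapping[tuple[str, str], LorentzParams],
    profiles: Iterable[LeafSPADProfile],
) -> pd.DataFrame:
    """Validate a fitted parameter table against independent profiles.

    For every validation plot, SPAD at each observed leaf position is
    predicted from that plot's (treatment, stage) parameters; predicted
    and observed values are pooled per stage and compared 1:1 with R²
    and RMSE.  Treatments absent from the parameter table are excluded
    and reported in the ``excluded_treatments`` column.
    """
    pooled: dict[str, tuple[list[float], list[float]]] = {}
    excluded: dict[str, set[str]] = {}
    for p in profiles:
        key = (p.n_treatment, p.stage)
        if key not in params_by_group:
            excluded.setdefault(p.stage, set()).add(p.n_treatment)
            continue
        pred = lorentz_evaluate(
            params_by_group[key], np.asarray(p.positions, dtype=float)
        )
        obs_l, pred_l = pooled.setdefault(p.stage, ([], []))
        obs_l.extend(p.spad)
        pred_l.extend(np.atleast_1d(pred))

    rows = []
    for stage in sorted(set(pooled) | set(excluded)):
        obs_l, pred_l = pooled.get(stage, ([], []))
        row: dict[str, object] = {
            "stage": stage,
            "n_obs": len(obs_l),
            "excluded_treatments": ",".join(sorted(excluded.get(stage, ()))),
        }
        if len(obs_l) >= 2 and np.ptp(obs_l) > 0:
            row["r2"] = metrics.r_squared(obs_l, pred_l)
            row["rmse"] = metrics.rmse(obs_l, pred_l)
        else:
            row["r2"] = float("nan")
            row["rmse"] = metrics.rmse(obs_l, pred_l) if obs_l else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("stage")


def params_table_to_mapping(table: pd.DataFrame) -> dict[tuple[str, str], LorentzParams]:
    """Convert a `fit_campaign` table to the mapping `validate_fit` takes."""
    out = {}
    for key, row in table.iterrows():
        if row.get("error"):
            continue
        out[key] = LorentzParams(row["spad_m"], row["n_m"], row["b"])
    return out
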