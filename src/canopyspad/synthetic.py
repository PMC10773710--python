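"""Synthetic maize-canopy campaigns with known ground truth.

No public dataset accompanies the vertical-SPAD problem, so every
downstream stage (curve fitting, index ranking, sensitive-leaf
screening, inversion) is exercised on simulated campaigns that mimic a
split-plot nitrogen trial: nitrogen level is the main plot (N0–N6,
0–400 kg N ha⁻¹), hybrid varieties are randomized within it, with
replicates.  For each plot × growth stage:

* the vertical SPAD profile is a Lorentz peak curve evaluated at the
  stage's integer leaf positions, using the (treatment, stage)
  parameter triple of the ground truth, plus additive Gaussian
  measurement noise truncated below at zero;
* plot reflectance is tied to the SPAD of the stage's designated
  sensitive leaf through a latent red-edge contrast
  ``c = a0 + a1·SPAD(sensitive) + noise`` realized as the plot's NDRE
  (clamped to [0.01, 0.99]); NIR is held at a plausible vegetation
  level and the red edge solved from NDRE, while blue/green/red are
  nuisance draws independent of SPAD.

Randomness is fully reproducible: one campaign seed, with per-plot
streams keyed by (seed, stage index, plot index) so the draw a plot
receives never depends on generation order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .indices import BANDS, PlotReflectance
from .lorentz import LeafSPADProfile, LorentzParams, lorentz_evaluate

__all__ = [
    "CampaignConfig",
    "GroundTruth",
    "ConfigurationError",
    "CampaignParseError",
    "generate_profiles",
    "generate_reflectance",
    "generate_campaign",
    "write_campaign",
    "read_campaign",
]

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Campaign configuration and ground truth are inconsistent."""


class CampaignParseError(ValueError):
    """A campaign file on disk is malformed."""


#: Nuisance band sampling ranges (fractional reflectance) and the fixed
#: NIR level used when constructing reflectance from the latent NDRE.
NUISANCE_RANGES = {"blue": (0.03, 0.06), "green": (0.06, 0.12), "red": (0.04, 0.10)}
NIR_LEVEL = 0.45

#: Default latent-contrast coefficients (a0, a1): NDRE = a0 + a1·SPAD.
#: Maps SPAD 20–60 to NDRE ≈ 0.17–0.61, a realistic maize canopy span.
DEFAULT_CONTRAST_COEFFS = (-0.05, 0.011)


@dataclass(frozen=True)
class CampaignConfig:
    """Design of one simulated split-plot campaign.

    Defaults follow a 7-nitrogen-level × 10-variety × 3-replicate
    trial observed at four growth stages.  ``spad_noise_sd`` is the
    per-leaf SPAD measurement noise (SPAD units); ``reflectance_noise_sd``
    perturbs the latent NDRE contrast (NDRE units).
    """

    n_treatments: tuple[str, ...] = reference.N_TREATMENTS
    varieties: int = 10
    reps: int = 3
    stages: tuple[str, ...] = reference.STAGES
    leaf_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(reference.LEAF_RANGES)
    )
    spad_noise_sd: float = 2.0
    reflectance_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.spad_noise_sd < 0 or self.reflectance_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.varieties < 1 or self.reps < 1:
            raise ValueError("varieties and reps must be >= 1")
        for stage in self.stages:
            if stage not in self.leaf_ranges:
                raise ConfigurationError(f"no leaf range for stage {stage!r}")
            lo, hi = self.leaf_ranges[stage]
            if hi - lo + 1 < 3:
                raise ConfigurationError(
                    f"stage {stage!r}: need >=3 leaf positions for a "
                    f"3-parameter fit, got range {lo}-{hi}"
                )

    def positions(self, stage: str) -> np.ndarray:
        lo, hi = self.leaf_ranges[stage]
        return np.arange(lo, hi + 1)

    @property
    def plot_ids(self) -> list[tuple[str, str, str, str]]:
        """(plot_id, treatment, variety, rep) in fixed design order."""
        out = []
        for t in self.n_treatments:
            for v in range(1, self.varieties + 1):
                for r in range(1, self.reps + 1):
                    out.append((f"{t}_C{v:02d}_r{r}", t, f"C{v:02d}", f"r{r}"))
        return out


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of a campaign.

    ``params[treatment][stage]`` is the Lorentz triple used for that
    group; ``sensitive_leaf[stage]`` is the leaf position whose SPAD
    drives reflectance; ``contrast_coeffs[stage]`` are the (a0, a1) of
    the latent NDRE link.
    """

    params: Mapping[str, Mapping[str, LorentzParams]] = field(
        default_factory=lambda: {
            t: dict(s) for t, s in reference.LORENTZ_PARAMS.items()
        }
    )
    sensitive_leaf: Mapping[str, int] = field(
        default_factory=lambda: dict(reference.SENSITIVE_LEAF)
    )
    contrast_coeffs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {s: DEFAULT_CONTRAST_COEFFS for s in reference.STAGES}
    )

    def lookup(self, treatment: str, stage: str) -> LorentzParams:
        try:
            return self.params[treatment][stage]
        except KeyError:
            raise ConfigurationError(
                f"no generating parameters for treatment {treatment!r} "
                f"at stage {stage!r}"
            ) from None

    def validate_against(self, config: CampaignConfig) -> None:
        for t in config.n_treatments:
            for s in config.stages:
                p = self.lookup(t, s)
                lo, hi = config.leaf_ranges[s]
                if not (lo <= p.n_m <= hi):
                    raise ConfigurationError(
                        f"({t}, {s}): peak position n_m={p.n_m} outside "
                        f"the stage leaf range {lo}-{hi}"
                    )

    def to_jsonable(self) -> dict:
        return {
            "params": {
                t: {s: {"spad_m": p.spad_m, "n_m": p.n_m, "b": p.b}
                    for s, p in stages.items()}
                for t, stages in self.params.items()
            },
            "sensitive_leaf": dict(self.sensitive_leaf),
            "contrast_coeffs": {s: list(c) for s, c in self.contrast_coeffs.items()},
        }

    @classmethod
    def from_jsonable(cls, obj: Mapping) -> "GroundTruth":
        return cls(
            params={
                t: {s: LorentzParams(d["spad_m"], d["n_m"], d["b"])
                    for s, d in stages.items()}
                for t, stages in obj["params"].items()
            },
            sensitive_leaf={s: int(v) for s, v in obj["sensitive_leaf"].items()},
            contrast_coeffs={s: tuple(c) for s, c in obj["contrast_coeffs"].items()},
        )


def _plot_rng(seed: int, namespace: int, stage_idx: int, plot_idx: int):
    # stream identity depends only on (seed, namespace, stage, plot),
    # never on generation order
    return np.random.default_rng([seed, namespace, stage_idx, plot_idx])


def generate_profiles(
    config: CampaignConfig, truth: GroundTruth | None = None
) -> list[LeafSPADProfile]:
    """One vertical SPAD profile per plot × stage.

    SPAD at leaf n = Lorentz(n; treatment, stage) + N(0, spad_noise_sd),
    truncated below at 0.  Deterministic given ``config.seed``.
    """
    truth = truth if truth is not None else GroundTruth()
    truth.validate_against(config)
    profiles: list[LeafSPADProfile] = []
    for s_idx, stage in enumerate(config.stages):
        positions = config.positions(stage)
        for p_idx, (plot_id, treatment, variety, _rep) in enumerate(config.plot_ids):
            params = truth.lookup(treatment, stage)
            clean = lorentz_evaluate(params, positions.astype(float))
            if config.spad_noise_sd > 0:
                rng = _plot_rng(config.seed, 0, s_idx, p_idx)
                noisy = clean + rng.normal(0.0, config.spad_noise_sd, positions.size)
            else:
                noisy = np.asarray(clean, dtype=float)
            profiles.append(
                LeafSPADProfile(
                    plot_id=plot_id,
                    stage=stage,
                    n_treatment=treatment,
                    variety=variety,
                    positions=tuple(int(n) for n in positions),
                    spad=tuple(float(v) for v in np.maximum(noisy, 0.0)),
                )
            )
    return profiles


def generate_reflectance(
    profiles: Sequence[LeafSPADProfile],
    truth: GroundTruth | None = None,
    config: CampaignConfig | None = None,
) -> list[PlotReflectance]:
    """Plot-mean reflectance co-varying with sensitive-leaf SPAD.

    For each plot the latent contrast ``c = a0 + a1·SPAD(sensitive)``
    plus Gaussian noise becomes the plot NDRE after clamping to
    [0.01, 0.99]; NIR is fixed at ``NIR_LEVEL`` and the red-edge band
    solved from NDRE, so the generated NDRE is exact.  Blue, green and
    red are uniform nuisance draws.  If clamping alters the contrast
    for more than 10% of plots a warning is logged with the count.
    """
    truth = truth if truth is not None else GroundTruth()
    config = config if config is not None else CampaignConfig()
    extra_stages = [
        s for s in dict.fromkeys(p.stage for p in profiles) if s not in config.stages
    ]
    stage_index = {
        s: i for i, s in enumerate(tuple(config.stages) + tuple(extra_stages))
    }
    plot_index = {pid: i for i, (pid, *_rest) in enumerate(config.plot_ids)}

    out: list[PlotReflectance] = []
    n_clamped = 0
    for prof in profiles:
        stage = prof.stage
        sens = truth.sensitive_leaf[stage]
        if sens not in prof.positions:
            raise ConfigurationError(
                f"plot {prof.plot_id!r} ({stage}): sensitive leaf {sens} "
                f"not among measured positions {prof.positions}"
            )
        a0, a1 = truth.contrast_coeffs[stage]
        s_idx = stage_index[stage]
        p_idx = plot_index.get(prof.plot_id, len(plot_index) + len(out))
        rng = _plot_rng(config.seed, 1, s_idx, p_idx)

        spad_sens = prof.spad[prof.positions.index(sens)]
        c = a0 + a1 * spad_sens
        if config.reflectance_noise_sd > 0:
            c += rng.normal(0.0, config.reflectance_noise_sd)
        ndre = float(np.clip(c, 0.01, 0.99))
        if ndre != c:
            n_clamped += 1
        nir = NIR_LEVEL
        red_edge = nir * (1.0 - ndre) / (1.0 + ndre)
        nuisance = {
            band: float(rng.uniform(lo, hi))
            for band, (lo, hi) in NUISANCE_RANGES.items()
        }
        out.append(
            PlotReflectance(
                plot_id=prof.plot_id, stage=stage,
                red_edge=red_edge, nir=nir, **nuisance,
            )
        )
    if profiles and n_clamped > 0.10 * len(profiles):
        log.warning(
            "latent NDRE contrast clamped for %d of %d plots; "
            "contrast coefficients may be off-scale", n_clamped, len(profiles),
        )
    return out


def generate_campaign(
    config: CampaignConfig, truth: GroundTruth | None = None
) -> tuple[list[LeafSPADProfile], list[PlotReflectance], GroundTruth]:
    """Convenience: profiles + reflectance + the truth that made them."""
    truth = truth if truth is not None else GroundTruth()
    profiles = generate_profiles(config, truth)
    reflectance = generate_reflectance(profiles, truth, config)
    return profiles, reflectance, truth


# ---------------------------------------------------------------- I/O

PROFILE_COLUMNS = ["plot_id", "variety", "n_treatment", "stage", "leaf_position", "spad"]
REFLECTANCE_COLUMNS = ["plot_id", "stage", *BANDS]


def write_campaign(
    profiles: Iterable[LeafSPADProfile],
    reflectance: Iterable[PlotReflectance],
    path: str | Path,
    truth: GroundTruth | None = None,
) -> None:
    """Write ``spad_profiles.csv``, ``plot_reflectance.csv`` and,
    when ground truth is supplied, ``ground_truth.json`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    prof_rows = [
        {
            "plot_id": p.plot_id, "variety": p.variety,
            "n_treatment": p.n_treatment, "stage": p.stage,
            "leaf_position": n, "spad": s,
        }
        for p in profiles
        for n, s in zip(p.positions, p.spad)
    ]
    pd.DataFrame(prof_rows, columns=PROFILE_COLUMNS).to_csv(
        path / "spad_profiles.csv", index=False, float_format="%.17g"
    )
    refl_rows = [
        {"plot_id": r.plot_id, "stage": r.stage, **r.as_dict()}
        for r in reflectance
    ]
    pd.DataFrame(refl_rows, columns=REFLECTANCE_COLUMNS).to_csv(
        path / "plot_reflectance.csv", index=False, float_format="%.17g"
    )
    if truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(truth.to_jsonable(), indent=2)
        )


def read_profiles(path: str | Path) -> list[LeafSPADProfile]:
    """Read a long-format SPAD profile table back into profile objects."""
    path = Path(path)
    df = pd.read_csv(
        path, dtype={c: str for c in PROFILE_COLUMNS[:4]},
        float_precision="round_trip",
    )
    if missing := set(PROFILE_COLUMNS) - set(df.columns):
        raise CampaignParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("leaf_position", "spad"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().all():
            bad = df.index[coerced.isna() & df[col].notna()]
            # +2: header line plus 1-based file numbering
            raise CampaignParseError(
                f"{path}: non-numeric {col!r} at file line {int(bad[0]) + 2}"
            )
        df[col] = coerced
    profiles = []
    for (plot_id, stage), grp in df.groupby(["plot_id", "stage"], sort=False):
        grp = grp.sort_values("leaf_position")
        profiles.append(
            LeafSPADProfile(
                plot_id=str(plot_id),
                stage=str(stage),
                n_treatment=str(grp["n_treatment"].iloc[0]),
                variety=str(grp["variety"].iloc[0]),
                positions=tuple(int(n) for n in grp["leaf_position"]),
                spad=tuple(float(s) for s in grp["spad"]),
            )
        )
    return profiles


def read_reflectance(path: str | Path) -> list[PlotReflectance]:
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"plot_id": str, "stage": str}, float_precision="round_trip"
    )
    if missing := set(REFLECTANCE_COLUMNS) - set(df.columns):
        raise CampaignParseError(f"{path}: missing columns {sorted(missing)}")
    for band in BANDS:
        coerced = pd.to_numeric(df[band], errors="coerce")
        if coerced.isna().any() and not df[band].isna().all():
            bad = df.index[coerced.isna() & df[band].notna()]
            raise CampaignParseError(
                f"{path}: non-numeric {band!r} at file line {int(bad[0]) + 2}"
            )
        df[band] = coerced
    return [
        PlotReflectance(
            plot_id=str(r.plot_id), stage=str(r.stage),
            **{band: float(getattr(r, band)) for band in BANDS},
        )
        for r in df.itertuples()
    ]


def read_campaign(
    path: str | Path,
) -> tuple[list[LeafSPADProfile], list[PlotReflectance], GroundTruth | None]:
    """Read a campaign directory written by :func:`write_campaign`."""
    path = Path(path)
    profiles = read_profiles(path / "spad_profiles.csv")
    reflectance = read_reflectance(path / "plot_reflectance.csv")
    truth = None
    truth_path = path / "ground_truth.json"
    if truth_path.exists():
        truth = GroundTruth.from_jsonable(json.loads(truth_path.read_text()))
    return profiles, reflectance, truth
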