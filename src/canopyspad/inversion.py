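"""Sensitive-leaf screening and linear SPAD inversion from indices.

The scientific question: which single leaf position's SPAD does a
canopy-scale vegetation index actually see?  Per growth stage,

* :func:`rank_vis` correlates every index with the canopy-mean SPAD
  across plots and ranks them (the top-5 table view);
* :func:`find_sensitive_leaf` correlates one chosen index with SPAD at
  each leaf position and returns the position with the highest signed
  correlation — the "sensitive" leaf;
* :func:`fit_inversion` builds the simple linear inversion
  SPAD = intercept + slope·VI against either the sensitive-leaf SPAD or
  the canopy mean, with train/test evaluation;
* :func:`compare_models` reports the relative R² gain of the
  sensitive-leaf model over the canopy-mean model;
* :func:`describe_profiles` summarizes the vertical distribution per
  treatment (peak position, canopy mean, bell shape).

Correlations are pairwise-complete per leaf position: positions missing
in some plots (senesced leaves) use only the plots where they were
measured, with n reported.  Screening is at raw p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .lorentz import LeafSPADProfile, mean_profile

__all__ = [
    "StageDataset",
    "StageInversionModel",
    "describe_profiles",
    "rank_vis",
    "find_sensitive_leaf",
    "fit_inversion",
    "compare_models",
    "predict_spad_map",
]

log = logging.getLogger(__name__)

MIN_PLOTS = 3


@dataclass(frozen=True)
class StageDataset:
    """Aligned per-plot SPAD and index data for one growth stage.

    ``spad``: plots × leaf-position table (NaN where a leaf was not
    measured); ``vi``: plots × index table; ``canopy_spad``: per-plot
    mean over measured leaves.  Rows of all three share the plot index.
    """

    stage: str
    spad: pd.DataFrame
    vi: pd.DataFrame
    canopy_spad: pd.Series

    def __post_init__(self):
        if not (self.spad.index.equals(self.vi.index)
                and self.spad.index.equals(self.canopy_spad.index)):
            raise ValueError("plot ids must align across SPAD, VI and canopy tables")

    @classmethod
    def from_campaign(
        cls,
        profiles: Sequence[LeafSPADProfile],
        vi_table: pd.DataFrame,
        stage: str,
    ) -> "StageDataset":
        """Assemble the stage dataset from profiles and an index table."""
        rows = {}
        for p in profiles:
            if p.stage == stage:
                rows[p.plot_id] = dict(zip(p.positions, p.spad))
        if not rows:
            raise ValueError(f"no profiles for stage {stage!r}")
        spad = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
        spad.index.name = "plot_id"
        vi = vi_table.drop(columns="stage", errors="ignore").loc[spad.index]
        return cls(
            stage=stage, spad=spad, vi=vi,
            canopy_spad=spad.mean(axis=1).rename("canopy_spad"),
        )

    def subset(self, plot_ids: Sequence[str]) -> "StageDataset":
        ids = list(plot_ids)
        return replace(
            self,
            spad=self.spad.loc[ids],
            vi=self.vi.loc[ids],
            canopy_spad=self.canopy_spad.loc[ids],
        )


@dataclass(frozen=True)
class StageInversionModel:
    """Simple linear inversion SPAD = intercept + slope · VI."""

    stage: str
    vi_name: str
    target: str  # "sensitive_leaf:<position>" or "canopy_mean"
    intercept: float
    slope: float
    train_metrics: dict[str, float]
    test_metrics: dict[str, float] | None
    resubstitution: bool
    train_plots: tuple[str, ...] = ()
    test_plots: tuple[str, ...] = ()

    def predict(self, vi_values) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(vi_values, dtype=float)

    def to_jsonable(self) -> dict:
        return {
            "stage": self.stage, "vi_name": self.vi_name, "target": self.target,
            "intercept": self.intercept, "slope": self.slope,
            "train_metrics": self.train_metrics, "test_metrics": self.test_metrics,
            "resubstitution": self.resubstitution,
        }


def describe_profiles(profiles: Iterable[LeafSPADProfile]) -> pd.DataFrame:
    """Vertical-distribution descriptives per (stage, treatment).

    For each group: the leaf position where the mean profile peaks, the
    mean canopy SPAD, and whether the mean profile rises then falls
    (the bell-shape signature: a strict interior maximum).
    """
    groups: dict[tuple[str, str], list[LeafSPADProfile]] = {}
    for p in profiles:
        groups.setdefault((p.stage, p.n_treatment), []).append(p)
    if not groups:
        raise ValueError("no profiles supplied")
    rows = []
    for (stage, treatment), members in sorted(groups.items()):
        pos, means = mean_profile(members)
        k = int(np.argmax(means))
        bell = bool(
            0 < k < means.size - 1
            and means[k] > means[0]
            and means[k] > means[-1]
        )
        rows.append(
            {
                "stage": stage,
                "n_treatment": treatment,
                "peak_position": int(pos[k]),
                "canopy_spad": float(np.mean([m.canopy_mean for m in members])),
                "bell_shaped": bell,
                "n_plots": len(members),
            }
        )
    return pd.DataFrame(rows).set_index(["stage", "n_treatment"])


def rank_vis(dataset: StageDataset) -> pd.DataFrame:
    """Rank indices by Pearson correlation with canopy-mean SPAD.

    Sorted by descending r, ties broken alphabetically by index name.
    Constant index columns are excluded with a log entry.  Requires at
    least three plots.
    """
    if len(dataset.canopy_spad) < MIN_PLOTS:
        raise ValueError(
            f"VI ranking needs >= {MIN_PLOTS} plots, got {len(dataset.canopy_spad)}"
        )
    rows = []
    for name in dataset.vi.columns:
        col = dataset.vi[name]
        mask = col.notna() & dataset.canopy_spad.notna()
        if mask.sum() < MIN_PLOTS or np.ptp(col[mask].to_numpy()) == 0:
            log.warning("index %s excluded from ranking (constant or too few)", name)
            continue
        res = metrics.pearson_r(col[mask], dataset.canopy_spad[mask])
        rows.append(
            {"vi": name, "r": res.r, "p": res.p_value, "n": res.n,
             "significant": res.significant}
        )
    if not rows:
        raise ValueError("no usable index column")
    out = pd.DataFrame(rows).sort_values(
        ["r", "vi"], ascending=[False, True], kind="mergesort"
    )
    out.insert(0, "stage", dataset.stage)
    out.insert(1, "rank", np.arange(1, len(out) + 1))
    return out.reset_index(drop=True)


def find_sensitive_leaf(
    dataset: StageDataset,
    vi_name: str,
    *,
    use_abs: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Leaf position whose SPAD correlates most with the chosen index.

    Per leaf position, Pearson r between the index and SPAD at that
    position over pairwise-complete plots.  Returns the position with
    the maximum signed r (``use_abs=True`` switches to |r|), ties going
    to the lower position, together with the full per-position
    correlation profile.  Positions with constant SPAD are excluded and
    flagged in the profile.
    """
    if vi_name not in dataset.vi.columns:
        raise ValueError(f"index {vi_name!r} not in dataset")
    if len(dataset.canopy_spad) < MIN_PLOTS:
        raise ValueError(f"need >= {MIN_PLOTS} plots")
    vi = dataset.vi[vi_name]
    rows = []
    for pos in dataset.spad.columns:
        col = dataset.spad[pos]
        mask = col.notna() & vi.notna()
        n = int(mask.sum())
        if n < MIN_PLOTS or np.ptp(col[mask].to_numpy()) == 0 \
                or np.ptp(vi[mask].to_numpy()) == 0:
            rows.append(
                {"leaf_position": int(pos), "r": np.nan, "p": np.nan,
                 "n": n, "usable": False}
            )
            continue
        res = metrics.pearson_r(vi[mask], col[mask])
        rows.append(
            {"leaf_position": int(pos), "r": res.r, "p": res.p_value,
             "n": res.n, "usable": True}
        )
    profile = pd.DataFrame(rows).set_index("leaf_position")
    usable = profile[profile["usable"]]
    if usable.empty:
        raise ValueError("no leaf position with non-constant SPAD across plots")
    score = usable["r"].abs() if use_abs else usable["r"]
    # idxmax on ascending index breaks ties toward the lower position
    best = int(score.idxmax())
    return best, profile


def fit_inversion(
    dataset: StageDataset,
    vi_name: str,
    target: Literal["canopy_mean"] | int,
    train_plots: Sequence[str] | None = None,
    test_plots: Sequence[str] | None = None,
    test_dataset: StageDataset | None = None,
) -> StageInversionModel:
    """Ordinary least squares SPAD = intercept + slope · VI.

    ``target`` is either ``"canopy_mean"`` or an integer leaf position
    (the sensitive leaf).  Training/evaluation plots come from explicit
    plot-id splits of ``dataset``, or from an independent
    ``test_dataset`` (e.g. another season).  With no test set the model
    is evaluated on its own training plots and flagged
    ``resubstitution``.
    """
    def extract(ds: StageDataset, ids: Sequence[str] | None):
        sub = ds if ids is None else ds.subset(ids)
        if target == "canopy_mean":
            y = sub.canopy_spad
        else:
            if target not in sub.spad.columns:
                raise ValueError(f"leaf position {target} not measured at {ds.stage}")
            y = sub.spad[target]
        x = sub.vi[vi_name]
        mask = x.notna() & y.notna()
        return x[mask].to_numpy(float), y[mask].to_numpy(float), tuple(x[mask].index)

    x_tr, y_tr, tr_ids = extract(dataset, train_plots)
    if x_tr.size < MIN_PLOTS:
        raise ValueError(f"need >= {MIN_PLOTS} training plots, got {x_tr.size}")
    if np.ptp(x_tr) == 0:
        raise ValueError(f"index {vi_name!r} constant on the training set")
    slope, intercept = np.polyfit(x_tr, y_tr, 1)

    def evaluate(x, y):
        pred = intercept + slope * x
        out = {"rmse": metrics.rmse(y, pred), "n": int(y.size)}
        if y.size >= 2 and np.ptp(y) > 0:
            out["r2"] = metrics.r_squared(y, pred)
            out["nrmse"] = metrics.nrmse(y, pred)
        else:
            out["r2"] = float("nan")
            out["nrmse"] = float("nan")
        return out

    train_metrics = evaluate(x_tr, y_tr)
    resub = test_plots is None and test_dataset is None
    te_ids: tuple[str, ...] = ()
    if resub:
        test_metrics = None
    else:
        src = test_dataset if test_dataset is not None else dataset
        x_te, y_te, te_ids = extract(src, test_plots)
        if test_plots is not None and test_dataset is None:
            overlap = set(tr_ids) & set(te_ids)
            if overlap:
                raise ValueError(f"train/test plots overlap: {sorted(overlap)[:5]}")
        test_metrics = evaluate(x_te, y_te) if x_te.size else None

    return StageInversionModel(
        stage=dataset.stage,
        vi_name=vi_name,
        target="canopy_mean" if target == "canopy_mean" else f"sensitive_leaf:{target}",
        intercept=float(intercept),
        slope=float(slope),
        train_metrics=train_metrics,
        test_metrics=test_metrics,
        resubstitution=resub,
        train_plots=tr_ids,
        test_plots=te_ids,
    )


def compare_models(
    model_sensitive: StageInversionModel,
    model_canopy: StageInversionModel,
) -> dict[str, float | str]:
    """Relative R² gain of the sensitive-leaf model over the canopy one.

    Both models must share stage, index and evaluation plots.  The
    headline number is (R²_sens − R²_canopy)/R²_canopy on the test set
    (training set under resubstitution), as a percentage rounded to the
    nearest integer, alongside absolute R² and RMSE deltas.
    """
    if model_sensitive.stage != model_canopy.stage:
        raise ValueError("models are for different stages")
    if model_sensitive.vi_name != model_canopy.vi_name:
        raise ValueError("models use different indices")
    if set(model_sensitive.test_plots) != set(model_canopy.test_plots):
        raise ValueError("models were evaluated on different test plots")

    def eval_metrics(m: StageInversionModel) -> dict[str, float]:
        return m.test_metrics if m.test_metrics is not None else m.train_metrics

    ms, mc = eval_metrics(model_sensitive), eval_metrics(model_canopy)
    if mc["r2"] == 0:
        raise ValueError("canopy model R² is zero; relative gain undefined")
    rel = (ms["r2"] - mc["r2"]) / mc["r2"]
    return {
        "stage": model_sensitive.stage,
        "vi_name": model_sensitive.vi_name,
        "r2_sensitive": ms["r2"],
        "r2_canopy": mc["r2"],
        "r2_improvement_pct": int(round(100.0 * rel)),
        "r2_delta": ms["r2"] - mc["r2"],
        "rmse_delta": ms["rmse"] - mc["rmse"],
    }


def predict_spad_map(
    model: StageInversionModel, vi_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-plot predicted SPAD from a fitted inversion model.

    Missing index values propagate to missing predictions; the count is
    logged.
    """
    if model.vi_name not in vi_table.columns:
        raise ValueError(f"index {model.vi_name!r} not in the table")
    vi = vi_table[model.vi_name]
    pred = model.intercept + model.slope * vi
    n_missing = int(pred.isna().sum())
    if n_missing:
        log.warning("%d plot(s) missing %s; predictions absent", n_missing, model.vi_name)
    return pd.DataFrame(
        {"stage": model.stage, "predicted_spad": pred}, index=vi_table.index
    )
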