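"""Published predictive models, nomograms and the selection flowchart.

Ships the four published linear models (two per endpoint: Model 1 uses the
full geometric feature set including the slice-wise Hausdorff distance
metrics; Model 2 only TPS-derivable volumes) and applies the two-stage
patient-selection flowchart:

  stage 1: predicted Pre-RV55 >= omega1 (default 3.0 %) -- patients whose
           pre-implant rectal high-dose volume is already small gain little;
  stage 2: predicted dRV55 >= omega2 (default 3.5 %) -- the spacer must be
           predicted to actually remove a worthwhile amount of dose.

A patient is recommended for implant only if both stages pass; values
exactly at a cutoff pass (a "lower limit" reads as retain >=).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .regression import LinearModel, Term

__all__ = [
    "PublishedModelRegistry",
    "DecisionConfig",
    "DecisionOutcome",
    "NomogramSpec",
    "load_published_models",
    "predict",
    "decide",
    "decide_from_predictions",
    "build_nomogram",
    "cohort_decision_summary",
    "plot_nomogram",
]

#: predicted dRV55 above the largest observed reduction carries large error
DELTA_EXTRAPOLATION_LIMIT = 10.0


class PublishedModelRegistry:
    """Immutable registry of the published models and cohort summaries."""

    def __init__(self, payload: dict):
        self._payload = payload
        self._models = {}
        for key, spec in payload["models"].items():
            terms = tuple(
                Term(t["name"], float(t["beta"]), float(t["se"]))
                for t in spec["terms"]
            )
            self._models[key] = LinearModel(
                dependent=spec["dependent"],
                intercept=Term(
                    "const", float(spec["intercept"]["est"]), float(spec["intercept"]["se"])
                ),
                terms=terms,
                r_squared=float(spec["r_squared"]),
                p_value=float(spec["p_value_upper"]),
                n=int(payload["n"]),
            )

    def model(self, dependent: str, model_choice: int = 2) -> LinearModel:
        """Published model for 'delta_rv55_pct' or 'pre_rv55_pct'."""
        stem = {"delta_rv55_pct": "delta_rv55", "pre_rv55_pct": "pre_rv55"}[dependent]
        key = f"{stem}_model{model_choice}"
        if key not in self._models:
            raise KeyError(f"no published model '{key}'")
        if key == "delta_rv55_model1":
            warnings.warn(
                "dRV55 Model 1 printed coefficients are inconsistent with the "
                "OLS centroid identity at the cohort means; prefer Model 2",
                stacklevel=2,
            )
        return self._models[key]

    def model_stats(self, dependent: str, model_choice: int = 2) -> dict:
        stem = {"delta_rv55_pct": "delta_rv55", "pre_rv55_pct": "pre_rv55"}[dependent]
        return dict(self._payload["models"][f"{stem}_model{model_choice}"])

    def pearson(self, dependent: str) -> dict:
        """Published Pearson correlations of each candidate with an endpoint."""
        return dict(self._payload["pearson"][dependent])

    def feature_summary(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self._payload["feature_summary"], orient="index")

    def endpoint_summary(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self._payload["endpoint_summary"], orient="index")

    def feature_ranges(self) -> dict:
        return {
            name: (row["min"], row["max"])
            for name, row in self._payload["feature_summary"].items()
        }

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self._payload))


def load_published_models() -> PublishedModelRegistry:
    """Load the versioned published-model registry shipped with the package."""
    text = resources.files("spacerselect").joinpath("data/published_models.json").read_text()
    return PublishedModelRegistry(json.loads(text))


@dataclass(frozen=True)
class DecisionConfig:
    """Cutoffs of the two-stage selection flowchart (percent of rectum volume)."""

    omega1: float = 3.0   # lower limit on predicted Pre-RV55
    omega2: float = 3.5   # lower limit on predicted dRV55
    model_choice: int = 2

    def __post_init__(self):
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("cutoffs must be >= 0")
        if self.model_choice not in (1, 2):
            raise ValueError("model_choice must be 1 or 2")


@dataclass(frozen=True)
class DecisionOutcome:
    predicted_pre_rv55: float
    predicted_delta_rv55: float
    stage1_pass: bool
    stage2_pass: bool
    recommend_implant: bool
    margin_to_cutoffs: float


def predict(
    model: LinearModel,
    f: Mapping[str, float],
    registry: PublishedModelRegistry | None = None,
) -> float:
    """Evaluate a linear model on a feature mapping (percent endpoint).

    Features outside the published training ranges, or a predicted dose
    reduction beyond the largest observed one, trigger extrapolation
    warnings -- the models are only calibrated inside the cohort envelope.
    """
    value = model.predict(f)
    if registry is not None:
        ranges = registry.feature_ranges()
        for t in model.terms:
            lo, hi = ranges.get(t.name, (-np.inf, np.inf))
            v = float(f[t.name])
            if not lo <= v <= hi:
                warnings.warn(
                    f"feature '{t.name}' = {v:.3g} outside the training range "
                    f"[{lo}, {hi}]: extrapolated prediction",
                    stacklevel=2,
                )
    if model.dependent == "delta_rv55_pct" and value > DELTA_EXTRAPOLATION_LIMIT:
        warnings.warn(
            f"predicted dRV55 {value:.2f}% exceeds the largest observed "
            f"reduction (~{DELTA_EXTRAPOLATION_LIMIT:.0f}%): large associated error",
            stacklevel=2,
        )
    return value


def decide_from_predictions(
    pre_rv55: float, delta_rv55: float, cfg: DecisionConfig | None = None
) -> DecisionOutcome:
    """Run the two-stage flowchart on already-predicted endpoints.

    Stage 1 screens Pre-RV55 against omega1; stage 2 screens dRV55 against
    omega2. Both comparisons retain values exactly at the cutoff.
    """
    cfg = DecisionConfig() if cfg is None else cfg
    s1 = pre_rv55 >= cfg.omega1
    s2 = delta_rv55 >= cfg.omega2
    return DecisionOutcome(
        predicted_pre_rv55=pre_rv55,
        predicted_delta_rv55=delta_rv55,
        stage1_pass=s1,
        stage2_pass=s2,
        recommend_implant=s1 and s2,
        margin_to_cutoffs=min(pre_rv55 - cfg.omega1, delta_rv55 - cfg.omega2),
    )


def decide(
    f: Mapping[str, float],
    cfg: DecisionConfig | None = None,
    reg: PublishedModelRegistry | None = None,
) -> DecisionOutcome:
    """Predict both endpoints for a patient and run the selection flowchart."""
    cfg = DecisionConfig() if cfg is None else cfg
    reg = load_published_models() if reg is None else reg
    pre = predict(reg.model("pre_rv55_pct", cfg.model_choice), f, reg)
    delta = predict(reg.model("delta_rv55_pct", cfg.model_choice), f, reg)
    return decide_from_predictions(pre, delta, cfg)


def cohort_decision_summary(
    t: pd.DataFrame,
    cfg: DecisionConfig | None = None,
    reg: PublishedModelRegistry | None = None,
) -> dict:
    """Stage-wise retention counts of the flowchart over a cohort table."""
    if len(t) == 0:
        raise ValueError("cohort table is empty")
    cfg = DecisionConfig() if cfg is None else cfg
    reg = load_published_models() if reg is None else reg
    outcomes = [decide(row, cfg, reg) for row in t.to_dict("records")]
    n = len(outcomes)
    s1 = sum(o.stage1_pass for o in outcomes)
    both = sum(o.recommend_implant for o in outcomes)
    return {
        "n": n,
        "pass_stage1": s1,
        "removed_stage1": n - s1,
        "recommended": both,
        "removed_stage2": s1 - both,
        "fraction_retained": both / n,
    }


# ---------------------------------------------------------------------------
# nomograms

@dataclass(frozen=True)
class NomogramSpec:
    """Machine-readable nomogram: affine point scales per predictor.

    Each predictor maps affinely to points over its stated range, scaled so
    the predictor with the largest contribution span covers 0-100 points;
    the total-points axis maps back to the predicted metric, so predictions
    recovered from points match the underlying linear model exactly (up to
    float rounding).
    """

    dependent: str
    intercept: float
    scales: tuple      # ((name, beta, lo, hi, points_per_unit_contribution_offset), ...)
    points_per_unit: float   # points per unit contribution (K)
    baseline: float          # sum over predictors of min contribution

    def points_for(self, name: str, value: float) -> float:
        for nm, beta, lo, hi, offset in self.scales:
            if nm == name:
                return self.points_per_unit * (beta * value) - offset
        raise KeyError(f"predictor '{name}' not on the nomogram")

    def total_points(self, f: Mapping[str, float]) -> float:
        return sum(self.points_for(nm, float(f[nm])) for nm, *_ in self.scales)

    def prediction_from_points(self, total: float) -> float:
        return self.intercept + self.baseline + total / self.points_per_unit

    def predict(self, f: Mapping[str, float]) -> float:
        return self.prediction_from_points(self.total_points(f))

    def to_dict(self) -> dict:
        return {
            "dependent": self.dependent,
            "intercept": self.intercept,
            "points_per_unit_contribution": self.points_per_unit,
            "baseline_contribution": self.baseline,
            "scales": [
                {
                    "name": nm,
                    "beta": beta,
                    "range": [lo, hi],
                    "points_at_range": [
                        self.points_per_unit * beta * lo - off,
                        self.points_per_unit * beta * hi - off,
                    ],
                }
                for nm, beta, lo, hi, off in self.scales
            ],
        }


def build_nomogram(model: LinearModel, ranges: Mapping[str, tuple]) -> NomogramSpec:
    """Nomogram from a linear model over stated predictor ranges.

    Follows the standard convention: the predictor with the largest
    contribution span |beta| * (hi - lo) spans 0-100 points and the others
    are scaled proportionally. Zero-coefficient predictors are excluded
    (with a warning) since they cannot carry points.
    """
    scales = []
    spans = {}
    for t in model.terms:
        if t.beta == 0:
            warnings.warn(
                f"predictor '{t.name}' has zero coefficient: excluded from nomogram",
                stacklevel=2,
            )
            continue
        lo, hi = ranges[t.name]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid range for '{t.name}': ({lo}, {hi})")
        spans[t.name] = abs(t.beta) * (hi - lo)
        scales.append((t.name, t.beta, float(lo), float(hi)))
    if not spans:
        raise ValueError("model has no nonzero-coefficient predictors")
    k = 100.0 / max(spans.values())
    full = []
    baseline = 0.0
    for name, beta, lo, hi in scales:
        cmin = min(beta * lo, beta * hi)
        baseline += cmin
        full.append((name, beta, lo, hi, k * cmin))  # offset puts min at 0 points
    return NomogramSpec(
        dependent=model.dependent,
        intercept=model.intercept.beta,
        scales=tuple(full),
        points_per_unit=k,
        baseline=baseline,
    )


def plot_nomogram(spec: NomogramSpec, ax=None):
    """Render a nomogram as stacked point scales (matplotlib Axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 1.2 * (len(spec.scales) + 2)))
    n = len(spec.scales)
    max_pts = sum(
        max(spec.points_for(nm, lo), spec.points_for(nm, hi))
        for nm, _, lo, hi, _ in spec.scales
    )
    for row, (nm, beta, lo, hi, _) in enumerate(spec.scales):
        y = n - row
        ticks = np.linspace(lo, hi, 6)
        pts = [spec.points_for(nm, v) for v in ticks]
        ax.plot([min(pts), max(pts)], [y, y], "k-", lw=1)
        for v, p in zip(ticks, pts):
            ax.plot([p, p], [y - 0.05, y + 0.05], "k-", lw=1)
            ax.text(p, y + 0.12, f"{v:g}", ha="center", fontsize=8)
        ax.text(-6, y, nm, ha="right", va="center", fontsize=9)
    # total points -> prediction axis
    total_ticks = np.linspace(0, max_pts, 6)
    preds = [spec.prediction_from_points(tp) for tp in total_ticks]
    ax.plot([0, max_pts], [0, 0], "k-", lw=1)
    for tp, pr in zip(total_ticks, preds):
        ax.plot([tp, tp], [-0.05, 0.05], "k-", lw=1)
        ax.text(tp, -0.25, f"{pr:.1f}", ha="center", fontsize=8)
    ax.text(-6, 0, f"{spec.dependent}", ha="right", va="center", fontsize=9)
    ax.set_ylim(-1, n + 1)
    ax.axis("off")
    return ax
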