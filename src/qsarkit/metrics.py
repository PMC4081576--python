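"""Model evaluation statistics: R, R², MAE, RMSE, and cross-class prediction.

R is the Pearson product-moment correlation between observed and predicted
potency; R² is the coefficient of determination 1 − SSE/SST with
SSE = Σ(obs − pred)² and SST = Σ(obs − mean(obs))².  Note R² here measures
agreement of predictions with observations (it can be negative for a biased
predictor) and is not in general the square of R.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .chemio import Compound, DockingEnergyRecord
    from .model import ModelBundle


class MetricError(ValueError):
    pass


def _as_vectors(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.ndim != 1 or pred.ndim != 1:
        raise MetricError("observed and predicted must be 1-D vectors")
    if obs.shape != pred.shape:
        raise MetricError(f"length mismatch: {obs.shape[0]} vs {pred.shape[0]}")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise MetricError("non-finite values in input")
    return obs, pred


def pearson_r(observed, predicted) -> float:
    """Pearson product-moment correlation between two vectors."""
    obs, pred = _as_vectors(observed, predicted)
    if obs.size < 3:
        raise MetricError(f"need n >= 3 for a correlation, got {obs.size}")
    do = obs - obs.mean()
    dp = pred - pred.mean()
    denom = np.sqrt((do**2).sum() * (dp**2).sum())
    if denom == 0:
        raise MetricError("undefined correlation: constant input vector")
    return float((do * dp).sum() / denom)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SSE/SST."""
    obs, pred = _as_vectors(observed, predicted)
    if obs.size < 2:
        raise MetricError(f"need n >= 2, got {obs.size}")
    sse = float(((obs - pred) ** 2).sum())
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise MetricError("SST = 0: observed values are constant")
    return 1.0 - sse / sst


def mae(observed, predicted) -> float:
    """Mean absolute error."""
    obs, pred = _as_vectors(observed, predicted)
    if obs.size < 1:
        raise MetricError("empty input")
    return float(np.abs(obs - pred).mean())


def rmse(observed, predicted) -> float:
    """Root mean squared error."""
    obs, pred = _as_vectors(observed, predicted)
    if obs.size < 1:
        raise MetricError("empty input")
    return float(np.sqrt(((obs - pred) ** 2).mean()))


@dataclass
class EvaluationReport:
    """R / R² / MAE / RMSE on one evaluation set, with fold bookkeeping."""

    n: int
    R: float
    R2: float
    MAE: float
    RMSE: float
    SSE: float
    SST: float
    label: str = ""
    fold_assignment: dict[str, int] | None = None

    @classmethod
    def from_predictions(
        cls,
        observed,
        predicted,
        label: str = "",
        fold_assignment: Mapping[str, int] | None = None,
    ) -> "EvaluationReport":
        obs, pred = _as_vectors(observed, predicted)
        sse = float(((obs - pred) ** 2).sum())
        sst = float(((obs - obs.mean()) ** 2).sum())
        return cls(
            n=int(obs.size),
            R=pearson_r(obs, pred),
            R2=r_squared(obs, pred),
            MAE=mae(obs, pred),
            RMSE=rmse(obs, pred),
            SSE=sse,
            SST=sst,
            label=label,
            fold_assignment=dict(fold_assignment) if fold_assignment is not None else None,
        )

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "n": self.n,
            "R": self.R,
            "R2": self.R2,
            "MAE": self.MAE,
            "RMSE": self.RMSE,
            "SSE": self.SSE,
            "SST": self.SST,
        }
        if self.fold_assignment is not None:
            d["fold_assignment"] = self.fold_assignment
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_table_row(self) -> str:
        """One line in the R / R² / MAE / RMSE column layout."""
        return (
            f"{self.label:<28s} {self.n:>5d} {self.R:>8.3f} {self.R2:>8.3f} "
            f"{self.MAE:>8.3f} {self.RMSE:>8.3f}"
        )

    @staticmethod
    def table_header() -> str:
        return f"{'dataset':<28s} {'n':>5s} {'R':>8s} {'R2':>8s} {'MAE':>8s} {'RMSE':>8s}"


def cross_predict(
    bundle: "ModelBundle",
    compounds: Sequence["Compound"],
    energies: Sequence["DockingEnergyRecord"] | None = None,
) -> EvaluationReport:
    """Apply a trained model to another compound class and evaluate.

    Recomputes the bundle's descriptor families for the given compounds
    (appending docking energies if the bundle selected any energy features)
    and scores predictions against the compounds' observed pIC50.  The report
    label carries (model scope, evaluated classes).
    """
    from .chemio import ENERGY_COLUMNS
    from .descriptors import append_docking_columns, compute_descriptor_matrix

    if not compounds:
        raise MetricError("no compounds to evaluate")
    matrix = compute_descriptor_matrix(compounds, bundle.descriptor_families)
    energy_features = [f for f in bundle.feature_names if f in ENERGY_COLUMNS]
    if energy_features:
        if energies is None:
            raise MetricError(
                f"model uses energy features {energy_features} but no energies given"
            )
        matrix = append_docking_columns(matrix, energies, columns=energy_features)
    pred = bundle.predict(matrix)
    obs = np.array([c.pic50 for c in compounds])
    classes = sorted({c.target_class for c in compounds})
    return EvaluationReport.from_predictions(
        obs, pred, label=f"model={bundle.model_scope} on class={'+'.join(classes)}"
    )
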