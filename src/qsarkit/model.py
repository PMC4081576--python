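"""Epsilon-SVR QSAR models: training, cross-validation, persistence, protocols.

Features are standardised (stored center/scale) before fitting an
epsilon-insensitive support vector regression.  The fitted model is kept as
its support vectors, dual coefficients and bias, so prediction is an explicit
kernel evaluation and a saved model (plain JSON) reproduces predictions
exactly.  ``run_protocol`` chains descriptor computation, staged feature
selection and evaluation into the wild / mutant / hybrid modelling protocols,
reporting whole-set, cross-validated-train and held-out-validation metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import selection as _selection
from .chemio import Compound, DockingEnergyRecord, split_dataset
from .descriptors import (
    DescriptorMatrix,
    append_docking_columns,
    compute_descriptor_matrix,
    screen_energy_descriptors,
    FAMILIES,
)
from .metrics import EvaluationReport

MODEL_SCOPES = ("wild", "mutant", "hybrid")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class SvrConfig:
    """Hyperparameters of the SVR engine and its cross-validation."""

    kernel: Literal["linear", "polynomial", "rbf"] = "rbf"
    C: float = 10.0
    epsilon: float = 0.1
    gamma: float | None = None  # None -> 1 / n_features
    degree: int = 3
    coef0: float = 0.0
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.epsilon <= 0:
            raise ModelError("C and epsilon must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ModelError("gamma must be positive")
        if self.cv_folds < 2:
            raise ModelError("cv_folds must be >= 2")
        if self.kernel not in ("linear", "polynomial", "rbf"):
            raise ModelError(f"unknown kernel {self.kernel!r}")

    def resolved_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SvrConfig":
        return cls(**d)


@dataclass
class ModelBundle:
    """A fitted SVR with its scaling, feature list and provenance metadata."""

    feature_names: list[str]
    center: np.ndarray  # per-feature mean
    scale: np.ndarray  # per-feature std
    support_vectors: np.ndarray  # in scaled feature space
    dual_coef: np.ndarray  # one weight per support vector
    intercept: float
    kernel: str
    gamma: float
    degree: int
    coef0: float
    model_scope: str = "wild"
    config: SvrConfig | None = None
    descriptor_families: tuple[str, ...] = FAMILIES
    metadata: dict = field(default_factory=dict)

    def _kernel_matrix(self, X: np.ndarray) -> np.ndarray:
        sv = self.support_vectors
        if self.kernel == "linear":
            return X @ sv.T
        if self.kernel == "polynomial":
            return (self.gamma * (X @ sv.T) + self.coef0) ** self.degree
        if self.kernel == "rbf":
            d2 = (
                (X**2).sum(axis=1)[:, None]
                + (sv**2).sum(axis=1)[None, :]
                - 2.0 * X @ sv.T
            )
            return np.exp(-self.gamma * np.clip(d2, 0.0, None))
        raise ModelError(f"unknown kernel {self.kernel!r}")

    def predict(self, matrix: DescriptorMatrix | np.ndarray) -> np.ndarray:
        """Predict pIC50 for each compound; columns are aligned by name."""
        if isinstance(matrix, DescriptorMatrix):
            missing = [c for c in self.feature_names if c not in matrix.data.columns]
            if missing:
                raise ModelError(f"missing feature column(s): {missing}")
            X = matrix.data[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(matrix, dtype=float)
            if X.ndim != 2 or X.shape[1] != len(self.feature_names):
                raise ModelError(
                    f"expected a (n, {len(self.feature_names)}) array, got {X.shape}"
                )
        Xs = (X - self.center) / self.scale
        return self._kernel_matrix(Xs) @ self.dual_coef + self.intercept

    def save(self, path) -> None:
        payload = {
            "format": "qsarkit-model/1",
            "feature_names": self.feature_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "kernel": self.kernel,
            "gamma": self.gamma,
            "degree": self.degree,
            "coef0": self.coef0,
            "model_scope": self.model_scope,
            "config": self.config.to_dict() if self.config else None,
            "descriptor_families": list(self.descriptor_families),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path) as fh:
            p = json.load(fh)
        if p.get("format") != "qsarkit-model/1":
            raise ModelError(f"{path}: not a qsarkit model file")
        return cls(
            feature_names=list(p["feature_names"]),
            center=np.array(p["center"], dtype=float),
            scale=np.array(p["scale"], dtype=float),
            support_vectors=np.array(p["support_vectors"], dtype=float),
            dual_coef=np.array(p["dual_coef"], dtype=float),
            intercept=float(p["intercept"]),
            kernel=p["kernel"],
            gamma=float(p["gamma"]),
            degree=int(p["degree"]),
            coef0=float(p["coef0"]),
            model_scope=p["model_scope"],
            config=SvrConfig.from_dict(p["config"]) if p["config"] else None,
            descriptor_families=tuple(p["descriptor_families"]),
            metadata=p["metadata"],
        )


def train_svr(
    matrix: DescriptorMatrix,
    activity,
    config: SvrConfig | None = None,
    *,
    model_scope: str = "wild",
    metadata: dict | None = None,
    allow_constant: bool = False,
) -> ModelBundle:
    """Fit an epsilon-SVR on standardised features.

    Zero-variance features are an error at this stage — the selection
    pipeline is responsible for removing them first.
    """
    config = config or SvrConfig()
    X = matrix.values
    y = np.asarray(activity, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ModelError(f"need >= 2 compounds to train, got {n}")
    if y.shape != (n,):
        raise ModelError(f"activity must be a length-{n} vector")
    if np.isnan(X).any():
        raise ModelError("descriptor matrix contains missing values")

    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    dead_idx = np.where(np.isclose(scale, 0.0))[0]
    if dead_idx.size:
        if not allow_constant:
            dead = [matrix.column_names[j] for j in dead_idx]
            raise ModelError(f"zero-variance feature(s) at training time: {dead}")
        scale = scale.copy()
        scale[dead_idx] = 1.0  # fold-constant feature: pass through uncentered noise
    Xs = (X - center) / scale

    meta = dict(metadata or {})
    try:  # descriptor values are engine-version-dependent; record provenance
        import rdkit

        meta.setdefault("rdkit_version", rdkit.__version__)
    except Exception:  # pragma: no cover
        pass

    gamma = config.resolved_gamma(p)
    sk_kernel = {"linear": "linear", "polynomial": "poly", "rbf": "rbf"}[config.kernel]
    svr = SVR(
        kernel=sk_kernel,
        C=config.C,
        epsilon=config.epsilon,
        gamma=gamma,
        degree=config.degree,
        coef0=config.coef0,
    )
    svr.fit(Xs, y)

    return ModelBundle(
        feature_names=list(matrix.column_names),
        center=center,
        scale=scale,
        support_vectors=np.asarray(svr.support_vectors_, dtype=float),
        dual_coef=np.asarray(svr.dual_coef_, dtype=float).ravel(),
        intercept=float(np.asarray(svr.intercept_).ravel()[0]),
        kernel=config.kernel,
        gamma=gamma,
        degree=config.degree,
        coef0=config.coef0,
        model_scope=model_scope,
        config=config,
        metadata=meta,
    )


def predict(bundle: ModelBundle, matrix: DescriptorMatrix) -> np.ndarray:
    """Functional alias for :meth:`ModelBundle.predict`."""
    return bundle.predict(matrix)


def cross_validate(
    matrix: DescriptorMatrix,
    activity,
    config: SvrConfig | None = None,
) -> EvaluationReport:
    """k-fold cross-validation with pooled out-of-fold predictions.

    The fold partition is determined by ``config.seed`` and the number of
    compounds only, so subsets of the same compound set share folds.
    """
    config = config or SvrConfig()
    X = matrix.values
    y = np.asarray(activity, dtype=float)
    n = X.shape[0]
    if config.cv_folds > n:
        raise ModelError(f"cv_folds={config.cv_folds} exceeds n={n}")
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    pooled = np.empty(n)
    fold_of: dict[str, int] = {}
    ids = matrix.compound_ids
    for fold, (tr, te) in enumerate(kf.split(X)):
        if len(te) < 1 or len(tr) < 2:
            raise ModelError(f"fold {fold} too small (train={len(tr)}, test={len(te)})")
        bundle = train_svr(
            _rewrap(matrix.data.iloc[tr], matrix), y[tr], config, allow_constant=True
        )
        pooled[te] = bundle.predict(_rewrap(matrix.data.iloc[te], matrix))
        for i in te:
            fold_of[ids[i]] = fold
    return EvaluationReport.from_predictions(
        y, pooled, label=f"{config.cv_folds}-fold CV", fold_assignment=fold_of
    )


def _rewrap(df, parent: DescriptorMatrix) -> DescriptorMatrix:
    return DescriptorMatrix(
        data=df, provenance={c: parent.provenance[c] for c in df.columns}
    )


# ---------------------------------------------------------------------------
# end-to-end protocols


@dataclass(frozen=True)
class ProtocolConfig:
    """Controls for one end-to-end modelling run."""

    families: tuple[str, ...] = FAMILIES
    corr_cutoff: float = 0.9
    energy_screen_cutoff: float = 0.9
    fraction_valid: float = 0.2
    explicit_counts: tuple[int, int] | None = None
    svr: SvrConfig = field(default_factory=SvrConfig)
    seed: int = 0
    run_f_stepping: bool = True


@dataclass
class ProtocolResult:
    bundle: ModelBundle  # trained on the training split (used for validation)
    bundle_whole: ModelBundle  # trained on the whole dataset
    reports: dict[str, EvaluationReport]  # whole / train / valid
    selection_reports: list
    selected_features: list[str]
    split: object


def run_protocol(
    compounds: Sequence[Compound],
    energies: Sequence[DockingEnergyRecord] | None = None,
    protocol: str = "wild",
    config: ProtocolConfig | None = None,
) -> ProtocolResult:
    """Execute one modelling protocol end-to-end.

    Steps: filter compounds to the protocol scope (hybrid = both classes),
    80/20 split, descriptor computation, optional docking-energy fusion
    (energies pre-screened for pairwise correlation), staged feature
    selection on the whole scoped dataset (the descriptor set is fixed once
    and reused by every evaluation, as in classical QSAR practice; note this
    means the validation metrics assess the model fit, not a
    selection-blind generalisation estimate), then three evaluations
    mirroring a whole / train / valid report layout:

    * ``whole`` — model trained on all compounds, evaluated on all (fit),
    * ``train`` — pooled k-fold cross-validation on the training split,
    * ``valid`` — training-split model applied to the held-out validation set.
    """
    config = config or ProtocolConfig()
    if protocol not in MODEL_SCOPES:
        raise ModelError(f"unknown protocol {protocol!r}; choose from {MODEL_SCOPES}")
    if protocol == "hybrid":
        pool = list(compounds)
    else:
        pool = [c for c in compounds if c.target_class == protocol]
    if not pool:
        raise ModelError(f"no compounds with class {protocol!r}")

    split = split_dataset(
        pool,
        fraction_valid=config.fraction_valid,
        seed=config.seed,
        explicit_counts=config.explicit_counts,
    )
    by_id = {c.compound_id: c for c in pool}
    train_compounds = [by_id[i] for i in split.train_ids]

    matrix = compute_descriptor_matrix(pool, config.families)
    selection_reports = []
    if energies is not None:
        retained_terms, _corr = screen_energy_descriptors(
            energies, pairwise_cutoff=config.energy_screen_cutoff
        )
        matrix = append_docking_columns(matrix, energies, columns=retained_terms)

    y_all = np.array([by_id[i].pic50 for i in matrix.compound_ids])
    train_matrix = _rewrap(matrix.data.loc[list(split.train_ids)], matrix)
    y_train = np.array([by_id[i].pic50 for i in split.train_ids])

    selected, selection_reports = _selection.select_features(
        matrix,
        y_all,
        corr_cutoff=config.corr_cutoff,
        trainer_config=config.svr,
        seed=config.seed,
        run_f_stepping=config.run_f_stepping,
    )

    sel_train = train_matrix.subset(selected)
    sel_all = _rewrap(matrix.data[selected], matrix)
    sel_valid = _rewrap(matrix.data.loc[list(split.valid_ids), selected], matrix)
    y_valid = np.array([by_id[i].pic50 for i in split.valid_ids])

    meta = {"protocol": protocol, "seed": config.seed, "n": len(pool)}
    # a whole-set-selected feature may lose its variance on the 80% split;
    # tolerate it there (the whole-set model still uses it)
    bundle_train = train_svr(
        sel_train, y_train, config.svr, model_scope=protocol, metadata=meta,
        allow_constant=True,
    )
    bundle_whole = train_svr(
        sel_all, y_all, config.svr, model_scope=protocol, metadata=meta
    )

    reports = {
        "whole": EvaluationReport.from_predictions(
            y_all, bundle_whole.predict(sel_all), label=f"{protocol}_whole (fit)"
        ),
        "train": cross_validate(sel_train, y_train, config.svr),
        "valid": EvaluationReport.from_predictions(
            y_valid, bundle_train.predict(sel_valid), label=f"{protocol}_valid"
        ),
    }
    reports["train"].label = f"{protocol}_train ({config.svr.cv_folds}-fold CV)"

    return ProtocolResult(
        bundle=bundle_train,
        bundle_whole=bundle_whole,
        reports=reports,
        selection_reports=selection_reports,
        selected_features=selected,
        split=split,
    )
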