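"""Double machine learning for the partially linear panel model.

Estimates the climate coefficient theta0 in

    Y_it = theta0 * D_it + g(X_it) + U_it,      E[U | D, X] = 0,
    D_it = m(X_it) + V_it,                      E[V | X] = 0,

by cross-fitted partialling-out: flexible learners estimate the nuisance
regressions g (outcome on controls) and m (treatment on controls)
out-of-fold, and the orthogonalized estimator

    theta_hat = ( sum_i V_hat_i D_i )^{-1}  sum_i V_hat_i (Y_i - g_hat_i)

uses the treatment residual as an instrument for the treatment, making the
score Neyman-orthogonal to first-order nuisance errors.  Standard errors
come from the influence-function (sandwich) variance of the score
psi_i = V_hat_i (Y_i - g_hat_i - theta_hat D_i).  Sample splitting is
stratified by unit (each fold receives each unit's years proportionally)
and repeated; repetitions are aggregated by the median with the standard
median-aggregation variance adjustment.

A multi-treatment variant residualizes several treatment columns at once
and solves the residual-on-residual least-squares system, which is how the
moderation design (climate + moderator + centered interaction) is
estimated.  Fixed effects enter as dummy columns appended to the controls
fed to the nuisance learners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .panel_ops import CONTROLS, OUTCOME, PanelDataset, UNIT, YEAR

__all__ = [
    "LearnerSpec",
    "DMLConfig",
    "DMLResults",
    "PanelDML",
    "crossfit_predict",
    "encode_fixed_effects",
    "dml_plr",
    "dml_multi_treatment",
    "make_interaction",
]

FE_MODES = ("none", "time", "unit", "two_way", "time_location_interaction")


class _MeanOnly:
    """Predicts the training-sample mean; the degenerate nuisance learner."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


@dataclass
class LearnerSpec:
    """Nuisance learner configuration.

    Random-forest defaults: 100 trees, unbounded depth, sqrt(p) features
    per split, minimum leaf size 1.  Neural-net defaults: one hidden layer
    of 100 ReLU units with a linear output (a three-layer network), Adam
    with learning rate 0.001, 100 epochs, L2 penalty 1e-4; features and
    target are standardized inside each training fold.  The ridge and
    mean-only kinds exist for closed-form checks.
    """

    kind: str = "random_forest"
    # random forest
    n_trees: int = 100
    max_depth: int | None = None
    features_per_split: str | int = "sqrt"
    min_leaf: int = 1
    # neural net
    hidden_units: int = 100
    learning_rate: float = 0.001
    epochs: int = 100
    l2_penalty: float = 0.0001
    # ridge
    ridge_alpha: float = 1e-6

    def validate(self) -> "LearnerSpec":
        if self.kind not in ("random_forest", "neural_net", "ridge_linear", "mean_only"):
            raise ValueError(f"unknown learner kind {self.kind!r}")
        return self

    def build(self, seed: int | None = None):
        self.validate()
        if self.kind == "mean_only":
            return _MeanOnly()
        if self.kind == "ridge_linear":
            return Ridge(alpha=self.ridge_alpha)
        if self.kind == "random_forest":
            return RandomForestRegressor(
                n_estimators=self.n_trees,
                max_depth=self.max_depth,
                max_features=self.features_per_split,
                min_samples_leaf=self.min_leaf,
                random_state=seed,
                n_jobs=1,
            )
        net = MLPRegressor(
            hidden_layer_sizes=(self.hidden_units,),
            activation="relu",
            solver="adam",
            learning_rate_init=self.learning_rate,
            max_iter=self.epochs,
            alpha=self.l2_penalty,
            random_state=seed,
        )
        return TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), net),
            transformer=StandardScaler(),
        )


@dataclass
class DMLConfig:
    """Cross-fitting configuration: folds, repetitions, learner, FE mode."""

    n_folds: int = 5
    n_repetitions: int = 101
    learner: LearnerSpec = field(default_factory=LearnerSpec)
    fe_mode: str = "none"
    aggregation: str = "median"
    seed: int = 0

    def validate(self) -> "DMLConfig":
        if self.n_folds < 2:
            raise ValueError("DMLConfig.n_folds must be >= 2")
        if self.n_repetitions < 1 or self.n_repetitions % 2 == 0:
            raise ValueError("DMLConfig.n_repetitions must be a positive odd count")
        if self.fe_mode not in FE_MODES:
            raise ValueError(f"DMLConfig.fe_mode must be one of {FE_MODES}")
        if self.aggregation != "median":
            raise ValueError("DMLConfig.aggregation: only 'median' is supported")
        self.learner.validate()
        return self


def crossfit_predict(
    learner: LearnerSpec,
    features: np.ndarray,
    target: np.ndarray,
    folds: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold nuisance predictions.

    The prediction for sample i comes from a learner trained only on
    samples outside i's fold.  Deterministic given ``seed``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    folds = np.asarray(folds)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != y.size or folds.size != y.size:
        raise ValueError("features, target and folds must have matching length")
    labels = np.unique(folds)
    if any(np.sum(folds == f) == 0 for f in labels):
        raise ValueError("every fold must be nonempty")
    preds = np.empty_like(y)
    children = np.random.SeedSequence(seed).spawn(len(labels))
    for child, f in zip(children, labels):
        test = folds == f
        train = ~test
        if train.sum() < 2:
            raise ValueError(f"fold {f!r} leaves fewer than 2 training samples")
        est = learner.build(int(child.generate_state(1)[0] % (2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(x[train], y[train])
            preds[test] = est.predict(x[test])
    return preds


def encode_fixed_effects(
    panel: PanelDataset | pd.DataFrame,
    fe_mode: str,
    controls: Sequence[str] = CONTROLS,
    group_col: str = "major_producer",
) -> pd.DataFrame:
    """Controls augmented with fixed-effect dummy columns.

    ``none`` leaves the control grid unchanged; ``time`` appends
    (n_years - 1) year dummies; ``unit`` appends (n_units - 1) unit
    dummies; ``two_way`` both.  ``time_location_interaction`` appends
    (group x year) dummies built from a coarse unit grouping
    (default: the major-producer flag), dropping one level.
    """
    if fe_mode not in FE_MODES:
        raise ValueError(f"unknown fe_mode {fe_mode!r}")
    df = panel.frame if isinstance(panel, PanelDataset) else panel
    out = df[list(controls)].copy()
    if fe_mode in ("time", "two_way"):
        dum = pd.get_dummies(df[YEAR].astype("category"), prefix="fe_year", drop_first=True, dtype=float)
        out = pd.concat([out, dum], axis=1)
    if fe_mode in ("unit", "two_way"):
        dum = pd.get_dummies(df[UNIT].astype("category"), prefix="fe_unit", drop_first=True, dtype=float)
        out = pd.concat([out, dum], axis=1)
    if fe_mode == "time_location_interaction":
        combo = df[group_col].astype(str) + "_" + df[YEAR].astype(str)
        dum = pd.get_dummies(combo.astype("category"), prefix="fe_tl", drop_first=True, dtype=float)
        out = pd.concat([out, dum], axis=1)
    return out


def _stratified_folds(units: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels stratified by unit: each fold spans units proportionally."""
    folds = np.empty(units.size, dtype=int)
    for u in pd.unique(units):
        rows = np.where(units == u)[0]
        rows = rng.permutation(rows)
        offset = int(rng.integers(n_folds))
        folds[rows] = (offset + np.arange(rows.size)) % n_folds
    return folds


def make_interaction(
    df: pd.DataFrame, var1: str, var2: str, center: bool = True
) -> tuple[pd.DataFrame, str]:
    """Append a product column var1 x var2, mean-centering both by default.

    Centering keeps the main effects interpretable as effects at the
    sample mean of the other factor.
    """
    name = f"{var1}_x_{var2}"
    out = df.copy()
    a = out[var1].to_numpy(dtype=float)
    b = out[var2].to_numpy(dtype=float)
    if center:
        a = a - a.mean()
        b = b - b.mean()
    out[name] = a * b
    return out, name


@dataclass
class DMLResults:
    """Point estimates, influence-function SEs and diagnostics."""

    theta: pd.Series
    se: pd.Series
    t_stat: pd.Series
    p_value: pd.Series
    per_rep_thetas: pd.DataFrame
    n_obs: int
    residual_diagnostics: dict
    config: DMLConfig
    outcome: str = OUTCOME

    @property
    def treatments(self) -> list[str]:
        return list(self.theta.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.theta - z * self.se, "upper": self.theta + z * self.se}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatments,
                "theta": self.theta.values,
                "se": self.se.values,
                "t": self.t_stat.values,
                "p": self.p_value.values,
                "n": self.n_obs,
                "folds": self.config.n_folds,
                "reps": self.config.n_repetitions,
                "learner": self.config.learner.kind,
                "fe_mode": self.config.fe_mode,
            }
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Partially linear DML results",
            "=" * 72,
            f"outcome: {self.outcome}   n = {self.n_obs}   folds = {self.config.n_folds}"
            f"   reps = {self.config.n_repetitions}",
            f"learner: {self.config.learner.kind}   fixed effects: {self.config.fe_mode}",
            "-" * 72,
            f"{'treatment':<16s}{'coef':>11s}{'std err':>11s}{'t':>9s}{'P>|t|':>9s}"
            f"{'[0.025':>10s}{'0.975]':>10s}",
        ]
        for name in self.treatments:
            lines.append(
                f"{name:<16s}{self.theta[name]:>11.4f}{self.se[name]:>11.4f}"
                f"{self.t_stat[name]:>9.2f}{self.p_value[name]:>9.3f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        return "\n".join(lines)


class PanelDML:
    """Partially linear DML model over a unit-year panel.

    Parameters
    ----------
    data
        Panel with outcome, treatment(s) and control columns; unit and
        year identifier columns are required for stratified folds and
        fixed-effect encoding.  Rows with missing values in any used
        column are rejected — interpolate first.
    treatments
        One name (scalar theta) or several (joint residual-on-residual
        system, e.g. climate + moderator + interaction).
    """

    def __init__(
        self,
        data: PanelDataset | pd.DataFrame,
        outcome: str = OUTCOME,
        treatments: str | Sequence[str] = "TEMP",
        controls: Sequence[str] = CONTROLS,
        group_col: str = "major_producer",
    ):
        df = data.frame if isinstance(data, PanelDataset) else data
        self.treatments = [treatments] if isinstance(treatments, str) else list(treatments)
        self.outcome = outcome
        self.controls = list(controls)
        used = [outcome, *self.treatments, *self.controls, UNIT, YEAR]
        missing_cols = [c for c in used if c not in df.columns]
        if missing_cols:
            raise KeyError(f"panel is missing columns: {missing_cols}")
        if df[used].isna().any().any():
            bad = [c for c in used if df[c].isna().any()]
            raise ValueError(f"missing values in columns {bad}; interpolate before estimation")
        self.data = df.reset_index(drop=True)
        self.group_col = group_col

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PanelDML":
        return cls(df, **kwargs)

    def _single_rep(
        self,
        y: np.ndarray,
        d: np.ndarray,
        x: np.ndarray,
        folds: np.ndarray,
        seed: int,
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """One repetition: cross-fit nuisances, solve the orthogonal score."""
        cfg = self.config
        n, k = d.shape
        seeds = np.random.SeedSequence(seed).spawn(k + 1)

        def _seed_int(ss):
            return int(ss.generate_state(1)[0] % (2**31))

        g_hat = crossfit_predict(cfg.learner, x, y, folds, seed=_seed_int(seeds[0]))
        m_hat = np.column_stack(
            [
                crossfit_predict(cfg.learner, x, d[:, j], folds, seed=_seed_int(seeds[j + 1]))
                for j in range(k)
            ]
        )
        v = d - m_hat
        j_mat = v.T @ d / n
        y_res = y - g_hat
        scale = max(float(np.mean(d**2)), 1e-300)
        if k == 1:
            # residual treatment variance ~ 0 means the controls fully
            # explain the treatment and theta is not identified
            if np.mean(v[:, 0] ** 2) < 1e-12 * scale or abs(j_mat[0, 0]) < 1e-12 * scale:
                raise ValueError(
                    f"treatment {self.treatments[0]!r} is fully explained by the "
                    "controls (residual-treatment covariance ~ 0): theta not identified"
                )
            theta = np.array([float(v[:, 0] @ y_res) / float(v[:, 0] @ d[:, 0])])
        else:
            if np.linalg.matrix_rank(v, tol=1e-8 * np.sqrt(scale)) < k:
                corr = np.corrcoef(v, rowvar=False)
                pairs = [
                    (self.treatments[a], self.treatments[b])
                    for a in range(k)
                    for b in range(a + 1, k)
                    if abs(corr[a, b]) > 0.999
                ]
                raise ValueError(
                    f"residualized treatments are rank deficient; collinear: {pairs or self.treatments}"
                )
            theta = np.linalg.solve(j_mat, v.T @ y_res / n)
        resid = y_res - d @ theta
        psi = v * resid[:, None]
        s_mat = psi.T @ psi / n
        j_inv = np.linalg.inv(j_mat)
        cov = j_inv @ s_mat @ j_inv.T / n
        diag = {
            "mean_outcome_residual": float(y_res.mean()),
            "mean_treatment_residual": [float(m) for m in v.mean(axis=0)],
            "max_abs_score_mean": float(np.max(np.abs(psi.mean(axis=0)))),
        }
        return theta, np.diag(cov).copy(), diag

    def fit(
        self,
        config: DMLConfig | None = None,
        fold_assignment: np.ndarray | None = None,
    ) -> DMLResults:
        """Cross-fitted estimation with repeated splits and median aggregation.

        ``fold_assignment`` overrides the stratified fold draw with a fixed
        labelling (used for exact reproducibility and closed-form checks);
        it applies to every repetition.
        """
        self.config = cfg = (config or DMLConfig()).validate()
        df = self.data
        y = df[self.outcome].to_numpy(dtype=float)
        d = df[self.treatments].to_numpy(dtype=float)
        x = encode_fixed_effects(df, cfg.fe_mode, self.controls, self.group_col).to_numpy(
            dtype=float
        )
        units = df[UNIT].to_numpy()
        n, k = d.shape

        thetas = np.empty((cfg.n_repetitions, k))
        variances = np.empty((cfg.n_repetitions, k))
        rep_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_repetitions)
        diag: dict = {}
        for r, ss in enumerate(rep_seeds):
            rng = np.random.default_rng(ss)
            folds = (
                fold_assignment
                if fold_assignment is not None
                else _stratified_folds(units, cfg.n_folds, rng)
            )
            theta_r, var_r, diag = self._single_rep(
                y, d, x, np.asarray(folds), int(ss.generate_state(1)[0] % (2**31))
            )
            thetas[r] = theta_r
            variances[r] = var_r

        theta_med = np.median(thetas, axis=0)
        # median-aggregation variance: add each repetition's squared deviation
        # from the median estimate, then take the median
        var_agg = np.median(variances + (thetas - theta_med) ** 2, axis=0)
        se = np.sqrt(var_agg)
        t = theta_med / se
        p = 2 * stats.norm.sf(np.abs(t))
        idx = pd.Index(self.treatments, name="treatment")
        return DMLResults(
            theta=pd.Series(theta_med, index=idx),
            se=pd.Series(se, index=idx),
            t_stat=pd.Series(t, index=idx),
            p_value=pd.Series(p, index=idx),
            per_rep_thetas=pd.DataFrame(thetas, columns=idx),
            n_obs=n,
            residual_diagnostics=diag,
            config=cfg,
            outcome=self.outcome,
        )


def dml_plr(
    panel: PanelDataset | pd.DataFrame,
    outcome: str = OUTCOME,
    treatment: str = "TEMP",
    controls: Sequence[str] = CONTROLS,
    config: DMLConfig | None = None,
    fold_assignment: np.ndarray | None = None,
) -> DMLResults:
    """Single-treatment partially linear DML estimate."""
    model = PanelDML(panel, outcome=outcome, treatments=treatment, controls=controls)
    return model.fit(config, fold_assignment=fold_assignment)


def dml_multi_treatment(
    panel: PanelDataset | pd.DataFrame,
    outcome: str = OUTCOME,
    treatments: Sequence[str] = ("TEMP", "SID", "SID_x_TEMP"),
    controls: Sequence[str] = CONTROLS,
    config: DMLConfig | None = None,
) -> DMLResults:
    """Joint DML for several treatment columns (moderation designs).

    Residualizes each treatment and the outcome by cross-fitting, then
    solves the residual-on-residual least-squares system; one coefficient
    row per treatment (main effect, moderator, interaction).
    """
    model = PanelDML(panel, outcome=outcome, treatments=list(treatments), controls=controls)
    return model.fit(config)
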