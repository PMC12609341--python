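"""Study orchestration: chain the pipeline stages into the standard designs.

A :class:`StudyConfig` describes one end-to-end run: data source
(synthetic or CSV), index construction, the main estimation grid
(two climate treatments x four fixed-effect configurations), and the
optional robustness, heterogeneity and moderation designs.  ``run_study``
executes the requested designs and returns formatted coefficient tables
(coefficient, t statistic in parentheses, significance stars at the
10/5/1% two-sided normal thresholds) plus a tidy machine-readable results
frame and a JSON-able manifest from which the run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .dml import DMLConfig, DMLResults, LearnerSpec, dml_multi_treatment, dml_plr, make_interaction
from .indicators import load_indicator_specs
from .panel_ops import (
    CONTROLS,
    MODERATOR,
    OUTCOME,
    PanelDataset,
    SubgroupRule,
    exclude_units,
    interpolate_missing,
    lag_controls,
    split_subgroup,
    winsorize,
)
from .ppc import GAConfig, compute_resilience_index
from .synthetic import SyntheticConfig, generate_panel

__all__ = ["StudyConfig", "StudyBundle", "validate_config", "run_study", "significance_stars"]

MAIN_FE_MODES = ("none", "time", "unit", "two_way")
LAGGED_CONTROLS = ("VAFA", "EPA", "RGPBE", "EUE")


def significance_stars(t: float) -> str:
    """Two-sided normal significance stars at the 10/5/1% levels."""
    at = abs(t)
    if at >= 2.576:
        return "***"
    if at >= 1.96:
        return "**"
    if at >= 1.645:
        return "*"
    return ""


def _cell(theta: float, t: float) -> str:
    star = significance_stars(t)
    return f"{theta:.3f} {star}({t:.2f})" if star else f"{theta:.3f} ({t:.2f})"


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    synthetic: bool = True
    input_path: str | None = None
    indicator_spec_path: str | None = None
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    dml: DMLConfig = field(default_factory=DMLConfig)
    treatments: tuple[str, ...] = ("RAIN", "TEMP")
    outcome: str = OUTCOME
    run_index: bool = True
    # robustness toggles
    exclusion_units: tuple[str, ...] = ()
    winsorize_pairs: tuple[tuple[float, float], ...] = ()
    tlife: bool = False
    fold_variants: tuple[int, ...] = ()
    learner_swap: str | None = None
    lag_columns: tuple[str, ...] = ()
    # heterogeneity
    subgroup_rules: dict[str, SubgroupRule] = field(default_factory=dict)
    # moderation
    moderation: bool = False
    center_interaction: bool = True
    out_dir: str | None = None
    seed: int | None = None


@dataclass
class StudyBundle:
    """Outputs of a study run: formatted tables, tidy results, manifest."""

    tables: dict[str, pd.DataFrame]
    results: pd.DataFrame
    manifest: dict[str, Any]
    panel: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables.items():
            tab.to_csv(out / f"table_{name}.csv")
        self.results.to_csv(out / "results.csv", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        self.panel.to_csv(out / "panel.csv", index=False)


def validate_config(config: StudyConfig) -> list[str]:
    """Itemized invariant violations (empty list = valid)."""
    errs: list[str] = []
    if config.synthetic == (config.input_path is not None):
        errs.append("StudyConfig: exactly one input source (synthetic or input_path)")
    for name, sub in (
        ("synthetic_config", config.synthetic_config),
        ("ga", config.ga),
        ("dml", config.dml),
    ):
        try:
            sub.validate()
        except ValueError as e:
            errs.append(f"StudyConfig.{name}: {e}")
    for pair in config.winsorize_pairs:
        if not (0 <= pair[0] < pair[1] <= 1):
            errs.append(f"StudyConfig.winsorize_pairs: invalid pair {pair}")
    for k in config.fold_variants:
        if k < 2:
            errs.append(f"StudyConfig.fold_variants: fold count {k} < 2")
    if config.learner_swap is not None:
        try:
            LearnerSpec(kind=config.learner_swap).validate()
        except ValueError as e:
            errs.append(f"StudyConfig.learner_swap: {e}")
    for name, rule in config.subgroup_rules.items():
        try:
            type(rule).__post_init__(rule)
        except ValueError as e:
            errs.append(f"StudyConfig.subgroup_rules[{name}]: {e}")
    return errs


def _reseed(config: StudyConfig) -> StudyConfig:
    """Derive all stage seeds from the global seed when one is given."""
    if config.seed is None:
        return config
    return dataclasses.replace(
        config,
        synthetic_config=dataclasses.replace(config.synthetic_config, seed=config.seed),
        ga=dataclasses.replace(config.ga, seed=config.seed + 1),
        dml=dataclasses.replace(config.dml, seed=config.seed + 2),
    )


def _estimate_pair(
    panel: pd.DataFrame,
    config: StudyConfig,
    dml_cfg: DMLConfig,
    label: str,
    records: list[dict],
) -> dict[str, str]:
    """One table column pair: each treatment estimated separately."""
    cells = {}
    for treatment in config.treatments:
        res = dml_plr(
            panel,
            outcome=config.outcome,
            treatment=treatment,
            controls=CONTROLS,
            config=dml_cfg,
        )
        th, t = float(res.theta.iloc[0]), float(res.t_stat.iloc[0])
        cells[treatment] = _cell(th, t)
        records.append(
            {
                "design": label,
                "treatment": treatment,
                "theta": th,
                "se": float(res.se.iloc[0]),
                "t": t,
                "p": float(res.p_value.iloc[0]),
                "n": res.n_obs,
                "folds": dml_cfg.n_folds,
                "learner": dml_cfg.learner.kind,
                "fe_mode": dml_cfg.fe_mode,
            }
        )
    cells["n"] = str(len(panel))
    return cells


def run_study(config: StudyConfig) -> StudyBundle:
    """Execute the configured designs and collect the report bundle."""
    errs = validate_config(config)
    if errs:
        raise ValueError("invalid StudyConfig:\n  " + "\n  ".join(errs))
    config = _reseed(config)
    manifest: dict[str, Any] = {"config": asdict(config)}

    # --- data ------------------------------------------------------------
    if config.synthetic:
        panel_ds, truth = generate_panel(config.synthetic_config)
        panel = panel_ds.frame
        manifest["truth"] = {
            "theta_by_treatment": truth.theta_by_treatment,
            "nuisance": truth.nuisance,
            "seed": truth.seed,
        }
    else:
        panel = PanelDataset.from_csv(config.input_path).frame

    panel = interpolate_missing(panel)

    # --- composite index --------------------------------------------------
    if config.run_index:
        specs = (
            load_indicator_specs(config.indicator_spec_path)
            if config.indicator_spec_path
            else None
        )
        index_col = config.outcome if config.outcome not in panel.columns else f"{config.outcome}_PPC"
        panel, ppc_res = compute_resilience_index(panel, specs, config.ga, column=index_col)
        manifest["index"] = ppc_res.run_log()
        manifest["index"]["column"] = index_col

    tables: dict[str, pd.DataFrame] = {}
    records: list[dict] = []

    # --- main specification grid -----------------------------------------
    main_cols = {}
    col_no = 0
    for fe_mode in MAIN_FE_MODES:
        cfg = dataclasses.replace(config.dml, fe_mode=fe_mode)
        for treatment in config.treatments:
            col_no += 1
            res = dml_plr(panel, outcome=config.outcome, treatment=treatment, controls=CONTROLS, config=cfg)
            th, t = float(res.theta.iloc[0]), float(res.t_stat.iloc[0])
            main_cols[f"({col_no})"] = {
                treatment: _cell(th, t),
                "Cross fitting": str(cfg.n_folds),
                "Time fixed": "YES" if fe_mode in ("time", "two_way") else "NO",
                "Individual fixed": "YES" if fe_mode in ("unit", "two_way") else "NO",
                "Sample size": str(len(panel)),
            }
            records.append(
                {
                    "design": "main",
                    "treatment": treatment,
                    "theta": th,
                    "se": float(res.se.iloc[0]),
                    "t": t,
                    "p": float(res.p_value.iloc[0]),
                    "n": res.n_obs,
                    "folds": cfg.n_folds,
                    "learner": cfg.learner.kind,
                    "fe_mode": fe_mode,
                }
            )
    tables["main"] = pd.DataFrame(main_cols).fillna("")

    two_way = dataclasses.replace(config.dml, fe_mode="two_way")

    # --- robustness -------------------------------------------------------
    robust_cols: dict[str, dict] = {}
    if config.exclusion_units:
        sub = exclude_units(panel, config.exclusion_units)
        robust_cols["sample_adjustment"] = _estimate_pair(sub, config, two_way, "exclude_units", records)
    for pair in config.winsorize_pairs:
        cols = [config.outcome, *config.treatments, *CONTROLS]
        wpanel = winsorize(panel, cols, *pair)
        label = f"winsor_{pair[0]:g}_{pair[1]:g}"
        robust_cols[label] = _estimate_pair(wpanel, config, two_way, label, records)
    if config.tlife:
        cfg = dataclasses.replace(config.dml, fe_mode="time_location_interaction")
        robust_cols["tlife"] = _estimate_pair(panel, config, cfg, "tlife", records)
    for k in config.fold_variants:
        cfg = dataclasses.replace(two_way, n_folds=k)
        robust_cols[f"folds_{k}"] = _estimate_pair(panel, config, cfg, f"folds_{k}", records)
    if config.learner_swap:
        cfg = dataclasses.replace(
            two_way, learner=dataclasses.replace(config.dml.learner, kind=config.learner_swap)
        )
        robust_cols[config.learner_swap] = _estimate_pair(panel, config, cfg, config.learner_swap, records)
    if config.lag_columns:
        lagged = lag_controls(panel, config.lag_columns, lag=1)
        robust_cols["lagged_controls"] = _estimate_pair(lagged, config, two_way, "lagged_controls", records)
    if robust_cols:
        tables["robustness"] = pd.DataFrame(robust_cols).fillna("")

    # --- heterogeneity ----------------------------------------------------
    sub_cols: dict[str, dict] = {}
    for name, rule in config.subgroup_rules.items():
        sub = split_subgroup(panel, rule)
        sub_cols[name] = _estimate_pair(sub, config, two_way, f"subgroup_{name}", records)
    if sub_cols:
        tables["heterogeneity"] = pd.DataFrame(sub_cols).fillna("")

    # --- moderation -------------------------------------------------------
    if config.moderation:
        mod_cols: dict[str, dict] = {}
        for treatment in config.treatments:
            mpanel, iname = make_interaction(panel, MODERATOR, treatment, config.center_interaction)
            res = dml_multi_treatment(
                mpanel,
                outcome=config.outcome,
                treatments=(treatment, MODERATOR, iname),
                controls=CONTROLS,
                config=two_way,
            )
            col = {}
            for nm in res.treatments:
                th, t = float(res.theta[nm]), float(res.t_stat[nm])
                col[nm] = _cell(th, t)
                records.append(
                    {
                        "design": "moderation",
                        "treatment": nm,
                        "theta": th,
                        "se": float(res.se[nm]),
                        "t": t,
                        "p": float(res.p_value[nm]),
                        "n": res.n_obs,
                        "folds": two_way.n_folds,
                        "learner": two_way.learner.kind,
                        "fe_mode": two_way.fe_mode,
                    }
                )
            col["Sample size"] = str(res.n_obs)
            mod_cols[treatment] = col
        tables["moderation"] = pd.DataFrame(mod_cols).fillna("")

    results = pd.DataFrame.from_records(records)
    manifest["designs"] = sorted(tables)
    bundle = StudyBundle(tables=tables, results=results, manifest=manifest, panel=panel)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


# --- YAML loading ----------------------------------------------------------


def study_config_from_yaml(path: str | Path) -> StudyConfig:
    """Build a StudyConfig from a YAML mapping of (nested) fields."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {}
    for key, val in raw.items():
        if key == "synthetic_config":
            kwargs[key] = SyntheticConfig(**val)
        elif key == "ga":
            kwargs[key] = GAConfig(**val)
        elif key == "dml":
            learner = val.pop("learner", None)
            cfg = DMLConfig(**val)
            if learner is not None:
                cfg.learner = LearnerSpec(**learner) if isinstance(learner, dict) else LearnerSpec(kind=learner)
            kwargs[key] = cfg
        elif key == "subgroup_rules":
            kwargs[key] = {k: SubgroupRule(**v) for k, v in val.items()}
        elif key in ("winsorize_pairs",):
            kwargs[key] = tuple(tuple(p) for p in val)
        elif key in ("exclusion_units", "fold_variants", "lag_columns", "treatments"):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return StudyConfig(**kwargs)
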