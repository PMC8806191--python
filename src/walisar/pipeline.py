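"""Reproducible end-to-end pipeline: simulate → score → screen → combos → predict.

A single master seed drives every stochastic stage through per-stage
seeds derived by hashing (master seed, stage name), so inserting a stage
never shifts another stage's random stream.  Each stage writes CSV/JSON
outputs that are schema-validated, and a run manifest records the config
snapshot, derived seeds and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as sdata
from . import preference_metrics as pmet
from . import eb_screen as ebs
from . import combination_models as cmb
from . import valence_prediction as vpred

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_schema",
            "derive_seed", "SCHEMAS"]

log = logging.getLogger("walisar")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed from the master seed (counter-based hash)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """All stage parameters plus the master seed and output directory."""

    master_seed: int = 0
    out_dir: str = "walisar_run"
    stages: tuple = ("simulate", "score", "screen", "combos", "predict")

    # simulate: trajectory-level demo ORNs (label -> valence per intensity).
    # The trajectory demo exercises the scoring path with a reduced cohort;
    # screen-scale statistics run at full N through the score-level
    # generator below.
    demo_orns: dict = field(default_factory=lambda: {
        "Gr66a": {"14": -0.4, "42": -0.7, "70": -1.0},
        "Orco": {"14": 0.3, "42": 0.5, "70": 0.7},
    })
    demo_flies_per_role: int = 12
    n_test: int = 52
    n_ctrl1: int = 52
    n_ctrl2: int = 52
    # simulate: score-level screen dataset
    screen_n_orns: int = 46
    screen_valent_fraction: float = 10 / 46
    screen_effect_magnitude: float = 0.4
    # simulate: combination trios
    combo_pairs: dict = field(default_factory=lambda: {
        "pairA": {"beta": [0.0, 0.7, 0.3], "singles": [-0.3, 0.2]},
        "pairB": {"beta": [0.0, 0.5, 0.5], "singles": [0.3, 0.3]},
        "pairC": {"beta": [0.0, 1.0, 0.1], "singles": [-0.4, -0.1]},
    })
    combo_n_flies: int = 52
    combo_noise_sd: float = 0.05
    # simulate: odor panel
    panel_n_odors: int = 110
    panel_n_orns: int = 23
    panel_n_latent: int = 8
    panel_noise_sd: float = 1.0

    # score / effects
    bootstrap_reps: int = 5000
    ci_method: str = "BCa"
    # screen
    fdr_threshold: float = 0.25
    # combos
    n_boot: int = 10000
    # predict
    n_components: int = 8
    regressor: str = "linear"
    folds: int = 10

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        return cfg


@dataclass
class RunManifest:
    config: dict
    derived_seeds: dict
    checksums: dict
    versions: dict
    timestamp: str

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# schemas

SCHEMAS: dict[str, dict] = {
    "trajectory": {
        "columns": {
            "fly_id": "object", "role": "object", "orn_label": "object",
            "step_index": "int", "intensity": "object", "airflow": "object",
            "epoch": "object", "frame": "int", "time_s": "float",
            "x_mm": "float", "lit_half": "object", "fly_half": "object",
        },
        "ranges": {"x_mm": (0.0, 50.0), "time_s": (0.0, None)},
        "allowed": {"role": {"test", "ctrl_driver", "ctrl_responder"},
                    "lit_half": {"left", "right", "none"},
                    "fly_half": {"left", "right"},
                    "airflow": {"on", "off"}},
    },
    "scores": {
        "columns": {"fly_id": "object", "role": "object", "orn_label": "object",
                    "intensity": "object", "airflow": "object", "epoch": "object",
                    "wtsale": "float"},
        "ranges": {"wtsale": (-1.0, 1.0)},
        "allowed": {"role": {"test", "ctrl_driver", "ctrl_responder"},
                    "epoch": {"first", "second"}},
    },
    "effects": {
        "columns": {"orn_label": "object", "intensity": "object",
                    "airflow": "object", "delta": "float", "ci_low": "float",
                    "ci_high": "float", "n_test": "int", "n_ctrl": "int"},
        "ranges": {"n_test": (1, None), "n_ctrl": (1, None)},
        "allowed": {},
    },
    "screen": {
        "columns": {"orn_label": "object", "d_stat": "float", "s_stat": "float",
                    "z_stat": "float", "posterior": "float", "local_fdr": "float",
                    "hit": "bool", "sign": "int"},
        "ranges": {"posterior": (-1.0, 1.0), "local_fdr": (0.0, 1.0),
                   "s_stat": (0.0, None)},
        "allowed": {},
    },
    "betas": {
        "columns": {"pair_label": "object", "intensity": "object",
                    "beta0": "float", "beta1": "float", "beta2": "float",
                    "distance": "float", "signed_distance": "float",
                    "n_dropped": "int"},
        "ranges": {"distance": (0.0, None), "n_dropped": (0, None)},
        "allowed": {},
    },
}


@dataclass
class SchemaReport:
    schema: str
    path: str
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_schema(path, schema_name: str) -> SchemaReport:
    """Check a CSV against a registered schema: columns, dtypes, ranges."""
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; "
                       f"known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema_name]
    df = pd.read_csv(path)
    violations = []
    for col, kind in spec["columns"].items():
        if col not in df.columns:
            violations.append({"kind": "missing_column", "column": col})
            continue
        if kind in ("int", "float"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna()
            for i in df.index[bad]:
                violations.append({"kind": "type", "column": col, "row": int(i)})
    for col, (lo, hi) in spec.get("ranges", {}).items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = pd.Series(False, index=df.index)
        if lo is not None:
            bad |= vals < lo
        if hi is not None:
            bad |= vals > hi
        for i in df.index[bad.fillna(False)]:
            violations.append({"kind": "range", "column": col, "row": int(i),
                               "value": float(vals[i])})
    for col, allowed in spec.get("allowed", {}).items():
        if col not in df.columns:
            continue
        bad = ~df[col].astype(str).isin(allowed)
        for i in df.index[bad]:
            violations.append({"kind": "value", "column": col, "row": int(i),
                               "value": str(df[col][i])})
    return SchemaReport(schema=schema_name, path=str(path), violations=violations)


# ---------------------------------------------------------------------------
# stages


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, schema: str | None = None,
               float_format: str = "%.10g") -> None:
    df.to_csv(path, index=False, float_format=float_format)
    if schema is not None:
        rep = validate_schema(path, schema)
        if not rep.ok:
            raise ValueError(f"schema violations in {path.name}: "
                             f"{rep.violations[:5]}"
                             + ("..." if len(rep.violations) > 5 else ""))


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    protocol = sdata.ProtocolSpec()
    seed = derive_seed(cfg.master_seed, "simulate")
    log.info("simulate: %d demo ORNs, %d screen ORNs, seed %d",
             len(cfg.demo_orns), cfg.screen_n_orns, seed)
    tracks = []
    for i, (orn, valences) in enumerate(sorted(cfg.demo_orns.items())):
        n = cfg.demo_flies_per_role
        eff = sdata.EffectSpec(orn_label=orn, true_valence_per_intensity=valences,
                               n_test=n, n_ctrl1=n, n_ctrl2=n)
        tracks += sdata.generate_cohort(eff, protocol, seed=seed + i)
    _write_csv(sdata.tracks_to_frame(tracks), out / "trajectories.csv",
               "trajectory", float_format="%.4f")

    scores, truth = sdata.generate_screen_scores(
        n_orns=cfg.screen_n_orns, valent_fraction=cfg.screen_valent_fraction,
        effect_size_distribution={"kind": "fixed",
                                  "magnitude": cfg.screen_effect_magnitude},
        n_test=cfg.n_test, n_ctrl=cfg.n_ctrl1 + cfg.n_ctrl2,
        seed=derive_seed(cfg.master_seed, "simulate.screen"))
    _write_csv(scores, out / "screen_scores.csv", "scores")
    _write_csv(truth, out / "screen_truth.csv")

    combo_rows = []
    for j, (pair, spec) in enumerate(sorted(cfg.combo_pairs.items())):
        truth_c = sdata.ComboTruth(*spec["beta"], noise_sd=cfg.combo_noise_sd,
                                   n_flies=cfg.combo_n_flies)
        s1, s2, sc = sdata.generate_combo_dataset(
            truth_c, tuple(spec["singles"]),
            seed=derive_seed(cfg.master_seed, f"simulate.combo.{pair}"))
        for grp, vals in (("orn1", s1), ("orn2", s2), ("combo", sc)):
            combo_rows.append(pd.DataFrame({
                "pair_label": pair, "group": grp,
                "fly_index": np.arange(vals.size), "wtsale": vals}))
    _write_csv(pd.concat(combo_rows, ignore_index=True), out / "combo_scores.csv")

    firing, valence, labels, _latent = sdata.generate_odor_panel(
        n_odors=cfg.panel_n_odors, n_orns=cfg.panel_n_orns,
        n_latent=cfg.panel_n_latent, noise_sd=cfg.panel_noise_sd,
        seed=derive_seed(cfg.master_seed, "simulate.panel"))
    firing.rename_axis("odor").reset_index().to_csv(out / "panel_firing.csv", index=False)
    pd.DataFrame({"odor": valence.index, "valence": valence.to_numpy(),
                  "class_label": labels.to_numpy()}).to_csv(
        out / "panel_valence.csv", index=False)


def stage_score(cfg: RunConfig, out: Path) -> None:
    traj_path = out / "trajectories.csv"
    if not traj_path.exists():
        raise FileNotFoundError(f"missing input {traj_path}; enable the "
                                "simulate stage or provide trajectories")
    long = pd.read_csv(traj_path)
    seed = derive_seed(cfg.master_seed, "score")
    log.info("score: %s, bootstrap reps %d", traj_path.name, cfg.bootstrap_reps)
    scores = []
    keys = ["fly_id", "role", "orn_label", "intensity", "airflow", "step_index", "epoch"]
    for key_vals, grp in long.groupby(keys, sort=True):
        meta = dict(zip(keys, key_vals))
        track = pmet.FlyTrack(
            fly_id=str(meta["fly_id"]), role=meta["role"],
            orn_label=str(meta["orn_label"]), intensity=str(meta["intensity"]),
            airflow=meta["airflow"], step_index=int(meta["step_index"]),
            epoch=meta["epoch"],
            frames=grp[["time_s", "x_mm", "lit_half"]].reset_index(drop=True))
        scores.append(pmet.compute_wtsale(track).__dict__)
    score_df = pd.DataFrame(scores)
    _write_csv(score_df.drop(columns=["tsale", "weight"]).assign(
        wtsale=score_df["wtsale"]), out / "scores.csv", "scores")
    second = pmet.select_analysis_epoch(score_df)
    effects = pmet.effect_table(second, bootstrap_reps=cfg.bootstrap_reps,
                                seed=seed, ci_method=cfg.ci_method)
    _write_csv(effects, out / "effects.csv", "effects")


def stage_screen(cfg: RunConfig, out: Path) -> None:
    scores = pd.read_csv(out / "screen_scores.csv")
    log.info("screen: %d ORNs, FDR threshold %.2f",
             scores["orn_label"].nunique(), cfg.fdr_threshold)
    mix_cfg = ebs.MixtureConfig(fdr_threshold=cfg.fdr_threshold)
    table, fit, alpha0 = ebs.run_screen(scores, mix_cfg)
    _write_csv(table, out / "screen.csv", "screen")
    report = {
        "alpha0": alpha0, "null_mean": fit.null_mean, "null_sd": fit.null_sd,
        "pi_null": fit.pi_null, "pi_neg": fit.pi_neg, "pi_pos": fit.pi_pos,
        "converged": fit.converged, "n_iter": fit.n_iter,
        "n_hits": int(table["hit"].sum()),
        "fdr_threshold": cfg.fdr_threshold,
    }
    (out / "screen_fit.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def stage_combos(cfg: RunConfig, out: Path) -> None:
    combo = pd.read_csv(out / "combo_scores.csv")
    seed = derive_seed(cfg.master_seed, "combos")
    log.info("combos: %d pairs, n_boot %d", combo["pair_label"].nunique(), cfg.n_boot)
    beta_rows, pool_rows = [], []
    observed, predicted = [], {"summation": [], "max_pool": [], "min_pool": []}
    for k, (pair, grp) in enumerate(sorted(combo.groupby("pair_label"))):
        s1 = grp.loc[grp["group"] == "orn1", "wtsale"].to_numpy()
        s2 = grp.loc[grp["group"] == "orn2", "wtsale"].to_numpy()
        sc = grp.loc[grp["group"] == "combo", "wtsale"].to_numpy()
        cb = cmb.bootstrap_trio_regression(s1, s2, sc, n_boot=cfg.n_boot,
                                           seed=seed + k, pair_label=pair)
        beta_rows.append(dict(
            pair_label=pair, intensity="", beta0=cb.beta0, beta1=cb.beta1,
            beta2=cb.beta2, distance=cb.distance_from_diagonal,
            signed_distance=cb.signed_distance, n_dropped=cb.n_dropped))
        v1, v2, vc = s1.mean(), s2.mean(), sc.mean()
        preds = {"summation": cmb.pool_sum(v1, v2),
                 "max_pool": cmb.pool_max_abs(v1, v2),
                 "min_pool": cmb.pool_min_abs(v1, v2)}
        observed.append(vc)
        for name, p in preds.items():
            predicted[name].append(p)
            pool_rows.append(dict(pair_label=pair, model=name,
                                  predicted=p, observed=vc))
    _write_csv(pd.DataFrame(beta_rows), out / "betas.csv", "betas")
    _write_csv(pd.DataFrame(pool_rows), out / "pooling.csv")
    agreement = {}
    for name, preds in predicted.items():
        if len(observed) >= 3:
            rep = cmb.evaluate_agreement(observed, preds, bootstrap_reps=1000,
                                         seed=seed, model_name=name)
            agreement[name] = {k: v for k, v in rep.__dict__.items()
                               if isinstance(v, (int, float, str, bool))}
    (out / "agreement.json").write_text(
        json.dumps(agreement, indent=2, sort_keys=True))


def stage_predict(cfg: RunConfig, out: Path) -> None:
    firing = pd.read_csv(out / "panel_firing.csv", index_col="odor")
    meta = pd.read_csv(out / "panel_valence.csv", index_col="odor")
    seed = derive_seed(cfg.master_seed, "predict")
    log.info("predict: %d odors x %d ORNs, %d LVs, %s regressor",
             *firing.shape, cfg.n_components, cfg.regressor)
    panel = vpred.OdorPanel(firing=firing, valence=meta["valence"],
                            class_label=meta["class_label"])
    lm = vpred.fit_latent_model(panel, n_components=cfg.n_components)
    _, adj_r2 = vpred.regress_valence(lm, panel, regressor=cfg.regressor)
    rmses, rmse_mean, rmse_sd = vpred.cross_validate(
        panel, n_components=cfg.n_components, regressor=cfg.regressor,
        folds=cfg.folds, seed=seed)
    pd.DataFrame(lm.scores, index=firing.index,
                 columns=[f"LV{i+1}" for i in range(cfg.n_components)]
                 ).rename_axis("odor").reset_index().to_csv(
        out / "lv_scores.csv", index=False)
    (out / "prediction_metrics.json").write_text(json.dumps({
        "adjusted_r2": adj_r2, "cv_rmse_mean": rmse_mean, "cv_rmse_sd": rmse_sd,
        "cv_rmse_per_split": list(rmses), "n_components": cfg.n_components,
        "regressor": cfg.regressor, "folds": cfg.folds,
    }, indent=2, sort_keys=True))


_STAGES = {
    "simulate": stage_simulate,
    "score": stage_score,
    "screen": stage_screen,
    "combos": stage_combos,
    "predict": stage_predict,
}


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order; emit a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in cfg.stages:
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
    for name in _STAGES:  # canonical order regardless of config order
        if name in cfg.stages:
            _STAGES[name](cfg, out)
    checksums = {p.name: _checksum(p) for p in sorted(out.iterdir())
                 if p.suffix in (".csv", ".json") and p.name != "manifest.json"}
    manifest = RunManifest(
        config=asdict(cfg),
        derived_seeds={s: derive_seed(cfg.master_seed, s) for s in cfg.stages},
        checksums=checksums,
        versions={"walisar": __import__("walisar").__version__,
                  "numpy": np.__version__, "pandas": pd.__version__},
        timestamp=pd.Timestamp.now().isoformat(),
    )
    manifest.save(out / "manifest.json")
    return manifest
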