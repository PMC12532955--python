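"""End-to-end orchestration: simulate -> preprocess -> discover -> train -> evaluate.

The discovery cohort (multi-disease, mixed array versions) is used only
for feature extraction; the modeling cohort is a distinct simulated
dataset that is stratified-split into training (default 80%) and holdout
sets.  Feature extraction never sees modeling samples, the holdout is
touched once, and every stochastic stage is seeded, so rerunning with an
identical configuration reproduces all artifacts byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clf import (
    ClassifierModel,
    encode_serology,
    predict_proba,
    train_elastic_net_cv,
    youden_cutoff,
)
from .evalstats import evaluate, write_report
from .ewas import run_ewas
from .methio import beta_to_m, filter_probes, harmonize_probes
from .simcohort import RA_GROUPS, SimConfig, simulate_cohort, split_by_array, write_cohort
from .stabsel import build_feature_panel, stability_selection, threshold_stability

__all__ = ["PipelineConfig", "StageError", "stratified_split", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _default_modeling_config() -> SimConfig:
    # RA + arthritis + healthy modeling cohort, measured on one array
    return SimConfig(
        group_sizes={
            "healthy": 50,
            "ra_seropos": 62,
            "ra_seroneg": 32,
            "other_arthritis": 74,
        },
        array_assignment={g: "EPIC" for g in
                          ("healthy", "ra_seropos", "ra_seroneg", "other_arthritis")},
        id_prefix="M",
        seed=1,
    )


@dataclass
class PipelineConfig:
    discovery: SimConfig = field(default_factory=lambda: SimConfig(id_prefix="D"))
    modeling: SimConfig = field(default_factory=_default_modeling_config)
    epsilon: float = 1e-6
    max_missing_frac: float = 0.1
    min_sd: float = 0.0
    ewas: dict = field(default_factory=lambda: {
        "alpha_fwer": 0.05,
        "covariate_names": ["age", "sex"],
        "drop_age_zero": True,
    })
    stabsel: dict = field(default_factory=lambda: {
        "B": 50,
        "alpha_mix": 1.0,
        "n_lambda": 10,
        "lambda_decades": 1.0,
        "pi_threshold": 0.1,
    })
    clf: dict = field(default_factory=lambda: {
        "k_folds": 5,
        "alpha_grid": [0.1, 0.5, 0.9, 1.0],
        "n_lambda": 30,
        "lambda_decades": 4.0,
    })
    eval: dict = field(default_factory=lambda: {"level": 0.95, "n_boot": 2000})
    split_frac: float = 0.8
    seed_split: int = 11
    seed_stability: int = 12
    seed_cv: int = 13
    seed_bootstrap: int = 14

    def validate(self) -> None:
        if not 0.0 < self.split_frac < 1.0:
            raise ValueError("split_frac must lie in (0, 1)")
        self.discovery.validate()
        self.modeling.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "discovery" in d:
            d["discovery"] = SimConfig(**d["discovery"])
        if "modeling" in d:
            d["modeling"] = SimConfig(**d["modeling"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def stratified_split(
    sheet: pd.DataFrame,
    frac: float = 0.8,
    seed: int = 0,
    age_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign split_role by stratified sampling with largest-remainder rounding.

    Strata are diagnosis x sex x age tertile (tertile edges computed on
    the sheet unless given).  The total training count is
    round(frac * n); per-stratum counts start at floor(frac * n_stratum)
    and the remainder is distributed by descending fractional part.
    Singleton strata always go to training (a lone sample cannot inform
    holdout metrics), with a warning.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    sheet = sheet.copy().reset_index(drop=True)
    ages = sheet["age"].to_numpy(float)
    if age_edges is None:
        age_edges = np.quantile(ages, [1 / 3, 2 / 3])
    age_bin = np.digitize(ages, age_edges)
    strata_keys = list(zip(sheet["group"], sheet["sex"], age_bin))
    strata: dict = {}
    for i, key in enumerate(strata_keys):
        strata.setdefault(key, []).append(i)

    keys = sorted(strata.keys(), key=str)
    sizes = np.array([len(strata[k]) for k in keys])
    target_total = int(round(frac * sizes.sum()))
    floors = np.floor(frac * sizes).astype(int)
    remainders = frac * sizes - floors
    extra = target_total - floors.sum()
    order = np.argsort(-remainders, kind="stable")
    counts = floors.copy()
    for idx in order[: max(extra, 0)]:
        counts[idx] += 1
    counts = np.minimum(counts, sizes)

    rng = np.random.default_rng(seed)
    role = np.array(["holdout"] * len(sheet), dtype=object)
    for k, n_train in zip(keys, counts):
        idx = np.array(strata[k])
        if idx.size == 1:
            warnings.warn(f"stratum {k} has a single sample; assigned to training",
                          stacklevel=2)
            role[idx] = "training"
            continue
        perm = rng.permutation(idx)
        role[perm[:n_train]] = "training"
    sheet["split_role"] = role
    return sheet


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, str(exc)) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write all artifacts under ``outdir``.

    Returns the manifest dictionary (also written as manifest.json).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        d_beta, d_sheet, d_truth = simulate_cohort(config.discovery)
        m_beta, m_sheet, m_truth = simulate_cohort(config.modeling)
        write_cohort(d_beta, d_sheet, d_truth, outdir / "discovery")
        write_cohort(m_beta, m_sheet, m_truth, outdir / "modeling")
        return d_beta, d_sheet, d_truth, m_beta, m_sheet, m_truth

    d_beta, d_sheet, d_truth, m_beta, m_sheet, m_truth = _simulate()

    # --- preprocess -------------------------------------------------------
    @_stage("preprocess")
    def _preprocess():
        parts = split_by_array(d_beta, d_sheet, config.discovery)
        d_harm = harmonize_probes(parts)
        d_filt = filter_probes(d_harm, config.max_missing_frac, config.min_sd)
        d_m = beta_to_m(d_filt, config.epsilon)
        m_parts = split_by_array(m_beta, m_sheet, config.modeling)
        m_harm = harmonize_probes(m_parts)
        m_filt = filter_probes(m_harm, config.max_missing_frac, config.min_sd)
        m_m = beta_to_m(m_filt, config.epsilon)
        return d_m, m_m

    d_m, m_m = _preprocess()

    # --- discover (feature extraction on discovery only) ------------------
    @_stage("discover")
    def _discover():
        ewas_res = run_ewas(
            d_m,
            d_sheet,
            covariate_names=tuple(config.ewas["covariate_names"]),
            alpha_fwer=config.ewas["alpha_fwer"],
            drop_age_zero=config.ewas["drop_age_zero"],
        )
        ewas_ids = list(ewas_res.loc[ewas_res["significant"], "probe_id"])
        case = d_sheet.set_index("sample_id").loc[list(d_m.columns), "group"].isin(RA_GROUPS)
        stab = stability_selection(
            d_m,
            case.to_numpy(),
            B=config.stabsel["B"],
            alpha_mix=config.stabsel["alpha_mix"],
            n_lambda=config.stabsel["n_lambda"],
            lambda_decades=config.stabsel["lambda_decades"],
            seed=config.seed_stability,
        )
        stab_ids = threshold_stability(stab, config.stabsel["pi_threshold"])
        panel = build_feature_panel(ewas_ids, stab_ids)
        ewas_res.to_csv(outdir / "ewas_results.tsv", sep="\t", index=False)
        stab.pi.rename("pi").to_csv(outdir / "stability.tsv", sep="\t",
                                    index_label="probe_id")
        panel.to_csv(outdir / "panel.tsv", sep="\t", index=False)
        return ewas_res, stab, panel

    ewas_res, stab, panel = _discover()

    # --- split ------------------------------------------------------------
    @_stage("split")
    def _split():
        sheet = stratified_split(m_sheet, config.split_frac, config.seed_split)
        sheet.to_csv(outdir / "modeling" / "sample_sheet.tsv", sep="\t", index=False)
        return sheet

    m_sheet2 = _split()

    # --- train ------------------------------------------------------------
    @_stage("train")
    def _train():
        panel_probes = [p for p in panel["probe_id"] if p in m_m.index]
        if not panel_probes:
            raise ValueError("no panel probe is present on the modeling array")
        train_ids = m_sheet2.loc[m_sheet2["split_role"] == "training", "sample_id"]
        X = m_m.loc[panel_probes, train_ids]
        labels = (
            m_sheet2.set_index("sample_id").loc[train_ids, "group"].isin(RA_GROUPS)
        ).to_numpy(int)
        sero = encode_serology(m_sheet2).loc[train_ids].to_numpy()
        model = train_elastic_net_cv(
            X,
            labels,
            sero,
            k_folds=config.clf["k_folds"],
            alpha_grid=tuple(config.clf["alpha_grid"]),
            n_lambda=config.clf["n_lambda"],
            lambda_decades=config.clf["lambda_decades"],
            seed=config.seed_cv,
        )
        train_scores = predict_proba(model, X, sero)
        model.cutoff = youden_cutoff(train_scores.to_numpy(), labels)
        model.save(outdir / "model.json")
        return model

    model = _train()

    # --- evaluate ---------------------------------------------------------
    @_stage("evaluate")
    def _evaluate():
        sheet_idx = m_sheet2.set_index("sample_id")
        hold_ids = m_sheet2.loc[m_sheet2["split_role"] == "holdout", "sample_id"]
        X = m_m.loc[:, hold_ids]
        groups = sheet_idx.loc[hold_ids, "group"]
        truth = groups.isin(RA_GROUPS).to_numpy(int)
        sero = encode_serology(m_sheet2).loc[hold_ids].to_numpy()
        scores = predict_proba(model, X, sero).to_numpy()
        report = {
            "all": evaluate(
                scores, truth, model.cutoff, group_labels=groups.to_numpy(),
                subset_label="all cases vs all controls",
                level=config.eval["level"], n_boot=config.eval["n_boot"],
                seed=config.seed_bootstrap,
            )
        }
        sub = groups.isin({"ra_seroneg", "other_arthritis"}).to_numpy()
        if sub.sum() >= 4 and len(set(truth[sub])) == 2:
            report["seroneg_vs_arthritis"] = evaluate(
                scores[sub], truth[sub], model.cutoff,
                group_labels=groups.to_numpy()[sub],
                subset_label="seronegative RA vs other arthritides",
                level=config.eval["level"], n_boot=config.eval["n_boot"],
                seed=config.seed_bootstrap,
            )
        write_report(report, outdir)
        # ROC coordinates of the holdout score
        order = np.argsort(-scores, kind="stable")
        tps = np.cumsum(truth[order])
        fps = np.cumsum(1 - truth[order])
        roc = pd.DataFrame({
            "threshold": scores[order],
            "tpr": tps / max(truth.sum(), 1),
            "fpr": fps / max((1 - truth).sum(), 1),
        })
        roc.to_csv(outdir / "roc.tsv", sep="\t", index=False)
        return report

    report = _evaluate()

    # --- manifest ---------------------------------------------------------
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    disc_ids = set(d_sheet["sample_id"])
    model_ids = set(m_sheet2["sample_id"])
    train_ids = set(m_sheet2.loc[m_sheet2["split_role"] == "training", "sample_id"])
    hold_ids = set(m_sheet2.loc[m_sheet2["split_role"] == "holdout", "sample_id"])
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": {
            "simulation_discovery": config.discovery.seed,
            "simulation_modeling": config.modeling.seed,
            "split": config.seed_split,
            "stability": config.seed_stability,
            "cv": config.seed_cv,
            "bootstrap": config.seed_bootstrap,
        },
        "counts": {
            "discovery_samples": len(disc_ids),
            "modeling_samples": len(model_ids),
            "training_samples": len(train_ids),
            "holdout_samples": len(hold_ids),
            "panel_features": int(len(panel)),
            "panel_from_ewas": int(panel["from_ewas"].sum()),
            "panel_from_stability": int(panel["from_stability"].sum()),
            "model_nonzero_features": model.feature_count,
        },
        "audit": {
            "discovery_modeling_overlap": sorted(disc_ids & model_ids),
            "training_holdout_overlap": sorted(train_ids & hold_ids),
        },
        "cutoff": model.cutoff,
        "cv_auc": model.cv_auc,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
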