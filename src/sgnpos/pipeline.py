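"""End-to-end pipeline: simulate -> extract -> model -> report.

Driven by a YAML configuration; every artifact embeds the seed and a hash of
the configuration so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features_cc import extract_cc_features
from .features_vc import extract_vc_features
from .io_tables import FeatureRecord, records_to_frame, write_feature_table
from .models import build_position_model, fit_age_gradients
from .morphometry import classify_face, compute_nbp
from .simulate import SimulationConfig, generate_dataset, load_dataset
from .stats import ancova_two_way, pearson

__all__ = ["PipelineError", "extract_features", "run_pipeline",
           "correlation_report", "ancova_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def extract_features(recordings, e_k: float | None = None) -> pd.DataFrame:
    """Merge per-neuron current-clamp, voltage-clamp and position features."""
    if e_k is None:
        e_k = recordings[0].params.e_k if recordings[0].params else -85.0
    records = []
    for rec in recordings:
        cc = extract_cc_features(rec.cc_family)
        try:
            vc = extract_vc_features(rec.vc_family, e_k=e_k)
        except ValueError:
            vc = {"g_max": None, "g_minus30": None, "v_half": None,
                  "tau_inact": None, "vc_excluded": True, "tau_excluded": True}
        nbp = face = None
        if rec.contact is not None:
            nbp = compute_nbp(rec.contact)
            face = classify_face(nbp)
        age = rec.params.age if rec.params is not None else -1
        fiber = rec.params.fiber_type if rec.params is not None else "type_I"
        records.append(FeatureRecord(
            neuron_id=rec.neuron_id, age=age, fiber_type=fiber,
            nbp=nbp, face_class=face,
            spiking=cc.spiking, firing_pattern=cc.firing_pattern,
            i_threshold=cc.i_threshold, v_threshold=cc.v_threshold,
            first_spike_latency=cc.first_spike_latency,
            response_latency=cc.response_latency, ahp_tau=cc.ahp_tau,
            resting_potential=cc.resting_potential, ap_height=cc.ap_height,
            g_max=vc["g_max"], g_minus30=vc["g_minus30"], v_half=vc["v_half"],
            tau_inact=vc["tau_inact"], vc_excluded=vc["vc_excluded"],
            tau_excluded=vc["tau_excluded"],
        ))
    return records_to_frame(records)


def correlation_report(features: pd.DataFrame,
                       columns=("i_threshold", "first_spike_latency",
                                "response_latency", "resting_potential",
                                "g_max", "g_minus30", "v_half",
                                "tau_inact")) -> pd.DataFrame:
    """Per-feature Pearson correlations with NBP (pairwise-complete rows)."""
    rows = []
    df = features[features["nbp"].notna()]
    if "fiber_type" in df.columns:
        df = df[df["fiber_type"] != "type_II"]
    for col in columns:
        if col not in df.columns:
            continue
        sub = df[[col, "nbp"]].dropna()
        if len(sub) < 3 or sub[col].nunique() < 2:
            continue
        res = pearson(sub[col], sub["nbp"])
        rows.append({"feature": col, "r": res.r, "df": res.df, "p": res.p,
                     "n": res.n})
    return pd.DataFrame(rows, columns=["feature", "r", "df", "p", "n"])


def ancova_report(features: pd.DataFrame) -> pd.DataFrame:
    """Face-class-by-age ANCOVA rows for the three key maturation features."""
    rows = []
    df = features[(features["nbp"].notna())
                  & (features["fiber_type"] != "type_II")].copy()
    df["face_class"] = df["face_class"].fillna("")
    for col in ("g_max", "i_threshold", "response_latency"):
        sub = df[[col, "face_class", "age"]].dropna()
        if sub.empty or sub["face_class"].nunique() < 2:
            continue
        try:
            table = ancova_two_way(sub[col], sub["face_class"], sub["age"])
        except ValueError:
            continue
        for row in table.rows:
            rows.append({"feature": col, **row})
    return pd.DataFrame(rows)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config_path, output_dir=None) -> dict:
    """Run the full pipeline from a YAML config; returns artifact paths.

    Config keys: ``seed``, ``simulation`` (SimulationConfig fields) or
    ``dataset_path`` (load instead of simulate), ``model``
    ({subsets: [...], age_range: [lo, hi]}), ``output_dir``.
    Inputs are validated before any artifact is written, so a failed run
    leaves nothing half-finished behind.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise PipelineError(f"config: file not found: {config_path}")
    raw = yaml.safe_load(config_path.read_text()) or {}
    out = Path(output_dir or raw.get("output_dir", "sgnpos_run"))
    seed = int(raw.get("seed", 0))

    dataset_path = raw.get("dataset_path")
    if dataset_path is not None and not Path(dataset_path).exists():
        raise PipelineError(f"simulate: dataset path not found: {dataset_path}")

    # --- simulate / load
    try:
        if dataset_path is not None:
            recordings = load_dataset(dataset_path)
        else:
            sim_kwargs = dict(raw.get("simulation", {}))
            sim_kwargs["seed"] = seed
            cfg = SimulationConfig(**sim_kwargs)
            recordings = generate_dataset(cfg)
    except (TypeError, ValueError, OSError) as exc:
        raise PipelineError(f"simulate: {exc}") from exc

    # --- extract
    try:
        features = extract_features(recordings)
    except ValueError as exc:
        raise PipelineError(f"extract: {exc}") from exc

    # --- model
    model_cfg = raw.get("model", {})
    subsets = model_cfg.get("subsets", ["spiking_only", "pooled"])
    age_range = tuple(model_cfg.get("age_range", (3, 10)))
    model_results = {}
    for subset in subsets:
        try:
            model_results[subset] = build_position_model(
                features, subset=subset, age_range=age_range)
        except ValueError as exc:
            raise PipelineError(f"model[{subset}]: {exc}") from exc

    # --- report + artifacts
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    write_feature_table(features, out / "features.csv")
    artifacts["features"] = out / "features.csv"
    model_rows = []
    for subset, model in model_results.items():
        p = out / f"model_{subset}.json"
        p.write_text(model.to_json())
        artifacts[f"model_{subset}"] = p
        for name, beta, v in zip(model.variables, model.beta, model.vif):
            model_rows.append({"model": subset, "variable": name,
                               "beta": beta, "vif": v,
                               "adj_r2": model.adj_r2, "rmse": model.rmse,
                               "n": model.n, "p_value": model.p_value})
    pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False,
                                    float_format="%.17g")
    artifacts["models"] = out / "models.csv"
    corr = correlation_report(features)
    corr.to_csv(out / "correlations.csv", index=False, float_format="%.17g")
    artifacts["correlations"] = out / "correlations.csv"
    anc = ancova_report(features)
    anc.to_csv(out / "ancova.csv", index=False, float_format="%.17g")
    artifacts["ancova"] = out / "ancova.csv"

    labeled = features[(features["nbp"].notna())
                       & (features["fiber_type"] != "type_II")]
    grad_rows = labeled[["g_max", "age", "face_class"]].dropna()
    gradients = None
    try:
        fit = fit_age_gradients(grad_rows["g_max"], grad_rows["age"],
                                grad_rows["face_class"])
        gradients = dataclasses.asdict(fit)
    except ValueError:
        pass

    run_meta = {
        "seed": seed,
        "config_hash": _config_hash(raw),
        "version": __version__,
        "n_neurons": len(recordings),
        "age_gradients": gradients,
    }
    (out / "run.json").write_text(json.dumps(run_meta, indent=1, sort_keys=True))
    artifacts["run"] = out / "run.json"
    return artifacts
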