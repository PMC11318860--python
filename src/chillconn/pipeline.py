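"""End-to-end runs: cohort -> features -> decoding -> inference -> report.

A run is described by a small config mapping (or YAML file):

.. code-block:: yaml

    seed: 7
    cohort:
      simulate: {n_participants: 38, n_trials: 8}   # or  dir: path/to/cohort
    features:
      networks_seed: auditory      # seed network paired with every other
      shrinkage: auto
      window: null                 # [start, end] seconds of the rest epoch
    model:
      label: chill
      lambda_grid: [0.001, 0.01, 0.1, 1, 10, 100, 1000]
    inference:
      n_perm: 1000
      alpha: 0.05

The run writes per-stage TSV tables (targets, per-pair accuracies with
FDR marks, held-out predictions, decoder weights), a JSON manifest
(package/library versions, seeds, analysis decisions) and a plain-text
report.  Re-running with the same manifest reproduces identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import list_network_pairs, pairs_containing
from .exceptions import AlignmentError, PipelineInputError
from .features import (
    feature_matrix_from_matrices,
    participant_mean_matrices,
    participant_targets,
)
from .model import (
    DEFAULT_LAMBDA_GRID,
    LassoFit,
    cv_accuracy,
    fit_transfer_model,
    nested_loocv,
)
from .simulate import SimulationConfig, load_cohort, simulate_cohort
from .stats import bh_fdr, pearson_r_p, permutation_test


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise PipelineInputError(f"config file not found: {path}")
        with open(path) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _resolve_cohort(cfg: dict, seed: int):
    section = cfg.get("cohort", {})
    if "dir" in section:
        path = Path(section["dir"])
        if not path.exists():
            raise PipelineInputError(f"cohort directory not found: {path}")
        return load_cohort(path)
    overrides = dict(section.get("simulate", {}))
    overrides.setdefault("seed", seed)
    return simulate_cohort(SimulationConfig(**overrides))


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path) -> dict:
    """Execute the decoding pipeline; returns a summary dict.

    Writes ``targets.tsv``, ``accuracy_by_pair.tsv``,
    ``predictions.tsv``, ``weights.tsv``, ``manifest.json`` and
    ``report.txt`` into ``out_dir``.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = _resolve_cohort(cfg, seed)
    feat_cfg = cfg.get("features", {})
    model_cfg = cfg.get("model", {})
    inf_cfg = cfg.get("inference", {})
    seed_net = feat_cfg.get("networks_seed", "auditory")
    shrinkage = feat_cfg.get("shrinkage", "auto")
    window = feat_cfg.get("window")
    window = tuple(window) if window else None
    label = model_cfg.get("label", "chill")
    grid = tuple(model_cfg.get("lambda_grid", DEFAULT_LAMBDA_GRID))
    n_perm = int(inf_cfg.get("n_perm", 1000))
    alpha = float(inf_cfg.get("alpha", 0.05))

    # targets
    pids, y = participant_targets(dataset, label=label)
    pd.DataFrame({"participant_id": pids, f"{label}_duration_s": y}).to_csv(
        out / "targets.tsv", sep="\t", index=False)

    # per-trial connectivity averaged per participant, once
    _, mats, mean_shrink = participant_mean_matrices(
        dataset, window=window, shrinkage=shrinkage)

    pairs = pairs_containing(list_network_pairs(dataset.parcellation), seed_net)
    rows, cv_by_pair, X_by_pair = [], {}, {}
    for pair in pairs:
        X, edges = feature_matrix_from_matrices(mats, dataset, mode="network_pair",
                                                networks=pair)
        cv = nested_loocv(X, y, lambda_grid=grid, unit_ids=pids)
        stat = pearson_r_p(cv.y_pred, cv.y_actual, sided="one") \
            if not cv.degenerate else None
        rows.append({"pair": "--".join(pair), "n_features": X.shape[1],
                     "accuracy_r": cv.accuracy_r,
                     "p": stat.p if stat else 1.0})
        cv_by_pair[pair] = cv
        X_by_pair[pair] = (X, edges)
    acc_df = pd.DataFrame(rows)

    # inference order: the correlation test is only a screen (it is
    # anticonservative for cross-validated accuracies); pairs passing it
    # get a full permutation test, and FDR is applied to the permutation
    # p-values (unscreened pairs enter as p = 1)
    perm_p = np.ones(len(pairs))
    for i, pair in enumerate(pairs):
        if acc_df["p"].iloc[i] < alpha and n_perm > 0:
            X, _ = X_by_pair[pair]
            res = permutation_test(
                lambda A, b: cv_accuracy(A, b, lambda_grid=grid),
                X, y, n_perm=n_perm, seed=seed + 1 + i,
                observed=cv_by_pair[pair].accuracy_r)
            perm_p[i] = res.p
    acc_df["p_perm"] = perm_p
    reject, p_adj = bh_fdr(perm_p, alpha=alpha)
    acc_df["p_fdr"] = p_adj
    acc_df["significant_fdr"] = reject
    acc_df.to_csv(out / "accuracy_by_pair.tsv", sep="\t", index=False)

    # predictions + exportable decoder for the primary (seed, reward) pair
    primary = tuple(sorted((seed_net, feat_cfg.get("target_network", "reward"))))
    if primary in cv_by_pair:
        cv = cv_by_pair[primary]
        pd.DataFrame({
            "participant_id": pids,
            "actual": cv.y_actual,
            "predicted": cv.y_pred,
            "fold_lambda": cv.fold_lambdas,
        }).to_csv(out / "predictions.tsv", sep="\t", index=False)
        X, edges = X_by_pair[primary]
        fit = fit_transfer_model(X, y, lambda_grid=grid, edges=edges)
        pd.DataFrame({
            "edge": ["--".join(e) for e in edges],
            "weight": fit.weights,
            "scaler_mean": fit.scaler_mean,
            "scaler_sd": fit.scaler_sd,
        }).to_csv(out / "weights.tsv", sep="\t", index=False)
        export_model(fit, out / "model.json")

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": cfg,
        "label": label,
        "lambda_grid": list(grid),
        "mean_shrinkage": mean_shrink,
        "decisions": {
            "scaling": "standardisation learned within each training fold",
            "partial_correlation": "shrunk-precision over the full ROI set",
            "lambda_tie_break": "larger penalty",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    lines = [f"chillconn pipeline report (seed {seed})",
             f"target: mean {label} duration, n = {len(pids)} participants", ""]
    for _, r in acc_df.iterrows():
        mark = " *" if r["significant_fdr"] else ""
        perm = (f" perm p = {r['p_perm']:.4g}" if r["p_perm"] < 1 else "")
        lines.append(f"  {r['pair']:<40s} r = {r['accuracy_r']:+.3f} "
                     f"screen p = {r['p']:.4g}{perm} "
                     f"(FDR {r['p_fdr']:.4g}){mark}")
    lines.append("")
    lines.append("* significant after Benjamini-Hochberg FDR across pairs")
    (out / "report.txt").write_text("\n".join(lines))

    return {"accuracy_by_pair": acc_df, "cv_by_pair": cv_by_pair,
            "targets": (pids, y), "manifest": manifest}


def export_model(fit: LassoFit, path: str | Path) -> Path:
    """Serialise a decoder (weights, scaler, edges, penalty) as JSON."""
    payload = {
        "weights": fit.weights.tolist(),
        "intercept": fit.intercept,
        "lambda": fit.lam,
        "scaler_mean": fit.scaler_mean.tolist(),
        "scaler_sd": fit.scaler_sd.tolist(),
        "edges": [list(e) for e in fit.edges] if fit.edges else None,
        "lambda_grid": list(fit.lambda_grid) if fit.lambda_grid else None,
        "package_version": __version__,
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    payload["sha256"] = digest
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def import_model(path: str | Path) -> LassoFit:
    """Load a decoder written by :func:`export_model`, verifying its hash."""
    path = Path(path)
    if not path.exists():
        raise PipelineInputError(f"model file not found: {path}")
    payload = json.loads(path.read_text())
    digest = payload.pop("sha256", None)
    expect = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    if digest != expect:
        raise AlignmentError(f"model file {path} failed its integrity hash")
    return LassoFit(
        weights=np.asarray(payload["weights"], float),
        intercept=float(payload["intercept"]),
        lam=float(payload["lambda"]),
        scaler_mean=np.asarray(payload["scaler_mean"], float),
        scaler_sd=np.asarray(payload["scaler_sd"], float),
        edges=tuple(tuple(e) for e in payload["edges"])
        if payload.get("edges") else None,
        lambda_grid=tuple(payload["lambda_grid"])
        if payload.get("lambda_grid") else None,
    )
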