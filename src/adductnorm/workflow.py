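"""End-to-end preprocessing workflow and report generation.

Runs filter -> impute -> (per method) normalize [-> batch align] -> DNA
correction -> QC metrics -> method comparison, and writes per-method metric
tables, retained-feature lists, PCA scores and plots, a Holm-adjusted
comparison table, and a machine-readable JSON summary. All outputs are a
pure function of the configuration and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .core import (
    FeatureTable,
    QcMetrics,
    RunType,
    read_feature_table,
)
from .metrics import count_retained, evaluate_features, rsd_star
from .normalize import METHODS, batch_align_mean, normalize, normalize_within_batches
from .preprocess import dna_conc_correct, filter_missing, impute_half_min, pca_transform
from .simulate import SimConfig, simulate_table
from .stats import dunn_all_pairs, durbin_conover, holm_adjust, significance_stars

logger = logging.getLogger(__name__)

__all__ = ["run_workflow", "adductome_map", "qc_sample_silhouette"]


def qc_sample_silhouette(scores: pd.DataFrame, table: FeatureTable,
                         n_components: int = 2) -> float:
    """Silhouette of QC vs sample run labels on the leading PCA scores.

    A large positive value means QCs cluster tightly away from samples —
    the visual criterion usually applied to score plots, quantified.
    """
    from sklearn.metrics import silhouette_score

    labels = np.array(
        ["qc" if r.run_type is not RunType.SAMPLE else "sample" for r in table.runs]
    )
    if len(set(labels)) < 2:
        raise ValueError("need both QC and sample runs for a silhouette")
    x = scores.iloc[:, :n_components].to_numpy()
    return float(silhouette_score(x, labels))


def adductome_map(table: FeatureTable, metrics: QcMetrics, out_path: str | Path) -> Path:
    """Scatter retained features in (RT, m/z), sized by median sample level.

    With no retained features a warning text file is written instead of a
    plot.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    retained = metrics.retained_ids
    if len(retained) == 0:
        warn = out_path.with_suffix(".WARNING.txt")
        warn.write_text("no retained features; adductome map not drawn\n")
        logger.warning("adductome_map: no retained features")
        return warn
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sample_cols = [r.run_id for r in table.runs if r.run_type is RunType.SAMPLE]
    med = table.values.loc[retained, sample_cols].median(axis=1)
    size = 8 + 40 * (np.log10(med.clip(lower=1)) / max(np.log10(med.clip(lower=1)).max(), 1))
    meta = table.feature_meta.loc[retained]
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(meta["rt"], meta["mz"], s=size, alpha=0.6, edgecolors="none")
    ax.set_xlabel("retention time (s)")
    ax.set_ylabel("m/z (Da)")
    ax.set_title(f"retained features (n={len(retained)})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def _load_input(config: Mapping[str, Any], seed: int) -> FeatureTable:
    if "sim" in config:
        sim_cfg = SimConfig.from_dict({**config["sim"], "seed": seed})
        table, _ = simulate_table(sim_cfg)
        return table
    inp = config["input"]
    return read_feature_table(inp["values"], inp["runs"], inp["features"])


def _istd_ids(table: FeatureTable, config: Mapping[str, Any]) -> list[str]:
    ids = config.get("istd_ids")
    if ids:
        return [i for i in ids if i in table.values.index]
    return [i for i in table.values.index if str(i).startswith("ISTD")]


def run_workflow(config: Mapping[str, Any], out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Execute the full preprocessing/evaluation workflow.

    ``config`` keys: ``sim`` (simulation parameters) or ``input`` (paths to
    the three CSVs); ``methods`` (list from :data:`~adductnorm.normalize.METHODS`);
    ``max_missing`` (default 0.5); ``rsd_threshold`` / ``dratio_threshold``
    (defaults 0.2 / 0.4); ``dna_correct`` (bool); ``batch_align`` (bool,
    default on when several batches are declared); ``seed``.

    Returns the report directory. The ``summary.json`` written there is
    byte-identical across runs with the same config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    methods = list(config.get("methods", ["none", "qc_rlsc"]))
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    rsd_thr = float(config.get("rsd_threshold", 0.2))
    dr_thr = float(config.get("dratio_threshold", 0.4))

    table = _load_input(config, seed)
    logger.info("workflow: input %d features x %d runs", table.n_features, table.n_runs)

    filtered, removed = filter_missing(table, float(config.get("max_missing", 0.5)))
    (out / "removed_features.txt").write_text("\n".join(map(str, removed)) + ("\n" if removed else ""))
    logger.info("workflow: filter kept %d features (removed %d)",
                filtered.n_features, len(removed))
    imputed = impute_half_min(filtered, seed=seed)

    n_batches = len(set(imputed.batches))
    do_align = bool(config.get("batch_align", n_batches > 1))
    do_dna = bool(config.get("dna_correct", False))
    istds = _istd_ids(imputed, config)

    summary: dict[str, Any] = {
        "seed": seed,
        "n_features_input": table.n_features,
        "n_features_filtered": filtered.n_features,
        "n_removed": len(removed),
        "methods": {},
    }
    per_method_rsd: dict[str, pd.Series] = {}
    istd_rsd_blocks: dict[str, pd.Series] = {}

    sample_cols = [r.run_id for r in imputed.runs if r.run_type is RunType.SAMPLE]
    for method in methods:
        if do_align and n_batches > 1:
            result = normalize_within_batches(imputed, method, align=True)
        else:
            result = normalize(imputed, method)
        corrected = result.table
        if do_dna:
            corrected = dna_conc_correct(corrected)
        metrics = evaluate_features(corrected, rsd_thr, dr_thr)
        metrics.frame.to_csv(out / f"metrics_{method}.csv")
        pd.Series(list(metrics.retained_ids)).to_csv(
            out / f"retained_{method}.txt", index=False, header=False
        )
        scores, explained = pca_transform(corrected)
        scores.iloc[:, : min(5, scores.shape[1])].to_csv(out / f"pca_scores_{method}.csv")
        sil = qc_sample_silhouette(scores, corrected)
        n_rsd, n_dr, n_ret = count_retained(metrics)
        summary["methods"][method] = {
            "n_rsd_pass": n_rsd,
            "n_dratio_pass": n_dr,
            "n_retained": n_ret,
            "qc_sample_silhouette_pc12": round(sil, 6),
            "explained_variance_pc1": round(float(explained[0]), 6),
        }
        passing = metrics.frame.loc[metrics.frame["rsd_pass"], "rsd_star"]
        per_method_rsd[method] = passing
        if istds:
            istd_rsd_blocks[method] = pd.Series(
                {
                    fid: rsd_star(corrected.values.loc[fid, sample_cols].to_numpy())
                    for fid in istds
                }
            )
        adductome_map(corrected, metrics, out / f"adductome_map_{method}.png")
        logger.info("workflow: method=%s retained=%d silhouette=%.3f",
                    method, n_ret, sil)

    if len(methods) >= 2:
        groups = [per_method_rsd[m].to_numpy() for m in methods]
        if all(g.size >= 2 for g in groups):
            dunn = dunn_all_pairs(groups, labels=methods)
            _write_pairwise(dunn, out / "comparison_rsd_dunn.csv")
        if istds and len(istds) >= 2:
            block = pd.DataFrame(istd_rsd_blocks)[methods]
            dc = durbin_conover(block)
            _write_pairwise(dc, out / "comparison_istd_durbin_conover.csv")
            block.to_csv(out / "istd_sample_rsd.csv")
    else:
        (out / "comparison_skipped.txt").write_text(
            "fewer than two methods requested; comparisons skipped\n"
        )

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "config_echo.json", "w") as fh:
        json.dump({k: v for k, v in config.items()}, fh, indent=2, sort_keys=True,
                  default=str)
        fh.write("\n")
    return out


def _write_pairwise(p: pd.DataFrame, path: Path) -> None:
    rows = []
    labels = list(p.columns)
    raw = []
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairs.append((labels[i], labels[j]))
            raw.append(p.iloc[i, j])
    adj = holm_adjust(raw) if raw else []
    for (a, b), praw, padj in zip(pairs, raw, adj):
        rows.append(
            {"method_a": a, "method_b": b, "p_raw": praw, "p_holm": padj,
             "label": significance_stars(padj)}
        )
    pd.DataFrame(rows).to_csv(path, index=False)
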