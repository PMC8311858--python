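"""End-to-end orchestration: simulate/load -> graphs -> partition -> metrics
-> statistics, with every artifact written as delimited text plus a JSON run
report carrying the seed and configuration hash."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from connseg import io
from connseg.graph_build import DEFAULT_THRESHOLDS, fisher_z_connectivity, multi_threshold_graphs
from connseg.node_metrics import metrics_table, module_connection_counts
from connseg.nodes import CONTROL_LABELS, TARGET_LABEL, node_id_of
from connseg.partition import ModularPartition
from connseg.reference_modules import group_mean_matrix, load_reference_partition, ward_partition, write_partition
from connseg.stats import (
    brain_behavior_model,
    change_model,
    independent_group_test,
    paired_change_test,
    per_module_comparisons,
    pretreatment_model,
)
from connseg.synthetic_data import Cohort, default_design, simulate_cohort

log = logging.getLogger("connseg")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    With ``simulate=True`` (default) a synthetic cohort is generated from the
    stock design and ``design_overrides``; otherwise ``timeseries_dir``,
    ``node_table_path`` and ``covariates_path`` must point at existing
    delimited-text inputs.  The reference partition is loaded from
    ``partition_path`` when given, else derived from the control group's mean
    matrix by a Ward cut at ``k_modules``.
    """

    out_dir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    design_overrides: dict = field(default_factory=dict)
    timeseries_dir: str | None = None
    node_table_path: str | None = None
    covariates_path: str | None = None
    partition_path: str | None = None
    k_modules: int = 7
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    target: str = TARGET_LABEL
    controls: tuple[str, ...] = CONTROL_LABELS
    welch: bool = False
    ranking: str = "signed"
    hemisphere_analysis: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["controls"] = list(self.controls)
        return d


def _load_cohort_from_files(config: RunConfig) -> tuple[Cohort, pd.DataFrame]:
    node_table = io.read_node_table(config.node_table_path)
    covariates = io.read_covariates(config.covariates_path)
    ts_dir = Path(config.timeseries_dir)
    timeseries = {}
    for _, row in covariates.iterrows():
        key = (row["subject_id"], row["timepoint"])
        path = ts_dir / f"{key[0]}_{key[1]}.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"stage load: missing time series for subject {key[0]} "
                f"timepoint {key[1]}: {path}"
            )
        ts, labels = io.read_timeseries(path)
        if labels != node_table["label"].tolist():
            raise ValueError(f"stage load: ROI labels in {path} do not match node table")
        timeseries[key] = ts
    return Cohort(timeseries, covariates, {}), node_table


def analyze_cohort(
    cohort: Cohort,
    node_table: pd.DataFrame,
    partition: ModularPartition | None = None,
    k_modules: int = 7,
    thresholds=DEFAULT_THRESHOLDS,
    target: str = TARGET_LABEL,
    controls=CONTROL_LABELS,
    welch: bool = False,
    ranking: str = "signed",
) -> dict:
    """Run the analysis stages on an in-memory cohort.

    Returns a dict with the connectivity matrices, reference partition,
    long-format metrics table, and the per-ROI statistics.
    """
    matrices = {
        key: fisher_z_connectivity(ts) for key, ts in cohort.timeseries.items()
    }

    if partition is None:
        hc_keys = [
            (row["subject_id"], row["timepoint"])
            for _, row in cohort.covariates.iterrows()
            if row["cohort"] == "HC"
        ]
        if not hc_keys:
            raise ValueError(
                "stage find-modules: no healthy-control scans to derive the "
                "reference partition from; supply a partition instead"
            )
        mean_hc = group_mean_matrix([matrices[k] for k in hc_keys])
        partition = ward_partition(mean_hc, k_modules)

    graphsets = {
        key: multi_threshold_graphs(mat, thresholds, ranking=ranking)
        for key, mat in matrices.items()
    }

    roi_labels = [target, *controls]
    roi_ids = [node_id_of(node_table, lab) for lab in roi_labels]
    metrics = metrics_table(graphsets, partition, node_table, roi_ids)

    stats = {
        lab: analyze_roi(
            metrics, cohort.covariates, lab,
            graphsets=graphsets, partition=partition,
            node_table=node_table,
            node_id=nid, welch=welch,
            per_module=(lab == target),
        )
        for lab, nid in zip(roi_labels, roi_ids)
    }

    return dict(
        matrices=matrices,
        partition=partition,
        graphsets=graphsets,
        metrics=metrics,
        stats=stats,
    )


def pc_values(metrics: pd.DataFrame, node_label: str) -> pd.DataFrame:
    """Threshold-averaged PC per subject/timepoint for one node."""
    sel = (
        (metrics["node_label"] == node_label)
        & (metrics["metric"] == "pc")
        & (metrics["threshold"] == "mean")
    )
    return metrics.loc[sel, ["subject_id", "timepoint", "value"]].reset_index(drop=True)


def metric_values(metrics: pd.DataFrame, node_label: str, metric: str) -> pd.DataFrame:
    sel = (
        (metrics["node_label"] == node_label)
        & (metrics["metric"] == metric)
        & (metrics["threshold"] == "mean")
    )
    return metrics.loc[sel, ["subject_id", "timepoint", "value"]].reset_index(drop=True)


def delta_table(values: pd.DataFrame) -> pd.DataFrame:
    """Post-minus-pre change per subject from a subject/timepoint value table."""
    wide = values.pivot(index="subject_id", columns="timepoint", values="value")
    for tp in ("pre", "post"):
        if tp not in wide.columns or wide[tp].isna().any():
            missing = (
                wide.index[wide[tp].isna()].tolist() if tp in wide.columns
                else wide.index.tolist()
            )
            raise ValueError(f"subject(s) missing {tp} timepoint: {missing}")
    return pd.DataFrame(
        {"subject_id": wide.index, "value": (wide["post"] - wide["pre"]).to_numpy()}
    )


def analyze_roi(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    node_label: str,
    graphsets: dict | None = None,
    partition: ModularPartition | None = None,
    node_table: pd.DataFrame | None = None,
    node_id: int | None = None,
    welch: bool = False,
    per_module: bool = False,
) -> dict:
    """The full statistical battery for one ROI's threshold-averaged PC.

    Always runs the pre-treatment models, the arm change model, per-arm
    paired tests and per-timepoint independent tests against HC; with
    ``per_module=True`` additionally compares within/between connection
    counts and each between-module count against HC with BH-FDR correction,
    and fits the brain-behavior interaction model.
    """
    subj_cov = covariates.drop_duplicates("subject_id")
    pc = pc_values(metrics, node_label)

    pre = pc[pc["timepoint"].isin(["pre", "single"])]
    fit_cohort, fit_severity = pretreatment_model(
        pre[["subject_id", "value"]], subj_cov
    )

    patients = pc[pc["timepoint"].isin(["pre", "post"])]
    delta = delta_table(patients)
    fit_change = change_model(delta, subj_cov)

    arm_of = dict(zip(subj_cov["subject_id"], subj_cov["arm"]))
    paired = {}
    for arm in ("active", "sham"):
        sids = [s for s in delta["subject_id"] if arm_of.get(s) == arm]
        wide = patients[patients["subject_id"].isin(sids)].pivot(
            index="subject_id", columns="timepoint", values="value"
        )
        paired[arm] = paired_change_test(
            wide["pre"].to_numpy(), wide["post"].to_numpy()
        )

    hc_vals = pc.loc[pc["timepoint"] == "single", "value"].to_numpy()
    vs_hc = {}
    for tp in ("pre", "post"):
        vals = pc.loc[pc["timepoint"] == tp, "value"].to_numpy()
        if hc_vals.size >= 2 and vals.size >= 2:
            vs_hc[tp] = independent_group_test(vals, hc_vals, welch=welch)

    out = dict(
        pretreatment_cohort=fit_cohort,
        pretreatment_severity=fit_severity,
        change=fit_change,
        paired=paired,
        vs_hc=vs_hc,
    )

    if per_module:
        within = metric_values(metrics, node_label, "within_count")
        between = metric_values(metrics, node_label, "between_count")
        counts_vs_hc = {}
        for name, table in (("within", within), ("between", between)):
            hc = table.loc[table["timepoint"] == "single", "value"].to_numpy()
            for tp in ("pre", "post"):
                vals = table.loc[table["timepoint"] == tp, "value"].to_numpy()
                if hc.size >= 2 and vals.size >= 2:
                    counts_vs_hc[f"{name}_{tp}"] = independent_group_test(
                        vals, hc, welch=welch
                    )
        out["counts_vs_hc"] = counts_vs_hc

        if partition is not None and graphsets is not None and node_id is not None:
            out["per_module_vs_hc"] = _per_module_tests(
                graphsets, partition, node_id, covariates, welch
            )

        gains = subj_cov.set_index("subject_id")["behavior_gain"]
        bb = pd.DataFrame(
            {
                "subject_id": delta["subject_id"],
                "delta_pc": delta["value"].to_numpy(),
                "behavior_gain": gains.reindex(delta["subject_id"]).to_numpy(),
            }
        )
        if not bb["behavior_gain"].isna().any():
            out["brain_behavior"] = brain_behavior_model(
                bb, subj_cov.drop(columns=["behavior_gain"])
            )
    return out


def _per_module_tests(graphsets, partition, node_id, covariates, welch):
    """Per-module count comparisons (patients pre vs HC), FDR within the
    between-module family."""
    rows = []
    for _, r in covariates.iterrows():
        key = (r["subject_id"], r["timepoint"])
        if key not in graphsets:
            continue
        counts = module_connection_counts(graphsets[key], partition, node_id)
        for _, m in counts.iterrows():
            rows.append(
                {
                    "subject_id": r["subject_id"],
                    "cohort": r["cohort"],
                    "timepoint": r["timepoint"],
                    "module_name": m["module_name"],
                    "is_own": m["is_own"],
                    "value": m["mean_count"],
                }
            )
    long = pd.DataFrame(rows)
    hc = long[long["cohort"] == "HC"]
    out = {}
    for tp in ("pre", "post"):
        pat = long[(long["cohort"] == "PPA") & (long["timepoint"] == tp)]
        if not pat.empty and not hc.empty:
            out[tp] = per_module_comparisons(pat, hc, welch=welch)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Returns the run report (also written as ``report.json``).  Outputs are
    deterministic given the same inputs and seed: rerunning into a different
    directory produces byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.to_dict())
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.simulate:
        design = default_design(seed=config.seed, **config.design_overrides)
        cohort = simulate_cohort(design)
        node_table = design.node_table
    else:
        cohort, node_table = _load_cohort_from_files(config)
    timings["load_or_simulate"] = time.perf_counter() - t0
    log.info("cohort ready: %d scans", len(cohort.timeseries))

    partition = None
    if config.partition_path:
        partition = load_reference_partition(config.partition_path, node_table)

    t0 = time.perf_counter()
    result = analyze_cohort(
        cohort, node_table,
        partition=partition,
        k_modules=config.k_modules,
        thresholds=config.thresholds,
        target=config.target,
        controls=config.controls,
        welch=config.welch,
        ranking=config.ranking,
    )
    timings["analysis"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    io.write_metrics(out / "metrics.tsv", result["metrics"])
    write_partition(result["partition"], node_table, out / "partition.tsv")
    io.write_node_table(out / "nodes.tsv", node_table)
    io.write_covariates(out / "covariates.tsv", cohort.covariates)
    stats_payload = {
        lab: _stats_to_dict(block) for lab, block in result["stats"].items()
    }
    io.write_json(out / "stats.json", stats_payload)
    report = dict(
        config=config.to_dict(),
        config_hash=chash,
        seed=config.seed,
        n_scans=len(cohort.timeseries),
        n_rois_analyzed=1 + len(config.controls),
        n_modules=result["partition"].n_modules,
        timings=timings,
    )
    io.write_json(out / "report.json", report)
    timings["write"] = time.perf_counter() - t0
    return dict(report=report, **result)


def _stats_to_dict(block):
    from connseg.stats import StatResult

    if isinstance(block, StatResult):
        d = dict(
            model_id=block.model_id,
            n=block.n,
            df_resid=block.df_resid,
            terms={
                str(idx): {k: float(v) for k, v in row.items()}
                for idx, row in block.terms.iterrows()
            },
        )
        if block.extra:
            d["extra"] = block.extra
        return d
    if isinstance(block, pd.DataFrame):
        return block.to_dict(orient="records")
    if isinstance(block, dict):
        return {k: _stats_to_dict(v) for k, v in block.items()}
    return block
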