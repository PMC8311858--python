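"""Monte-Carlo studies over planted cohorts: type-I calibration and
effect recovery.

A *replicate* simulates one full cohort, derives the reference partition
from the healthy-control scans exactly as the main pipeline does, computes
the target node's threshold-averaged participation coefficient and
between-module counts, and fits the statistical battery.  Replicates are
driven by a base seed plus replicate index, so studies are reproducible and
embarrassingly parallel in principle (run serially here).

Two study conditions are packaged:

* the *null* condition sets every planted effect to zero (severity slope,
  treatment effect, brain-behavior coupling) to measure type-I error of each
  model at the study's sample sizes (19 controls, 16 per arm);
* the *effect* condition plants the default strong effects (severity slope
  0.02 per severity point, active-arm between-module correlation reduction
  0.15, brain-behavior coupling slopes -8/+8 gain-percent per SD of PC
  change) to measure detection rates.

Scan length per condition is a deliberate trade-off between correlation
sampling noise (~1/sqrt(T)) and simulation cost; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from connseg.graph_build import DEFAULT_THRESHOLDS, fisher_z_connectivity, multi_threshold_graphs
from connseg.node_metrics import threshold_averaged_pc, within_between_counts
from connseg.nodes import CONTROL_LABELS, TARGET_LABEL, node_id_of
from connseg.reference_modules import group_mean_matrix, ward_partition
from connseg.stats import (
    brain_behavior_model,
    change_model,
    independent_group_test,
    paired_change_test,
    pretreatment_model,
)
from connseg.synthetic_data import default_design, make_behavior_gain, simulate_cohort

#: Brain-behavior coupling (gain percent per SD of PC change) in the
#: effect condition: active patients gain more the more their PC drops,
#: sham patients show the opposite relation.  With gain noise of 8 percent
#: the planted within-arm association is |r| ~ 0.78, matching the strong
#: per-arm correlation magnitude the analysis is designed to detect.
EFFECT_COUPLING = (-10.0, 10.0)
EFFECT_GAIN_NOISE = 8.0

NULL_OVERRIDES = dict(severity_slope=0.0, treatment_effect=0.0)


@dataclass
class ReplicateResult:
    """Scalar statistics of one simulated cohort."""

    stats: dict  # name -> dict(estimate=..., t=..., p=...)
    partition_modules: int


def _term_summary(result, term_name):
    row = result.term(term_name)
    return dict(estimate=float(row["estimate"]), t=float(row["t"]), p=float(row["p"]))


def run_replicate(
    rep_seed: int,
    design_overrides: dict | None = None,
    coupling: tuple[float, float] | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    k_modules: int = 7,
    control_labels=CONTROL_LABELS,
) -> ReplicateResult:
    """Simulate one cohort and fit the full battery on the target node.

    ``coupling`` (slope_active, slope_sham) regenerates behavioral gains
    from the realized PC changes; ``None`` leaves gains uncoupled noise.
    """
    design = default_design(seed=rep_seed, **(design_overrides or {}))
    cohort = simulate_cohort(design)
    node_table = design.node_table
    target = node_id_of(node_table, TARGET_LABEL)
    control_ids = {lab: node_id_of(node_table, lab) for lab in control_labels}

    matrices = {k: fisher_z_connectivity(ts) for k, ts in cohort.timeseries.items()}
    hc_keys = [
        (r["subject_id"], r["timepoint"])
        for _, r in cohort.covariates.iterrows()
        if r["cohort"] == "HC"
    ]
    partition = ward_partition(
        group_mean_matrix([matrices[k] for k in hc_keys]), k_modules
    )

    rows = []
    nodes_of_interest = [target, *control_ids.values()]
    for key, mat in matrices.items():
        gs = multi_threshold_graphs(mat, thresholds)
        mean_pc, _ = threshold_averaged_pc(gs, partition)
        record = dict(subject_id=key[0], timepoint=key[1])
        for nid in nodes_of_interest:
            record[f"pc_{nid}"] = mean_pc[nid]
        within, between = within_between_counts(gs, partition, target)
        record["within"] = within
        record["between"] = between
        rows.append(record)
    scan_table = pd.DataFrame(rows)

    cov = cohort.covariates
    subj_cov = cov.drop_duplicates("subject_id").copy()
    stats: dict[str, dict] = {}

    def wide(col):
        return scan_table.pivot(index="subject_id", columns="timepoint", values=col)

    pc_wide = wide(f"pc_{target}")
    arm_of = dict(zip(subj_cov["subject_id"], subj_cov["arm"]))
    cohort_of = dict(zip(subj_cov["subject_id"], subj_cov["cohort"]))

    # pre-treatment models on the target PC
    pre_vals = []
    for sid in pc_wide.index:
        tp = "single" if cohort_of[sid] == "HC" else "pre"
        pre_vals.append((sid, pc_wide.loc[sid, tp]))
    pre_df = pd.DataFrame(pre_vals, columns=["subject_id", "value"])
    fit_cohort, fit_severity = pretreatment_model(pre_df, subj_cov)
    stats["pretreatment_cohort"] = _term_summary(fit_cohort, "PPA")
    stats["pretreatment_severity"] = _term_summary(fit_severity, "severity")

    # change model + paired tests
    patients = [s for s in pc_wide.index if cohort_of[s] == "PPA"]
    delta = pd.DataFrame(
        {
            "subject_id": patients,
            "value": [
                pc_wide.loc[s, "post"] - pc_wide.loc[s, "pre"] for s in patients
            ],
        }
    )
    fit_change = change_model(delta, subj_cov)
    stats["change_arm"] = _term_summary(fit_change, "active")
    for arm in ("active", "sham"):
        sids = [s for s in patients if arm_of[s] == arm]
        res = paired_change_test(
            pc_wide.loc[sids, "pre"].to_numpy(), pc_wide.loc[sids, "post"].to_numpy()
        )
        stats[f"paired_{arm}"] = _term_summary(res, "mean_change")

    # control-ROI change models (regional specificity)
    for lab, nid in control_ids.items():
        w = wide(f"pc_{nid}")
        d = pd.DataFrame(
            {
                "subject_id": patients,
                "value": [w.loc[s, "post"] - w.loc[s, "pre"] for s in patients],
            }
        )
        stats[f"change_arm_{lab}"] = _term_summary(change_model(d, subj_cov), "active")

    # target PC and between-count comparisons against HC
    hc_ids = [s for s in pc_wide.index if cohort_of[s] == "HC"]
    active_ids = [s for s in patients if arm_of[s] == "active"]
    between_wide = wide("between")
    stats["pc_pre_vs_hc"] = _term_summary(
        independent_group_test(
            pc_wide.loc[patients, "pre"].to_numpy(),
            pc_wide.loc[hc_ids, "single"].to_numpy(),
        ),
        "mean_difference",
    )
    for tp in ("pre", "post"):
        stats[f"between_{tp}_vs_hc"] = _term_summary(
            independent_group_test(
                between_wide.loc[active_ids, tp].to_numpy(),
                between_wide.loc[hc_ids, "single"].to_numpy(),
            ),
            "mean_difference",
        )

    # brain-behavior interaction
    if coupling is not None:
        gain_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=rep_seed, spawn_key=(10**6,))
        )
        gains = make_behavior_gain(
            delta.set_index("subject_id")["value"],
            pd.Series(arm_of),
            slope_active=coupling[0],
            slope_sham=coupling[1],
            noise_sd=EFFECT_GAIN_NOISE,
            seed=gain_rng,
        )
        subj_cov.loc[subj_cov["cohort"] == "PPA", "behavior_gain"] = (
            subj_cov.loc[subj_cov["cohort"] == "PPA", "subject_id"].map(gains).to_numpy()
        )
    bb = pd.DataFrame(
        {
            "subject_id": delta["subject_id"],
            "delta_pc": delta["value"].to_numpy(),
            "behavior_gain": subj_cov.set_index("subject_id")["behavior_gain"]
            .reindex(delta["subject_id"])
            .to_numpy(),
        }
    )
    fit_bb = brain_behavior_model(bb, subj_cov)
    stats["interaction"] = _term_summary(fit_bb, "delta_pc:")
    stats["simple_slopes"] = fit_bb.extra["simple_slopes"]

    return ReplicateResult(stats=stats, partition_modules=partition.n_modules)


def _rep_seed(base_seed: int, rep: int) -> int:
    # distinct, reproducible, and well below 2**31
    return int((base_seed * 100_003 + rep) % 2_000_000_011)


def type_one_error_study(
    n_reps: int = 500, base_seed: int = 0, T: int = 60, alpha: float = 0.05
) -> pd.DataFrame:
    """Rejection rates of each model when every planted effect is zero."""
    models = [
        "pretreatment_cohort", "pretreatment_severity", "change_arm",
        "paired_active", "paired_sham", "pc_pre_vs_hc", "interaction",
    ]
    rejections = {m: 0 for m in models}
    for rep in range(n_reps):
        overrides = dict(NULL_OVERRIDES, T=T, hc_T=T)
        result = run_replicate(_rep_seed(base_seed, rep), overrides, coupling=None)
        for m in models:
            if result.stats[m]["p"] < alpha:
                rejections[m] += 1
    return pd.DataFrame(
        {
            "model": models,
            "rejections": [rejections[m] for m in models],
            "n_reps": n_reps,
            "rate": [rejections[m] / n_reps for m in models],
        }
    )


#: Detection criteria of the effect condition.
#: "positive"/"negative" require a significant effect with that sign;
#: "null" counts rejections where the planted truth has no effect (rates
#: should stay near alpha); "shrinks" requires the post-treatment elevation
#: over HC to fall below half its pre-treatment size — the planted flat
#: treatment reduction cancels the *average* severity elevation, so
#: normalization means a large shrinkage of the group elevation, not an
#: exactly-zero residual.
EFFECT_PATTERN = {
    "pretreatment_severity": "positive",
    "change_arm": "negative",
    "paired_active": "negative",
    "paired_sham": "null",
    "between_pre_vs_hc": "positive",
    "between_post_vs_hc": "shrinks",
    "interaction": "negative",
    **{f"change_arm_{lab}": "null" for lab in CONTROL_LABELS},
}


def effect_recovery_study(
    n_reps: int = 200,
    base_seed: int = 0,
    T: int = 1000,
    alpha: float = 0.05,
    design_overrides: dict | None = None,
) -> pd.DataFrame:
    """Detection rates of the planted qualitative pattern at strong effects."""
    counts = {name: 0 for name in EFFECT_PATTERN}
    for rep in range(n_reps):
        overrides = dict(T=T, hc_T=T)
        overrides.update(design_overrides or {})
        result = run_replicate(
            _rep_seed(base_seed, rep), overrides, coupling=EFFECT_COUPLING
        )
        for name, requirement in EFFECT_PATTERN.items():
            s = result.stats[name]
            if requirement == "positive":
                hit = s["p"] < alpha and s["estimate"] > 0
            elif requirement == "negative":
                hit = s["p"] < alpha and s["estimate"] < 0
            elif requirement == "shrinks":
                pre = result.stats["between_pre_vs_hc"]["estimate"]
                hit = pre > 0 and s["estimate"] < 0.5 * pre
            else:  # "null": the planted truth has no effect; count rejections
                hit = s["p"] < alpha
            counts[name] += hit
    return pd.DataFrame(
        {
            "statistic": list(EFFECT_PATTERN),
            "requirement": [EFFECT_PATTERN[k] for k in EFFECT_PATTERN],
            "hits": [counts[k] for k in EFFECT_PATTERN],
            "n_reps": n_reps,
            "rate": [counts[k] / n_reps for k in EFFECT_PATTERN],
        }
    )


def partition_recovery_study(
    n_reps: int = 20, base_seed: int = 0, T: int = 210
) -> pd.DataFrame:
    """ARI between the Ward-derived and planted partitions over replicates."""
    from sklearn.metrics import adjusted_rand_score

    rows = []
    for rep in range(n_reps):
        # patients are irrelevant to the reference organization: HC only
        design = default_design(seed=_rep_seed(base_seed, rep), T=T, hc_T=T,
                                n_per_arm=0)
        cohort = simulate_cohort(design)
        mats = [
            fisher_z_connectivity(ts) for _, _, ts in cohort.scans(cohort="HC")
        ]
        part = ward_partition(group_mean_matrix(mats), 7)
        ari = adjusted_rand_score(design.partition.assignment, part.assignment)
        rows.append({"rep": rep, "ari": float(ari)})
    return pd.DataFrame(rows)
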