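"""Synthetic cohorts with planted modular structure and treatment effects.

The generator emulates the statistical skeleton of a longitudinal
resting-state connectivity study: a healthy-control (HC) group scanned once
and a patient group scanned before and after treatment, with patients split
into an active-stimulation arm and a sham arm.  ROI signals are drawn from a
zero-mean multivariate normal whose correlation matrix has a two-level block
structure (``within_r`` inside planted modules, ``between_r`` across them).
One designated target node is perturbed: its between-module correlations are
raised in proportion to each patient's dementia-severity score, and lowered
again at the post-treatment timepoint in the active arm only.  Every planted
parameter is recorded so downstream stages can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from connseg.nodes import default_node_table, node_id_of, validate_node_table
from connseg.partition import ModularPartition


class GenerationError(RuntimeError):
    """Raised when a planted design cannot produce a usable covariance."""


class InvalidDesignError(ValueError):
    """Raised for structurally impossible design requests."""


def make_partition(
    n_nodes: int, n_modules: int, node_table: pd.DataFrame
) -> ModularPartition:
    """Plant a partition of ``n_nodes`` into ``n_modules`` bilateral modules.

    Homolog pairs (same structure, opposite hemisphere) are kept together so
    every module receives nodes from both hemispheres, mirroring the bilateral
    resting-state modules seen in group connectomes.  Module sizes are as
    equal as divisibility allows.  When ``n_modules`` exceeds the number of
    homolog pairs, bilaterality is impossible and nodes are split
    individually (the ``n_modules == n_nodes`` limit yields singletons).
    """
    if n_modules > n_nodes:
        raise InvalidDesignError(
            f"cannot split {n_nodes} nodes into {n_modules} modules"
        )
    if n_modules < 1:
        raise InvalidDesignError("n_modules must be >= 1")
    validate_node_table(node_table)
    table = node_table.iloc[:n_nodes]
    left = table.loc[table["hemisphere"] == "L", "node_id"].to_numpy()
    right = table.loc[table["hemisphere"] == "R", "node_id"].to_numpy()

    assignment = np.empty(n_nodes, dtype=int)
    if len(left) == len(right) and n_modules <= len(left) and len(left) > 0:
        # assign homolog pairs (matched by position within each hemisphere)
        # to modules in nearly equal contiguous blocks
        pair_modules = _balanced_blocks(len(left), n_modules)
        assignment[left] = pair_modules
        assignment[right] = pair_modules
    else:
        assignment[table["node_id"].to_numpy()] = _balanced_blocks(
            n_nodes, n_modules
        )
    return ModularPartition(assignment)


def _balanced_blocks(n_items: int, n_blocks: int) -> np.ndarray:
    """Block ids 0..n_blocks-1 over n_items, sizes differing by at most 1."""
    base, extra = divmod(n_items, n_blocks)
    sizes = [base + (1 if b < extra else 0) for b in range(n_blocks)]
    return np.repeat(np.arange(n_blocks), sizes)


@dataclass(frozen=True)
class GroundTruthDesign:
    """Every planted parameter of a synthetic cohort.

    Defaults mirror the study design the pipeline targets: 76 nodes in 7
    bilateral modules, 19 HC and 16 subjects per treatment arm, 210 time
    points per scan, severity on a 0-15 dementia-rating scale.
    """

    partition: ModularPartition
    node_table: pd.DataFrame
    within_r: float = 0.5
    between_r: float = 0.1
    target_node: int = 0
    severity_slope: float = 0.02
    treatment_effect: float = 0.15
    n_hc: int = 19
    n_per_arm: int = 16
    T: int = 210
    hc_T: int | None = None  # HC scan length when the two protocols differ
    seed: int = 0
    psd_drift_bound: float = 0.05
    severity_range: tuple[float, float] = (1.0, 15.0)

    def __post_init__(self) -> None:
        if not (abs(self.within_r) < 1 and abs(self.between_r) < 1):
            raise InvalidDesignError("|within_r| and |between_r| must be < 1")
        if self.within_r <= self.between_r:
            raise InvalidDesignError(
                "within_r must exceed between_r for modular structure"
            )
        n = self.partition.n_nodes
        if not (0 <= self.target_node < n):
            raise InvalidDesignError(f"target_node {self.target_node} out of range")
        if len(self.node_table) != n:
            raise InvalidDesignError("node_table size does not match partition")
        if self.T < 2:
            raise InvalidDesignError("T must be >= 2")


def default_design(**overrides) -> GroundTruthDesign:
    """The stock 76-node / 7-module design with the L IFG-triangularis target."""
    table = default_node_table()
    part = make_partition(len(table), 7, table)
    kwargs = dict(
        partition=part,
        node_table=table,
        target_node=node_id_of(table, "L_IFG_tri"),
    )
    kwargs.update(overrides)
    return GroundTruthDesign(**kwargs)


def build_block_covariance(
    design: GroundTruthDesign,
    severity: float = 0.0,
    timepoint: str = "single",
    arm: str = "none",
) -> np.ndarray:
    """Planted node-by-node correlation matrix for one scan.

    Entries are ``within_r`` inside modules and ``between_r`` across modules,
    with unit diagonal.  The target node's between-module entries become
    ``between_r + severity_slope * severity``, minus ``treatment_effect``
    when the scan is a post-treatment scan in the active arm.  The result is
    repaired to the nearest positive semi-definite correlation matrix if the
    perturbation breaks PSD; repair aborts if any entry drifts more than
    ``design.psd_drift_bound``.
    """
    part = design.partition
    same_module = part.assignment[:, None] == part.assignment[None, :]
    cov = np.where(same_module, design.within_r, design.between_r)

    t = design.target_node
    r_target = design.between_r + design.severity_slope * severity
    if timepoint == "post" and arm == "active":
        r_target -= design.treatment_effect
    r_target = float(np.clip(r_target, -0.99, 0.99))
    between_target = ~same_module[t]
    cov[t, between_target] = r_target
    cov[between_target, t] = r_target
    np.fill_diagonal(cov, 1.0)
    return repair_psd(cov, drift_bound=design.psd_drift_bound)


def repair_psd(
    cov: np.ndarray, drift_bound: float = 0.05, eig_floor: float = 1e-8
) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone and restore unit diagonal.

    Negative eigenvalues are clipped to ``eig_floor``, the matrix is
    reconstructed, re-symmetrized and rescaled to a correlation matrix.
    Raises :class:`GenerationError` if any entry moves by more than
    ``drift_bound``, which would mean the repair destroyed the planted
    structure.
    """
    cov = np.asarray(cov, dtype=float)
    sym = (cov + cov.T) / 2
    vals = np.linalg.eigvalsh(sym)
    if vals[0] >= eig_floor and np.allclose(np.diag(sym), 1.0):
        return sym
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eig_floor, None)
    rep = (v * w) @ v.T
    d = np.sqrt(np.diag(rep))
    rep = rep / np.outer(d, d)
    rep = (rep + rep.T) / 2
    np.fill_diagonal(rep, 1.0)
    drift = float(np.max(np.abs(rep - sym)))
    if drift > drift_bound:
        raise GenerationError(
            f"PSD repair moved an entry by {drift:.4f} > bound {drift_bound}"
        )
    return rep


def simulate_timeseries(
    cov: np.ndarray, T: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw an n x T matrix of ROI signals from N(0, cov).

    ``seed`` may be an integer or a ``numpy.random.Generator``; a fixed
    integer seed reproduces the scan bit for bit.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance is not positive semi-definite") from exc
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return chol @ rng.standard_normal((len(cov), T))


@dataclass
class Cohort:
    """One simulated cohort: scans, covariates, and the planted truth."""

    timeseries: dict[tuple[str, str], np.ndarray]  # (subject_id, timepoint) -> n x T
    covariates: pd.DataFrame  # one row per subject/timepoint scan
    ground_truth: dict

    def scans(self, cohort: str | None = None, timepoint: str | None = None):
        """Iterate (subject_id, timepoint, array) filtered by covariate values."""
        cov = self.covariates
        mask = pd.Series(True, index=cov.index)
        if cohort is not None:
            mask &= cov["cohort"] == cohort
        if timepoint is not None:
            mask &= cov["timepoint"] == timepoint
        for _, row in cov[mask].iterrows():
            key = (row["subject_id"], row["timepoint"])
            yield key[0], key[1], self.timeseries[key]


# demographic defaults: (mean, sd) per group, and count of female subjects
_AGE = {"HC": (65.0, 8.14), "active": (64.0, 7.45), "sham": (69.0, 5.06)}
_EDU = {"HC": (16.0, 2.63), "active": (17.0, 2.02), "sham": (17.0, 1.91)}
_N_FEMALE = {"HC": 14, "active": 8, "sham": 8}


def _subject_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    """Deterministic per-subject substream: adding subjects never perturbs
    the draws of existing ones."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index, stream))
    )


def simulate_cohort(design: GroundTruthDesign) -> Cohort:
    """Simulate the full longitudinal cohort a study run consumes.

    HC subjects are scanned once (``timepoint="single"``); each patient is
    scanned at ``pre`` and ``post``.  Severity, age, gender, education and
    in-scanner motion are drawn per subject from configured distributions;
    the planted covariance follows each patient's severity, arm and
    timepoint.  ``behavior_gain`` is filled with uncoupled noise — couple it
    to realized connectivity changes with :func:`make_behavior_gain`.
    """
    timeseries: dict[tuple[str, str], np.ndarray] = {}
    rows: list[dict] = []
    severities: dict[str, float] = {}

    hc_T = design.hc_T if design.hc_T is not None else design.T
    subject_index = 0

    for i in range(design.n_hc):
        sid = f"HC{i + 1:02d}"
        demo = _subject_rng(design.seed, subject_index, 0)
        age = demo.normal(*_AGE["HC"])
        edu = max(8.0, demo.normal(*_EDU["HC"]))
        gender = "F" if i < _N_FEMALE["HC"] else "M"
        motion = float(np.exp(demo.normal(-2.3, 0.4)))
        cov = build_block_covariance(design, severity=0.0)
        scan_rng = _subject_rng(design.seed, subject_index, 1)
        timeseries[(sid, "single")] = simulate_timeseries(cov, hc_T, scan_rng)
        rows.append(
            dict(
                subject_id=sid, cohort="HC", arm="none", timepoint="single",
                age=age, gender=gender, education=edu, severity=0.0,
                motion_rms=motion, behavior_gain=np.nan,
            )
        )
        subject_index += 1

    lo, hi = design.severity_range
    for arm, prefix in (("active", "TD"), ("sham", "SH")):
        for i in range(design.n_per_arm):
            sid = f"{prefix}{i + 1:02d}"
            demo = _subject_rng(design.seed, subject_index, 0)
            age = demo.normal(*_AGE[arm])
            edu = max(8.0, demo.normal(*_EDU[arm]))
            gender = "F" if i < _N_FEMALE[arm] else "M"
            severity = float(demo.uniform(lo, hi))
            severities[sid] = severity
            gain = float(np.clip(demo.normal(50.0, 15.0), 0.0, 100.0))
            for stream, tp in ((1, "pre"), (2, "post")):
                cov = build_block_covariance(
                    design, severity=severity, timepoint=tp, arm=arm
                )
                scan_rng = _subject_rng(design.seed, subject_index, stream)
                timeseries[(sid, tp)] = simulate_timeseries(
                    cov, design.T, scan_rng
                )
                motion = float(np.exp(demo.normal(-2.3, 0.4)))
                rows.append(
                    dict(
                        subject_id=sid, cohort="PPA", arm=arm, timepoint=tp,
                        age=age, gender=gender, education=edu,
                        severity=severity, motion_rms=motion,
                        behavior_gain=gain,
                    )
                )
            subject_index += 1

    covariates = pd.DataFrame(rows)
    ground_truth = dict(
        within_r=design.within_r,
        between_r=design.between_r,
        target_node=int(design.target_node),
        severity_slope=design.severity_slope,
        treatment_effect=design.treatment_effect,
        n_hc=design.n_hc,
        n_per_arm=design.n_per_arm,
        T=design.T,
        hc_T=hc_T,
        seed=design.seed,
        partition=design.partition.assignment.tolist(),
        severities=severities,
    )
    return Cohort(timeseries, covariates, ground_truth)


def make_behavior_gain(
    delta_pc: Mapping[str, float] | pd.Series,
    arm: Mapping[str, str] | pd.Series,
    slope_active: float,
    slope_sham: float,
    noise_sd: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Couple behavioral gain (percent of maximal gain) to realized PC change.

    Gains are ``50 + slope * z(delta_pc) + noise`` clipped to [0, 100],
    where z standardizes the PC change *within each arm* (so the coupling
    expresses individual differences around each arm's mean change, not the
    arm-mean offset itself) and the slope is chosen per treatment arm — the
    planted brain-behavior interaction is ``slope_active - slope_sham``.
    """
    delta = pd.Series(delta_pc, dtype=float)
    arms = pd.Series(arm).reindex(delta.index)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = pd.Series(0.0, index=delta.index)
    for arm_name, grp in delta.groupby(arms):
        sd = float(grp.std(ddof=1))
        z[grp.index] = (grp - grp.mean()) / (sd if sd > 0 else 1.0)
    slopes = arms.map({"active": slope_active, "sham": slope_sham}).astype(float)
    gains = 50.0 + slopes * z + noise_sd * rng.standard_normal(len(delta))
    return gains.clip(0.0, 100.0)
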