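"""End-to-end study replica: simulate/ingest -> connect -> threshold ->
measure -> compare -> correlate -> regress, plus validation harnesses.

One seeded run executes the primary analysis (binary networks, sparsity
0.10-0.22) and the two robustness variants (binary over the extended
0.05-0.25 range; weighted networks over the primary range), reusing the
per-subject Fisher-z matrices across variants, and emits the full set of
results tables as CSV with a JSON provenance manifest. Identical config and
seed reproduce every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .atlas import default_labels
from .connectivity import ROITimeSeries, connectivity_from_timeseries, seed_fc_contrast
from .errors import ConfigurationError
from .graph_metrics import (
    EXTENDED_GRID,
    GLOBAL_METRICS,
    NODAL_METRICS,
    PRIMARY_GRID,
    SparsityGrid,
    SubjectMetrics,
    compute_subject_metrics,
)
from .group_stats import (
    PairedSample,
    bh_fdr,
    compare_paired,
    linear_regression,
    paired_table,
    spearman_table,
)
from .synthetic import (
    BEHAVIOR_TESTS,
    GeneratorConfig,
    PairedSubjectRecord,
    generate_paired_dataset,
    read_dataset,
)

logger = logging.getLogger("netshift")

VARIANTS: tuple[tuple[str, str, str], ...] = (
    # (variant name, grid role, mode)
    ("original_binary", "primary", "binary"),
    ("extended_binary", "extended", "binary"),
    ("weighted", "primary", "weighted"),
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full study run."""

    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    primary_grid: SparsityGrid = PRIMARY_GRID
    extended_grid: SparsityGrid = EXTENDED_GRID
    variants: tuple[str, ...] = tuple(v[0] for v in VARIANTS)
    n_rand: int = 100
    seed_region: int = 24
    degraded_region: int = 55
    q: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    global_metrics: tuple[str, ...] = GLOBAL_METRICS
    nodal_metrics: tuple[str, ...] = NODAL_METRICS
    threads: int = 1

    def validate(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ConfigurationError("exactly one of generator / input_dir required")
        known = {v[0] for v in VARIANTS}
        if not set(self.variants) <= known:
            raise ConfigurationError(f"unknown variant(s): {set(self.variants) - known}")
        if not 0 < self.q < 1:
            raise ConfigurationError("q must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        if self.generator is not None:
            payload["generator"] = self.generator.to_dict()
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """All result tables of one run plus provenance."""

    global_table: pd.DataFrame
    nodal_tables: dict[str, pd.DataFrame]
    seedfc_table: pd.DataFrame
    robustness_table: pd.DataFrame
    correlation_table: pd.DataFrame
    regression_tables: dict[str, pd.DataFrame]
    provenance: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.global_table.to_csv(out / "global_comparison.csv", index=False)
        for metric, table in self.nodal_tables.items():
            table.to_csv(out / f"nodal_comparison_{metric}.csv", index=False)
        self.seedfc_table.to_csv(out / "seed_fc_contrast.csv", index=False)
        self.robustness_table.to_csv(out / "robustness.csv", index=False)
        self.correlation_table.to_csv(out / "correlations.csv", index=False)
        for dv, table in self.regression_tables.items():
            table.to_csv(out / f"regression_{dv}.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))
        return out


# ---------------------------------------------------------------------------
# stages


def load_records(config: RunConfig) -> tuple[list[PairedSubjectRecord], list[str]]:
    if config.generator is not None:
        records = generate_paired_dataset(config.generator)
        labels = default_labels(config.generator.n_regions)
    else:
        records, gen = read_dataset(config.input_dir)
        n_regions = records[0].ts_A.shape[1]
        labels = default_labels(n_regions) if gen is None else default_labels(gen.n_regions)
    return records, labels


def connectivity_stage(
    records: Sequence[PairedSubjectRecord], labels: Sequence[str], tr: float = 2.0
) -> dict[str, list[np.ndarray]]:
    """Fisher-z matrices per condition, subject order preserved."""
    z = {"A": [], "B": []}
    for rec in records:
        for cond, ts in (("A", rec.ts_A), ("B", rec.ts_B)):
            cm = connectivity_from_timeseries(
                ROITimeSeries(values=ts, region_labels=list(labels), tr=tr)
            )
            z[cond].append(cm.z)
    return z


def metrics_stage(
    z_by_cond: dict[str, list[np.ndarray]],
    grid: SparsityGrid,
    mode: str,
    n_rand: int,
    seed: int,
    global_metrics: Sequence[str],
    nodal_metrics: Sequence[str],
    threads: int = 1,
) -> dict[str, list[SubjectMetrics]]:
    """Per-subject metric sweeps; each subject-condition gets a stable
    seed stream so results are independent of execution order."""

    def one(cond_idx: int, subj_idx: int, z: np.ndarray) -> SubjectMetrics:
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(cond_idx, subj_idx))
        )
        return compute_subject_metrics(
            z, grid=grid, mode=mode, n_rand=n_rand, seed=rng,
            global_metrics=global_metrics, nodal_metrics=nodal_metrics,
        )

    tasks = [
        (ci, si, z)
        for ci, cond in enumerate(("A", "B"))
        for si, z in enumerate(z_by_cond[cond])
    ]
    if threads > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=threads, backend="threading")(
            delayed(one)(*t) for t in tasks
        )
    else:
        results = [one(*t) for t in tasks]
    out: dict[str, list[SubjectMetrics]] = {"A": [], "B": []}
    for (ci, _, _), sm in zip(tasks, results):
        out["A" if ci == 0 else "B"].append(sm)
    return out


def metrics_long_table(
    metrics: dict[str, list[SubjectMetrics]],
    records: Sequence[PairedSubjectRecord],
    labels: Sequence[str],
    mode: str,
) -> pd.DataFrame:
    """Long-format table: (subject_id, condition, mode, metric,
    region_or_global, sparsity_or_AUC, value)."""
    rows = []
    for cond in ("A", "B"):
        for rec, sm in zip(records, metrics[cond]):
            for name, curve in sm.global_curves.items():
                for s, v in zip(curve.sparsities, curve.values):
                    rows.append((rec.subject_id, cond, mode, name, "global", s, v))
                rows.append((rec.subject_id, cond, mode, name, "global", "AUC", curve.auc))
            for name, curve in sm.nodal_curves.items():
                auc = np.asarray(curve.auc)
                for r, label in enumerate(labels):
                    rows.append((rec.subject_id, cond, mode, name, label, "AUC", auc[r]))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "condition", "mode", "metric",
                 "region_or_global", "sparsity_or_AUC", "value"],
    )


def _global_auc_matrix(
    metrics: dict[str, list[SubjectMetrics]], name: str
) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([sm.global_auc(name) for sm in metrics["A"]])
    b = np.array([sm.global_auc(name) for sm in metrics["B"]])
    return a, b


def _nodal_auc_matrix(
    metrics: dict[str, list[SubjectMetrics]], name: str
) -> tuple[np.ndarray, np.ndarray]:
    a = np.column_stack([sm.nodal_auc(name) for sm in metrics["A"]])  # regions x subj
    b = np.column_stack([sm.nodal_auc(name) for sm in metrics["B"]])
    return a, b


def global_comparison(
    metrics: dict[str, list[SubjectMetrics]], alpha: float = 0.05
) -> pd.DataFrame:
    """Between-condition comparison of global metric AUCs (uncorrected,
    flagged exploratory, mirroring the global-metric reporting convention)."""
    names = list(metrics["A"][0].global_curves)
    samples = {}
    for name in names:
        a, b = _global_auc_matrix(metrics, name)
        samples[name] = PairedSample(x_A=a, x_B=b)
    return paired_table(samples, alpha=alpha, q=None)


def nodal_comparison(
    metrics: dict[str, list[SubjectMetrics]],
    labels: Sequence[str],
    alpha: float = 0.05,
    q: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-node comparisons of nodal-metric AUCs, BH-FDR within each metric."""
    out = {}
    for name in metrics["A"][0].nodal_curves:
        a, b = _nodal_auc_matrix(metrics, name)
        samples = {
            f"{r + 1}:{labels[r]}": PairedSample(x_A=a[r], x_B=b[r])
            for r in range(a.shape[0])
        }
        table = paired_table(samples, alpha=alpha, q=q)
        table.insert(0, "region", np.arange(1, a.shape[0] + 1))
        table.insert(1, "label", list(labels))
        out[name] = table.drop(columns=["outcome"])
    return out


def behavior_analyses(
    records: Sequence[PairedSubjectRecord],
    metrics: dict[str, list[SubjectMetrics]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Behavior comparison, brain-behavior/age Spearman table, regressions.

    Correlations pair each behavior change score (and age) with each global
    metric's condition-B level and B-A change; regressions mirror the
    validation models: change scores on the condition-B clustering AUC with
    age and sex as covariates, and the Lp change on age and sex.
    """
    score_diff = {
        t: np.array([rec.scores_B[t] - rec.scores_A[t] for rec in records])
        for t in BEHAVIOR_TESTS if all(t in rec.scores_A for rec in records)
    }
    behav_samples = {
        t: PairedSample(
            x_A=np.array([rec.scores_A[t] for rec in records]),
            x_B=np.array([rec.scores_B[t] for rec in records]),
        )
        for t in score_diff
    }
    behavior_table = paired_table(behav_samples, alpha=alpha, q=None)

    age = np.array([rec.age for rec in records])
    sex = np.array([1.0 if rec.sex == "M" else 0.0 for rec in records])

    pairs = []
    for name in metrics["A"][0].global_curves:
        a, b = _global_auc_matrix(metrics, name)
        for attr, vals in ((f"{name} (B)", b), (f"{name} (RW)", a), (f"{name} (B-A)", b - a)):
            pairs.append((attr, "age", vals, age))
            for t, ds in score_diff.items():
                pairs.append((attr, f"delta_{t}", vals, ds))
    correlation_table = spearman_table(pairs)

    regressions = {}

    def fit(name: str, y: np.ndarray, X: pd.DataFrame) -> None:
        if len(y) <= X.shape[1] + 1 or np.linalg.matrix_rank(
            np.column_stack([np.ones(len(y)), X])
        ) < X.shape[1] + 1:
            logger.warning("skipping regression %s: unidentifiable design", name)
            return
        regressions[name] = linear_regression(y, X)

    if "Cp" in metrics["A"][0].global_curves:
        _, cp_b = _global_auc_matrix(metrics, "Cp")
        for t in ("SDT", "NCT-A"):
            if t in score_diff:
                fit(f"delta_{t}", score_diff[t],
                    pd.DataFrame({"aCp": cp_b, "age": age, "sex": sex}))
    if "Lp" in metrics["A"][0].global_curves:
        lp_a, lp_b = _global_auc_matrix(metrics, "Lp")
        fit("delta_Lp", lp_b - lp_a, pd.DataFrame({"age": age, "sex": sex}))
    return behavior_table, correlation_table, regressions


def robustness_summary(
    per_variant: dict[str, dict[str, list[SubjectMetrics]]],
    hub: int,
    degraded: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Key findings across network-construction variants (three-column
    layout: original binary / extended binary / weighted)."""
    rows = {}
    for variant, metrics in per_variant.items():
        cells = {}
        if "Cp" in metrics["A"][0].global_curves:
            a, b = _global_auc_matrix(metrics, "Cp")
            res = compare_paired(PairedSample(a, b), alpha=alpha)
            cells["Cp"] = res
        for metric, node, label in (
            ("degree", hub, f"degree@node{hub}"),
            ("nodal_efficiency", degraded, f"nodal_efficiency@node{degraded}"),
            ("nodal_efficiency", hub, f"nodal_efficiency@node{hub}"),
        ):
            if metric in metrics["A"][0].nodal_curves:
                a, b = _nodal_auc_matrix(metrics, metric)
                if not 1 <= node <= a.shape[0]:
                    continue
                res = compare_paired(PairedSample(a[node - 1], b[node - 1]), alpha=alpha)
                cells[label] = res
        for outcome, res in cells.items():
            rows.setdefault(outcome, {})[f"{variant}_statistic"] = res.statistic
            rows.setdefault(outcome, {})[f"{variant}_p"] = res.p_raw
    table = pd.DataFrame(rows).T.reset_index(names="outcome")
    return table


# ---------------------------------------------------------------------------
# orchestration


def run_full(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the primary analysis and all configured robustness variants."""
    config.validate()
    t0 = time.time()
    records, labels = load_records(config)
    tr = config.generator.tr if config.generator is not None else 2.0
    logger.info("run %s: %d subjects loaded", config.config_hash(), len(records))

    z_by_cond = connectivity_stage(records, labels, tr=tr)
    logger.info("connectivity stage done (%.1fs)", time.time() - t0)

    grids = {"primary": config.primary_grid, "extended": config.extended_grid}
    per_variant: dict[str, dict[str, list[SubjectMetrics]]] = {}
    for variant, grid_role, mode in VARIANTS:
        if variant not in config.variants:
            continue
        per_variant[variant] = metrics_stage(
            z_by_cond, grids[grid_role], mode, config.n_rand,
            seed=config.seed, global_metrics=config.global_metrics,
            nodal_metrics=config.nodal_metrics, threads=config.threads,
        )
        logger.info("metrics stage %s done (%.1fs)", variant, time.time() - t0)

    primary = per_variant[config.variants[0]]
    global_table = global_comparison(primary, alpha=config.alpha)
    nodal_tables = nodal_comparison(primary, labels, alpha=config.alpha, q=config.q)
    seedfc_table = seed_fc_contrast(
        z_by_cond["A"], z_by_cond["B"], labels,
        seed_region=config.seed_region, alpha=config.alpha, q=config.q,
    )
    robustness_table = robustness_summary(
        per_variant, hub=config.seed_region, degraded=config.degraded_region,
        alpha=config.alpha,
    )
    behavior_table, correlation_table, regression_tables = behavior_analyses(
        records, primary, alpha=config.alpha
    )
    global_table = pd.concat(
        [global_table, behavior_table.assign(family="behavior")],
        ignore_index=True,
    )

    report = RunReport(
        global_table=global_table,
        nodal_tables=nodal_tables,
        seedfc_table=seedfc_table,
        robustness_table=robustness_table,
        correlation_table=correlation_table,
        regression_tables=regression_tables,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "software_version": __version__,
            "n_subjects": len(records),
            "variants": list(per_variant),
        },
    )
    if out_dir is not None:
        report.write(out_dir)
        logger.info("report written to %s (%.1fs total)", out_dir, time.time() - t0)
    return report


# ---------------------------------------------------------------------------
# validation harnesses


def _replicate_cp_degree(
    gen: GeneratorConfig, grid: SparsityGrid, alpha: float, q: float
) -> dict:
    """One replicate of the reduced pipeline: Cp AUC comparison plus the
    per-node degree-AUC p-value ranking (no null-model metrics)."""
    records = generate_paired_dataset(gen)
    labels = default_labels(gen.n_regions)
    z = connectivity_stage(records, labels, tr=gen.tr)
    metrics = metrics_stage(
        z, grid, "binary", n_rand=0, seed=gen.seed,
        global_metrics=("Cp",), nodal_metrics=("degree",),
    )
    a, b = _global_auc_matrix(metrics, "Cp")
    cp_res = compare_paired(PairedSample(a, b), alpha=alpha)
    da, db = _nodal_auc_matrix(metrics, "degree")
    p_nodes = np.array(
        [compare_paired(PairedSample(da[r], db[r]), alpha=alpha).p_raw
         for r in range(da.shape[0])]
    )
    _, signif = bh_fdr(p_nodes, q=q)
    return {
        "cp_p": cp_res.p_raw,
        "cp_direction": cp_res.direction,
        "node_p": p_nodes,
        "best_node": int(np.argmin(p_nodes)) + 1,
        "n_fdr_significant_nodes": int(signif.sum()),
    }


def run_null_calibration(
    config: RunConfig,
    n_replicates: int = 200,
    nominal: float = 0.05,
) -> dict:
    """Empirical type-I error of the Cp-AUC comparison and the nodal-degree
    FDR layer under the zero-effect generator.

    Each replicate regenerates a dataset with all effect deltas zero and a
    fresh seed, runs the reduced pipeline, and records whether the global
    comparison rejects and how many nodes survive FDR.
    """
    config.validate()
    if config.generator is None:
        raise ConfigurationError("null calibration needs a generator config")
    if config.generator.n_subjects < 1:
        raise ConfigurationError("zero subjects: nothing to calibrate")
    precision_warning = n_replicates < 50
    base = dataclasses.replace(config.generator, effect=config.generator.effect.null())
    rejections = 0
    any_fdr_hits = 0
    for rep in range(n_replicates):
        gen = dataclasses.replace(base, seed=int(np.random.SeedSequence(
            config.seed, spawn_key=(4, rep)).generate_state(1)[0] % (2**31)))
        out = _replicate_cp_degree(gen, config.primary_grid, config.alpha, config.q)
        rejections += out["cp_p"] < nominal
        any_fdr_hits += out["n_fdr_significant_nodes"] > 0
    rate = rejections / n_replicates
    se = np.sqrt(nominal * (1 - nominal) / n_replicates)
    return {
        "n_replicates": n_replicates,
        "cp_rejection_rate": rate,
        "cp_rate_mc_ci": (max(rate - 1.96 * se, 0.0), rate + 1.96 * se),
        "nodal_fdr_familywise_rate": any_fdr_hits / n_replicates,
        "precision_warning": precision_warning,
    }


def run_effect_recovery(
    config: RunConfig,
    n_replicates: int = 50,
) -> dict:
    """Fraction of replicates in which the implanted effects are recovered:
    the Cp increase flagged (p < alpha, direction B > A) and the hub node
    ranked first among all nodes by degree-centrality p-value."""
    config.validate()
    if config.generator is None:
        raise ConfigurationError("effect recovery needs a generator config")
    cp_flagged = 0
    hub_first = 0
    for rep in range(n_replicates):
        gen = dataclasses.replace(config.generator, seed=int(np.random.SeedSequence(
            config.seed, spawn_key=(5, rep)).generate_state(1)[0] % (2**31)))
        out = _replicate_cp_degree(gen, config.primary_grid, config.alpha, config.q)
        cp_flagged += (out["cp_p"] < config.alpha) and (out["cp_direction"] > 0)
        hub_first += out["best_node"] == config.seed_region
    return {
        "n_replicates": n_replicates,
        "cp_flag_rate": cp_flagged / n_replicates,
        "hub_rank1_rate": hub_first / n_replicates,
    }
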