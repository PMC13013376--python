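"""Synthetic paired-condition ROI time-series generator.

Emulates a within-subject two-condition resting-state study: each subject
contributes two band-limited multivariate Gaussian time series (volumes x
regions) drawn from modular block covariances, so that Pearson functional
connectivity recovers a small-world-like community structure after
proportional thresholding. Condition B carries implanted topological effects
(a global within-module correlation increment driving the clustering
coefficient; a hub node whose connectivity rises; a degraded node whose
connectivity falls) and behavioral scores are linearly coupled to a
network-metric surrogate, mirroring the paired design the downstream
statistics assume.

All randomness derives from one master seed through ``numpy``
``SeedSequence`` streams keyed by subject index and condition, so adding
subjects never perturbs earlier subjects' draws and identical configurations
reproduce datasets bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import FUSIFORM_L, SFGMED_R, default_labels
from .errors import ConfigurationError

Condition = Literal["A", "B"]

#: Fixed set of neuropsychological tests. DST scores higher = better; the
#: three timed tests (NCT-A, LTT, SDT) score lower = better.
BEHAVIOR_TESTS = ("DST", "NCT-A", "LTT", "SDT")

_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class EffectSpec:
    """Implanted condition-B effects on the target correlation structure.

    ``clustering_delta`` raises every within-module correlation (drives the
    global clustering coefficient up). ``hub_delta`` raises all correlations
    of ``hub_node`` (drives its degree centrality up); ``degraded_delta``
    lowers all correlations of ``degraded_node`` (drives its nodal
    efficiency down). Node indices are 1-based atlas order.
    """

    clustering_delta: float = 0.10
    hub_node: int = SFGMED_R
    hub_delta: float = 0.15
    degraded_node: int = FUSIFORM_L
    degraded_delta: float = 0.10

    def null(self) -> "EffectSpec":
        """Copy with every delta zeroed (null-hypothesis generator)."""
        return dataclasses.replace(
            self, clustering_delta=0.0, hub_delta=0.0, degraded_delta=0.0
        )


@dataclass(frozen=True)
class BehaviorTestSpec:
    """One test's generative parameters.

    ``score = baseline_mean + condition_shift*[B] + coupling*(metric - mean metric) + noise``
    """

    baseline_mean: float
    baseline_sd: float
    condition_shift: float
    coupling: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


def default_behavior_spec() -> dict[str, BehaviorTestSpec]:
    """Defaults emulating the rested-wakefulness baselines and condition
    shifts of the study design (DST falls under deprivation; the timed tests
    slow down), with couplings sized to yield moderate metric-behavior
    correlations at n = 36."""
    return {
        "DST": BehaviorTestSpec(69.58, 9.43, -4.77, -20.0, 6.6),
        "NCT-A": BehaviorTestSpec(29.28, 9.56, +2.58, +25.0, 6.7),
        "LTT": BehaviorTestSpec(49.06, 17.32, +5.63, +40.0, 12.0),
        "SDT": BehaviorTestSpec(41.33, 9.89, +1.11, +30.0, 7.0),
    }


def contiguous_partition(n_regions: int, n_modules: int) -> np.ndarray:
    """Assign regions to ``n_modules`` contiguous, near-equal modules."""
    if not 1 <= n_modules <= n_regions:
        raise ConfigurationError("need 1 <= n_modules <= n_regions")
    chunks = np.array_split(np.arange(n_regions), n_modules)
    return np.concatenate([np.full(len(c), m) for m, c in enumerate(chunks)])


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic paired dataset.

    Defaults reproduce the study conditions this package emulates: 36 paired
    subjects, 90 AAL regions, 230 retained volumes at TR = 2 s band-limited
    to 0.01-0.08 Hz, six modules of fifteen regions with within/between
    target correlations 0.30/0.05, subject-level jitter of the correlation
    levels on the Fisher-z scale, and condition-B effects per ``EffectSpec``.
    """

    n_subjects: int = 36
    n_regions: int = 90
    n_volumes: int = 230
    tr: float = 2.0
    band: tuple[float, float] = (0.01, 0.08)
    partition: tuple[int, ...] | None = None  # module label per region
    n_modules: int = 6
    within_r: float = 0.30
    between_r: float = 0.05
    subject_jitter_sd: float = 0.10
    effect: EffectSpec = field(default_factory=EffectSpec)
    behavior: Mapping[str, BehaviorTestSpec] = field(
        default_factory=default_behavior_spec
    )
    seed: int = 0

    def module_labels(self) -> np.ndarray:
        if self.partition is not None:
            return np.asarray(self.partition, dtype=int)
        return contiguous_partition(self.n_regions, self.n_modules)

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ConfigurationError("need at least 2 regions")
        if self.n_subjects < 1:
            raise ConfigurationError("need at least 1 subject")
        f_lo, f_hi = self.band
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0 <= f_lo < f_hi <= nyquist + 1e-12):
            raise ConfigurationError(
                f"band must satisfy 0 <= f_lo < f_hi <= Nyquist ({nyquist} Hz)"
            )
        if not (abs(self.between_r) < self.within_r < 1):
            raise ConfigurationError("need |between_r| < within_r < 1")
        labels = self.module_labels()
        if labels.shape != (self.n_regions,):
            raise ConfigurationError("partition must assign every region exactly once")
        for node in (self.effect.hub_node, self.effect.degraded_node):
            if not 1 <= node <= self.n_regions:
                raise ConfigurationError(f"effect node {node} outside 1..{self.n_regions}")
        unknown = set(self.behavior) - set(BEHAVIOR_TESTS)
        if unknown:
            raise ConfigurationError(f"unknown behavior test name(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect"] = dataclasses.asdict(self.effect)
        d["behavior"] = {k: dataclasses.asdict(v) for k, v in self.behavior.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "effect" in d and isinstance(d["effect"], Mapping):
            d["effect"] = EffectSpec(**d["effect"])
        if "behavior" in d and isinstance(d["behavior"], Mapping):
            d["behavior"] = {
                k: (v if isinstance(v, BehaviorTestSpec) else BehaviorTestSpec(**v))
                for k, v in d["behavior"].items()
            }
        if d.get("band") is not None:
            d["band"] = tuple(d["band"])
        if d.get("partition") is not None:
            d["partition"] = tuple(d["partition"])
        return cls(**d)


@dataclass
class PairedSubjectRecord:
    """One subject's two-condition time series, behavior, and covariates."""

    subject_id: str
    age: float
    sex: str  # "M" or "F"
    ts_A: np.ndarray  # volumes x regions
    ts_B: np.ndarray
    scores_A: dict[str, float]
    scores_B: dict[str, float]

    def __post_init__(self) -> None:
        if self.ts_A.shape != self.ts_B.shape:
            raise ConfigurationError("ts_A and ts_B must share a shape")


# ---------------------------------------------------------------------------
# covariance construction


def _subject_jitter(config: GeneratorConfig, subject_seed: int) -> tuple[float, float]:
    """Gaussian jitter of the two target correlation levels, Fisher-z scale.

    Keyed only by (master seed, subject) so both conditions share it: the
    paired design's between-subject variance cancels in within-subject
    differences.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, int(subject_seed)))
    )
    eps = rng.normal(0.0, config.subject_jitter_sd, size=2)
    return float(eps[0]), float(eps[1])


def make_block_covariance(
    config: GeneratorConfig,
    condition: Condition,
    subject_seed: int,
    *,
    repair: bool = True,
) -> np.ndarray:
    """Target correlation matrix for one subject and condition.

    Within-module entries sit near ``within_r`` (plus ``clustering_delta``
    in condition B), between-module entries near ``between_r``; condition B
    additionally raises the hub node's row/column by ``hub_delta`` and
    lowers the degraded node's by ``degraded_delta``. Jitter is shared
    across conditions. With ``repair`` the matrix is made positive definite
    by eigenvalue clipping and rescaled to unit diagonal.
    """
    config.validate()
    if condition not in ("A", "B"):
        raise ConfigurationError(f"condition must be 'A' or 'B', got {condition!r}")

    labels = config.module_labels()
    eps_w, eps_b = _subject_jitter(config, subject_seed)

    within = config.within_r
    if condition == "B":
        within = within + config.effect.clustering_delta
    r_within = np.tanh(np.arctanh(np.clip(within, -0.999, 0.999)) + eps_w)
    r_between = np.tanh(np.arctanh(np.clip(config.between_r, -0.999, 0.999)) + eps_b)

    same_module = labels[:, None] == labels[None, :]
    cov = np.where(same_module, r_within, r_between)

    if condition == "B":
        hub = config.effect.hub_node - 1
        bad = config.effect.degraded_node - 1
        cov[hub, :] += config.effect.hub_delta
        cov[:, hub] += config.effect.hub_delta
        cov[bad, :] -= config.effect.degraded_delta
        cov[:, bad] -= config.effect.degraded_delta

    np.clip(cov, -0.99, 0.99, out=cov)
    np.fill_diagonal(cov, 1.0)
    cov = (cov + cov.T) / 2.0

    if repair:
        cov = nearest_pd_correlation(cov)
    return cov


def nearest_pd_correlation(mat: np.ndarray, eig_floor: float = _EIG_FLOOR) -> np.ndarray:
    """Clip eigenvalues below ``eig_floor`` and rescale to unit diagonal.

    Minimal deterministic repair; raises if the result still fails a strict
    positive-definiteness check.
    """
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() < eig_floor:
        vals = np.maximum(vals, eig_floor)
        mat = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
        mat = (mat + mat.T) / 2.0
        np.fill_diagonal(mat, 1.0)
    if np.linalg.eigvalsh(mat).min() <= 1e-10:
        raise ConfigurationError("covariance not positive definite after repair")
    return mat


# ---------------------------------------------------------------------------
# band-limited sampling


def bandpass_filter(
    ts: np.ndarray, tr: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Ideal (frequency-mask) band-pass along axis 0.

    Retains rFFT components with ``f_lo <= f <= f_hi`` and zeroes the rest,
    so the operation is exactly idempotent and removes the DC component
    whenever ``f_lo > 0``.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[0]
    if n < 3:
        raise ConfigurationError("need at least 3 time points to filter")
    nyquist = 1.0 / (2.0 * tr)
    if not (0 <= f_lo < f_hi):
        raise ConfigurationError("need 0 <= f_lo < f_hi")
    if f_hi > nyquist + 1e-12:
        raise ConfigurationError(f"f_hi {f_hi} exceeds Nyquist {nyquist}")
    freqs = np.fft.rfftfreq(n, d=tr)
    mask = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    spec = np.fft.rfft(ts, axis=0)
    spec[~mask] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def sample_bandlimited_timeseries(
    cov: np.ndarray,
    n_volumes: int,
    tr: float,
    band: tuple[float, float],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """White Gaussian series with spatial covariance ``cov``, band-passed.

    The ideal mask preserves the cross-regional correlation structure of
    the white input in expectation while confining spectral content to the
    pass-band, emulating low-frequency BOLD fluctuations.
    """
    cov = np.asarray(cov, dtype=float)
    f_lo, f_hi = band
    if n_volumes <= 2.0 / ((f_hi - f_lo) * tr):
        raise ConfigurationError("n_volumes too small for a non-empty pass-band")
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    if not np.any((freqs >= f_lo) & (freqs <= f_hi)):
        raise ConfigurationError("pass-band contains no frequency bin")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    white = rng.standard_normal((n_volumes, cov.shape[0]))
    ts = white @ chol.T
    return bandpass_filter(ts, tr, f_lo, f_hi)


# ---------------------------------------------------------------------------
# dataset assembly


def _proxy_metric(config: GeneratorConfig, subject_seed: int, condition: Condition) -> float:
    """Mean within-module off-diagonal target correlation for a subject.

    Cheap, noiseless surrogate for the subject's clustering level: it moves
    one-to-one with the jittered within-module correlation that drives the
    measured clustering coefficient.
    """
    cov = make_block_covariance(config, condition, subject_seed, repair=False)
    labels = config.module_labels()
    same = labels[:, None] == labels[None, :]
    off = same & ~np.eye(config.n_regions, dtype=bool)
    return float(cov[off].mean())


def generate_behavior(
    records: Sequence[PairedSubjectRecord],
    metric_values: np.ndarray,
    spec: Mapping[str, BehaviorTestSpec],
    seed: int,
) -> list[PairedSubjectRecord]:
    """Fill behavior scores coupled to a per-subject, per-condition metric.

    ``metric_values`` is ``(n_subjects, 2)`` with columns for conditions A
    and B. Scores follow
    ``baseline + shift*[B] + coupling*(metric - grand mean) + noise``; the
    noise stream is keyed by (seed, subject index) so datasets regenerate
    deterministically.
    """
    unknown = set(spec) - set(BEHAVIOR_TESTS)
    if unknown:
        raise ConfigurationError(f"unknown behavior test name(s): {sorted(unknown)}")
    metric_values = np.asarray(metric_values, dtype=float)
    if metric_values.shape != (len(records), 2):
        raise ConfigurationError("need one metric value per subject per condition")
    center = metric_values.mean()

    out = []
    for i, rec in enumerate(records):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, i)))
        scores_A, scores_B = {}, {}
        for test in BEHAVIOR_TESTS:
            if test not in spec:
                continue
            ts = spec[test]
            noise = rng.normal(0.0, ts.noise_sd, size=2)
            scores_A[test] = (
                ts.baseline_mean
                + ts.coupling * (metric_values[i, 0] - center)
                + noise[0]
            )
            scores_B[test] = (
                ts.baseline_mean
                + ts.condition_shift
                + ts.coupling * (metric_values[i, 1] - center)
                + noise[1]
            )
        out.append(dataclasses.replace(rec, scores_A=scores_A, scores_B=scores_B))
    return out


def generate_paired_dataset(config: GeneratorConfig) -> list[PairedSubjectRecord]:
    """Generate the full paired cohort.

    Ages are normal(32, 4.3) truncated to [26, 42]; sex is Bernoulli with
    the emulated cohort's male fraction (21/36). Both are keyed per subject
    so the cohort is stable under extension. Behavior scores couple to the
    pre-noise within-module correlation surrogate (see ``_proxy_metric``).
    """
    config.validate()
    records: list[PairedSubjectRecord] = []
    proxy = np.empty((config.n_subjects, 2))
    for s in range(config.n_subjects):
        demo_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(0, s))
        )
        age = float(demo_rng.normal(32.0, 4.3))
        while not 26.0 <= age <= 42.0:
            age = float(demo_rng.normal(32.0, 4.3))
        sex = "M" if demo_rng.random() < 21.0 / 36.0 else "F"

        ts = {}
        for c_idx, cond in enumerate(("A", "B")):
            cov = make_block_covariance(config, cond, s)
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(3, s, c_idx))
            )
            ts[cond] = sample_bandlimited_timeseries(
                cov, config.n_volumes, config.tr, config.band, rng
            )
            proxy[s, c_idx] = _proxy_metric(config, s, cond)

        records.append(
            PairedSubjectRecord(
                subject_id=f"sub-{s + 1:03d}",
                age=age,
                sex=sex,
                ts_A=ts["A"],
                ts_B=ts["B"],
                scores_A={},
                scores_B={},
            )
        )
    return generate_behavior(records, proxy, config.behavior, config.seed)


# ---------------------------------------------------------------------------
# dataset I/O (TSV time series + CSV behavior + JSON manifest)


def write_dataset(
    records: Iterable[PairedSubjectRecord],
    config: GeneratorConfig,
    out_dir: str | Path,
) -> Path:
    """Write one directory per dataset: per-subject TSVs, behavior CSV, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = default_labels(config.n_regions)
    behavior_rows = []
    for rec in records:
        for cond, ts, scores in (
            ("A", rec.ts_A, rec.scores_A),
            ("B", rec.ts_B, rec.scores_B),
        ):
            df = pd.DataFrame(ts, columns=labels)
            df.to_csv(out_dir / f"{rec.subject_id}_cond-{cond}_ts.tsv", sep="\t", index=False)
            behavior_rows.append(
                {"subject_id": rec.subject_id, "age": rec.age, "sex": rec.sex,
                 "condition": cond, **{t: scores.get(t) for t in BEHAVIOR_TESTS}}
            )
    pd.DataFrame(behavior_rows).to_csv(out_dir / "behavior.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps({"generator_config": config.to_dict()}, indent=2)
    )
    return out_dir


def read_dataset(in_dir: str | Path) -> tuple[list[PairedSubjectRecord], GeneratorConfig | None]:
    """Read a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    behavior = pd.read_csv(in_dir / "behavior.csv")
    config = None
    manifest = in_dir / "manifest.json"
    if manifest.exists():
        config = GeneratorConfig.from_dict(
            json.loads(manifest.read_text())["generator_config"]
        )
    records = []
    for subject_id, grp in behavior.groupby("subject_id", sort=True):
        row_by_cond = {r["condition"]: r for _, r in grp.iterrows()}
        ts = {
            cond: pd.read_csv(
                in_dir / f"{subject_id}_cond-{cond}_ts.tsv", sep="\t"
            ).to_numpy()
            for cond in ("A", "B")
        }
        records.append(
            PairedSubjectRecord(
                subject_id=str(subject_id),
                age=float(row_by_cond["A"]["age"]),
                sex=str(row_by_cond["A"]["sex"]),
                ts_A=ts["A"],
                ts_B=ts["B"],
                scores_A={t: float(row_by_cond["A"][t]) for t in BEHAVIOR_TESTS
                          if t in row_by_cond["A"]},
                scores_B={t: float(row_by_cond["B"][t]) for t in BEHAVIOR_TESTS
                          if t in row_by_cond["B"]},
            )
        )
    return records, config
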