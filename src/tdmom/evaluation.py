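"""Metrics, statistical comparisons and the end-to-end benchmark.

Recovered HRFs are scored against ground truth with RMSE and the Fisher
transform of the Pearson correlation; methods are compared with paired
Student t-tests across channels.  :func:`run_benchmark` ties simulation,
recovery and evaluation into a deterministic ensemble run: independent seed
groups ("subjects") sharing generator parameters, each with its own probe
of SS/LS detector pairs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .moments import fisher_transform
from .recovery import METHODS, RecoveredHRF, run_method_suite
from .synth import CanonicalHRF, NoiseConfig, ProbeGeometry, simulate_session
from .transport import SensitivityTable

__all__ = [
    "EvaluationRecord",
    "ComparisonResult",
    "BenchmarkConfig",
    "clipped_fisher",
    "evaluate",
    "paired_compare",
    "percent_improvement",
    "run_benchmark",
    "records_to_frame",
]

#: |r| clip for the Fisher transform when a noise-free test hits exactly 1
FISHER_CLIP = 1.0 - 1e-12


@dataclass
class EvaluationRecord:
    """Score of one recovered chromophore curve against ground truth."""

    channel: int
    method: str
    chromophore: str  # "HbO" | "HbR"
    rmse: float  # uM
    fisher_z: float
    scale: float
    covariance_source: str = "none"
    group: int = 0
    clipped: bool = False
    excluded: bool = False


@dataclass
class ComparisonResult:
    """Paired t-test between two methods on matched channels."""

    method_a: str
    method_b: str
    metric: str
    mean_difference: float
    t_statistic: float
    p_value: float
    n_channels: int


def clipped_fisher(r: float) -> tuple[float, bool]:
    """Fisher z with |r| clipped at 1 - 1e-12; returns (z, was_clipped)."""
    r = float(r)
    if abs(r) >= FISHER_CLIP:
        return fisher_transform(np.sign(r) * FISHER_CLIP), True
    return fisher_transform(r), False


def _score_curve(recovered, truth, time_base):
    base = time_base <= 0.0
    rec = recovered - recovered[base].mean()
    tru = truth - truth[base].mean()
    rmse = float(np.sqrt(np.mean((rec - tru) ** 2)))
    if rec.std() == 0 or tru.std() == 0:
        return rmse, float("nan"), False, True
    r = float(np.corrcoef(rec, tru)[0, 1])
    z, clipped = clipped_fisher(r)
    return rmse, z, clipped, False


def evaluate(
    recovered: RecoveredHRF,
    truth: CanonicalHRF,
    channel: int = 0,
    group: int = 0,
) -> list[EvaluationRecord]:
    """Score a recovered HRF against the generating truth (HbO and HbR).

    Truth is resampled to the recovered time base and both curves are
    baseline-adjusted over [-2, 0] s.  A zero-variance recovered curve
    yields a record flagged ``excluded`` (undefined correlation).
    """
    tb = recovered.time_base
    t_hbo, t_hbr = truth.sample(tb)
    out = []
    for name, rec, tru in (
        ("HbO", recovered.hbo, t_hbo),
        ("HbR", recovered.hbr, t_hbr),
    ):
        rmse, z, clipped, excluded = _score_curve(
            np.asarray(rec, float), np.asarray(tru, float), tb
        )
        out.append(
            EvaluationRecord(
                channel=channel,
                method=recovered.method,
                chromophore=name,
                rmse=rmse,
                fisher_z=z,
                scale=truth.scale,
                covariance_source=recovered.covariance_source,
                group=group,
                clipped=clipped,
                excluded=excluded,
            )
        )
    return out


def paired_compare(
    a: list[EvaluationRecord],
    b: list[EvaluationRecord],
    metric: str = "fisher_z",
) -> ComparisonResult:
    """Two-sided paired Student t-test on per-channel metric differences.

    Records are matched on (group, channel, chromophore, scale); both arms
    must cover the same channels.  ``metric`` is "fisher_z" or "rmse".
    """
    if metric not in ("fisher_z", "rmse"):
        raise ValueError("metric must be 'fisher_z' or 'rmse'")

    def key(r):
        return (r.group, r.channel, r.chromophore, r.scale)

    da = {key(r): getattr(r, metric) for r in a if not r.excluded}
    db = {key(r): getattr(r, metric) for r in b if not r.excluded}
    common = sorted(set(da) & set(db))
    if len(common) != len(da) or len(common) != len(db):
        raise ValueError("paired design requires identical channel sets")
    if len(common) < 2:
        raise ValueError("need at least two matched channels for a paired t-test")
    xa = np.array([da[k] for k in common])
    xb = np.array([db[k] for k in common])
    diff = xa - xb
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            # identical arms: mean difference 0, the t statistic is undefined
            return ComparisonResult(
                method_a=a[0].method,
                method_b=b[0].method,
                metric=metric,
                mean_difference=0.0,
                t_statistic=float("nan"),
                p_value=float("nan"),
                n_channels=len(common),
            )
        raise ValueError(
            "degenerate paired t-test: zero-variance differences "
            f"(constant offset {diff[0]:.3g})"
        )
    t, p = stats.ttest_rel(xa, xb)
    return ComparisonResult(
        method_a=a[0].method,
        method_b=b[0].method,
        metric=metric,
        mean_difference=float(diff.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_channels=len(common),
    )


def percent_improvement(a: float, b: float, kind: str = "correlation") -> float:
    """Percent improvement of mean metric ``a`` over reference ``b``.

    Correlation-type metrics report ``100*(a - b)/|b|`` (higher is better);
    RMSE-type metrics report the decrease ``100*(b - a)/|b|``.
    """
    if b == 0:
        raise ValueError("reference metric is zero; percent change undefined")
    if kind == "correlation":
        return 100.0 * (a - b) / abs(b)
    if kind == "rmse":
        return 100.0 * (b - a) / abs(b)
    raise ValueError("kind must be 'correlation' or 'rmse'")


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


@dataclass
class BenchmarkConfig:
    """Deterministic ensemble benchmark configuration.

    ``n_groups`` independent seed groups ("subjects") share all generator
    parameters; each group gets its own probe of ``n_detectors`` SS/LS
    pairs, its own physiology realization and its own stimulus trains.
    """

    n_groups: int = 6
    n_detectors: int = 20
    duration: float = 300.0
    sample_rate: float = 7.0
    scales: tuple = (1.0,)
    methods: tuple = METHODS
    covariance_sources: tuple = ("ZE",)
    base_seed: int = 2024
    scalp_thickness: float = 13.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def group_seed(self, group: int, scale_index: int) -> int:
        return int(self.base_seed + 1000 * scale_index + group)


def run_benchmark(
    table: SensitivityTable,
    config: BenchmarkConfig | None = None,
    log=None,
) -> dict:
    """Simulate, recover and score the full ensemble.

    Returns a report dict with the flat evaluation records, per
    (scale, covariance, method, chromophore) summary rows (mean RMSE, mean
    Fisher z, n), headline paired comparisons (plain p-values plus a
    Bonferroni-adjusted column, the adjustment being an extension to the
    plain-t convention), the method ranking by mean HbO Fisher z, and the
    full configuration for regeneration.  Deterministic given the config.
    """
    config = config or BenchmarkConfig()
    log = log or (lambda msg: None)
    geometry = ProbeGeometry(n_detectors=config.n_detectors)
    records: list[EvaluationRecord] = []
    failures: list[dict] = []
    t_start = time.time()
    for si, scale in enumerate(config.scales):
        for group in range(config.n_groups):
            seed = config.group_seed(group, si)
            t0 = time.time()
            session = simulate_session(
                table,
                geometry,
                duration=config.duration,
                sample_rate=config.sample_rate,
                scale=scale,
                noise_config=config.noise,
                seed=seed,
                scalp_thickness=config.scalp_thickness,
            )
            log(
                f"scale {scale} group {group}: simulated seed {seed} "
                f"in {time.time() - t0:.1f}s"
            )
            cov_dependent = {"TD-SS", "TD-LS", "TD-LS+SS", "TD-GLM"}
            for ci, cov in enumerate(config.covariance_sources):
                # CW methods ignore the moment covariance; run them once
                methods = (
                    config.methods
                    if ci == 0
                    else tuple(m for m in config.methods if m in cov_dependent)
                )
                if not methods:
                    continue
                t0 = time.time()
                results = run_method_suite(
                    session, table, methods=methods, covariance_source=cov
                )
                for res in results:
                    if res.error is not None:
                        failures.append(
                            {
                                "scale": scale,
                                "group": group,
                                "detector": res.detector,
                                "method": res.method,
                                "covariance": cov,
                                "error": res.error,
                            }
                        )
                        continue
                    records.extend(
                        evaluate(
                            res.hrf,
                            session.hrf,
                            channel=res.detector,
                            group=group,
                        )
                    )
                log(f"  {cov}: recovered+scored in {time.time() - t0:.1f}s")
    frame = records_to_frame(records)
    summary_rows = []
    if len(frame):
        grouped = frame[~frame["excluded"]].groupby(
            ["scale", "covariance_source", "method", "chromophore"]
        )
        for (scale, cov, method, chrom), g in grouped:
            summary_rows.append(
                {
                    "scale": scale,
                    "covariance": cov,
                    "method": method,
                    "chromophore": chrom,
                    "mean_rmse": float(g["rmse"].mean()),
                    "mean_fisher_z": float(g["fisher_z"].mean()),
                    "n": int(len(g)),
                }
            )
    comparisons = _headline_comparisons(records, config)
    ranking = sorted(
        (
            row
            for row in summary_rows
            if row["chromophore"] == "HbO"
        ),
        key=lambda row: -row["mean_fisher_z"],
    )
    report = {
        "config": _config_dict(config),
        "records": [asdict(r) for r in records],
        "summary": summary_rows,
        "comparisons": comparisons,
        "ranking_hbo": [
            {k: row[k] for k in ("scale", "covariance", "method", "mean_fisher_z")}
            for row in ranking
        ],
        "failures": failures,
        "wall_time_s": time.time() - t_start,
    }
    return report


def _config_dict(config: BenchmarkConfig) -> dict:
    d = asdict(config)
    d["scales"] = list(config.scales)
    d["methods"] = list(config.methods)
    d["covariance_sources"] = list(config.covariance_sources)
    return d


def _headline_comparisons(records: list[EvaluationRecord], config) -> list[dict]:
    """Paired comparisons between adjacent methods in the expected ranking."""
    pairs = [
        ("TD-GLM", "TD-LS+SS"),
        ("TD-LS+SS", "CW-GLM"),
        ("CW-GLM", "CW-BA"),
        ("TD-SS", "CW-SS"),
    ]
    by_key: dict[tuple, list[EvaluationRecord]] = {}
    for r in records:
        by_key.setdefault((r.method, r.chromophore, r.scale, r.covariance_source), []).append(r)
    out = []
    tests = []
    for scale in config.scales:
        for chrom in ("HbO", "HbR"):
            for ma, mb in pairs:
                for cov_a in {r.covariance_source for r in records if r.method == ma}:
                    a = by_key.get((ma, chrom, scale, cov_a))
                    if not a:
                        continue
                    cov_b_opts = {
                        r.covariance_source for r in records if r.method == mb
                    }
                    cov_b = cov_a if cov_a in cov_b_opts else next(iter(cov_b_opts), None)
                    b = by_key.get((mb, chrom, scale, cov_b))
                    if not b:
                        continue
                    for metric in ("fisher_z", "rmse"):
                        try:
                            cmp_res = paired_compare(a, b, metric)
                        except ValueError:
                            continue
                        tests.append((scale, chrom, cov_a, cmp_res))
    m = max(len(tests), 1)
    for scale, chrom, cov, cmp_res in tests:
        out.append(
            {
                "scale": scale,
                "chromophore": chrom,
                "covariance": cov,
                **asdict(cmp_res),
                # Bonferroni column is an extension beyond the plain
                # alpha=0.05 paired t convention
                "p_bonferroni": min(cmp_res.p_value * m, 1.0),
            }
        )
    return out


def save_report(report: dict, json_path, csv_path=None) -> None:
    """Write the JSON summary (and optionally the per-record CSV)."""
    slim = {k: v for k, v in report.items() if k != "records"}
    with open(json_path, "w") as f:
        json.dump(slim, f, indent=2, default=float)
    if csv_path is not None:
        pd.DataFrame(report["records"]).to_csv(csv_path, index=False)
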