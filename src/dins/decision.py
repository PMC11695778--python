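"""Rejection regions and the excessive-DINS flagging procedure.

The tolerable level of disagreement is stated as M, the acceptable
average relative increase in pointwise OLS prediction-interval widths.
Because the estimator obeys zeta-hat = (1+M)^2 * zeta-hat_0, the decision
threshold for a study design (n, R) is

    zeta_upper = (1+M)^2 * q99(zeta-hat_0 | n, R),

the scaled 99th percentile of the simulated no-DINS distribution.  A
comparison whose observed zeta-hat exceeds zeta_upper is flagged as
showing excessive DINS; by construction at most 1% of comparisons whose
true inflation is within M are flagged.

The flagging procedure runs: (1) screen replicate outliers per sample
with the studentized range test; (2-3) take the tolerance M and the
design (n, R) of the screened data; (4) obtain zeta_upper from a look-up
table or fresh simulation; (5) compute zeta-hat on raw or log scale,
whichever lands closer to 1; (6) flag iff zeta-hat > zeta_upper.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from functools import lru_cache
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    ComparisonData,
    DegenerateDesignError,
    DomainError,
    log_transform,
)
from .estimator import DinsEstimate, zeta_full
from .simulator import ScenarioConfig, simulate_zeta_distribution

__all__ = [
    "DecisionResult",
    "zeta_upper",
    "build_lookup_table",
    "lookup_zeta_upper",
    "screen_outliers",
    "select_transformation",
    "flag_excessive_dins",
]

DEFAULT_THRESHOLD_REPS = 200_000


@dataclass(frozen=True)
class DecisionResult:
    """Audit trail of one excessive-DINS decision."""

    zeta_hat: float
    zeta_upper: float
    M: float
    n: int
    R: int
    transformation: str  # "raw" or "log"
    excessive: bool
    outliers_removed: tuple
    zeta_raw: float | None = None
    zeta_log: float | None = None
    threshold_source: str = "simulation"
    estimate: DinsEstimate | None = None

    def __post_init__(self) -> None:
        if self.excessive != (self.zeta_hat > self.zeta_upper):
            raise DomainError("flag inconsistent with threshold comparison")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("estimate")
        d["outliers_removed"] = list(self.outliers_removed)
        return json.dumps(d, indent=2)


def zeta_upper(
    n: int,
    R: int,
    M: float,
    reps: int = DEFAULT_THRESHOLD_REPS,
    seed: int | None = None,
    randomize_nuisance: bool = True,
) -> float:
    """Decision threshold (1+M)^2 * q99 of the simulated null distribution.

    The null simulation draws nuisance CVs and concentration intervals
    per dataset by default, matching the conditions of the shipped
    reference table.  With a shared seed the M-dependence is exactly the
    algebraic factor (1+M)^2.
    """
    if M < 0:
        raise DomainError("M must be >= 0")
    if reps < 10_000:
        raise DomainError("threshold simulation needs reps >= 10^4")
    config = ScenarioConfig(
        scenario=1, n=n, R=R, randomize_nuisance=randomize_nuisance
    )
    z0 = simulate_zeta_distribution(config, reps, seed=seed)
    return float((1.0 + M) ** 2 * np.quantile(z0, 0.99))


def build_lookup_table(
    designs: list[tuple[int, int]],
    Ms: list[float],
    reps: int = DEFAULT_THRESHOLD_REPS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pre-simulated thresholds keyed by (n, R, M).

    One null simulation per design; every M row is the exact (1+M)^2
    multiple of that design's base percentile.  The generation seed and
    replicate count are recorded per row for audit.
    """
    if not designs or not Ms:
        raise DomainError("need at least one design and one M value")
    ss = np.random.SeedSequence(seed)
    rows = []
    for (n, R), child in zip(designs, ss.spawn(len(designs))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        base = zeta_upper(n, R, 0.0, reps=reps, seed=sub_seed)
        for M in Ms:
            rows.append(
                {
                    "n": n,
                    "R": R,
                    "M_percent": 100.0 * M,
                    "zeta_upper": (1.0 + M) ** 2 * base,
                    "reps": reps,
                    "seed": sub_seed,
                }
            )
    return pd.DataFrame(rows)


def lookup_zeta_upper(table: pd.DataFrame, n: int, R: int, M: float) -> float | None:
    """Exact-match lookup of a threshold; None when the row is absent."""
    hit = table[
        (table["n"] == n)
        & (table["R"] == R)
        & (np.isclose(table["M_percent"], 100.0 * M))
    ]
    if hit.empty:
        return None
    return float(hit["zeta_upper"].iloc[0])


@lru_cache(maxsize=256)
def _studentized_range_critical(k: int, df: int, level: float) -> float:
    return float(stats.studentized_range.ppf(level, k, df))


def screen_outliers(
    data: ComparisonData, alpha: float = 0.01
) -> tuple[ComparisonData, tuple]:
    """Remove samples whose replicates contain an outlier on either device.

    Per sample and device the studentized range (replicate range over the
    pooled within-sample SD) is compared to the critical value of the
    studentized range distribution with the pooled degrees of freedom.
    ``alpha`` is the family-wise level: it is split (Bonferroni) over all
    per-sample-per-device tests, so clean data rarely lose any sample.
    Flagged samples are removed whole from both devices.
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must lie in (0, 1)")
    ids = np.unique(data.sample_ids)
    if data.R < 2:
        raise DomainError("outlier screening needs R >= 2 replicates")

    flagged: set = set()
    n_tests = 0
    tests = []  # (sample, k, w) with pooled df per device
    for values in (data.x, data.y):
        per_sample = []
        for s in ids.tolist():
            v = values[data.sample_ids == s]
            v = v[np.isfinite(v)]
            if len(v) >= 2:
                per_sample.append((s, v))
        df = sum(len(v) - 1 for _, v in per_sample)
        pooled_sd = np.sqrt(
            sum(((v - v.mean()) ** 2).sum() for _, v in per_sample) / df
        )
        for s, v in per_sample:
            n_tests += 1
            if pooled_sd > 0:
                tests.append((s, len(v), float(np.ptp(v)) / pooled_sd, df))
    for s, k, w, df in tests:
        crit = _studentized_range_critical(k, df, 1.0 - alpha / n_tests)
        if w > crit:
            flagged.add(s)

    if not flagged:
        return data, ()
    keep = ~np.isin(data.sample_ids, list(flagged))
    if len(np.unique(data.sample_ids[keep])) < 2:
        raise DegenerateDesignError("outlier removal left fewer than 2 samples")
    screened = dataclasses.replace(
        data,
        sample_ids=data.sample_ids[keep],
        replicate_ids=data.replicate_ids[keep],
        x=data.x[keep],
        y=data.y[keep],
    )
    return screened, tuple(sorted(flagged, key=str))


def select_transformation(
    data: ComparisonData,
) -> tuple[str, DinsEstimate, dict[str, float]]:
    """Choose the scale (raw or natural log) whose zeta-hat is nearest 1.

    The log scale is only considered when all measurements are positive;
    otherwise raw is forced.  Returns the chosen scale, its estimate and
    both candidate values.
    """
    est_raw = zeta_full(data)
    candidates = {"raw": est_raw}
    can_log = bool(
        (data.x[np.isfinite(data.x)] > 0).all()
        and (data.y[np.isfinite(data.y)] > 0).all()
    )
    if can_log:
        candidates["log"] = zeta_full(log_transform(data))
    chosen = min(candidates, key=lambda k: abs(candidates[k].zeta - 1.0))
    values = {k: v.zeta for k, v in candidates.items()}
    return chosen, candidates[chosen], values


def flag_excessive_dins(
    data: ComparisonData,
    M: float,
    alpha_outlier: float | None = 0.01,
    reps: int = DEFAULT_THRESHOLD_REPS,
    seed: int | None = None,
    transformation: str = "auto",
    lookup_table: pd.DataFrame | None = None,
) -> DecisionResult:
    """The six-step excessive-DINS decision for one device pair.

    Screens replicate outliers (skipped when ``alpha_outlier`` is None),
    determines the post-screening design, obtains the threshold from the
    look-up table when it covers (n, R, M) and otherwise from a fresh
    simulation, computes zeta-hat on the selected scale, and compares:
    the pair is flagged iff zeta-hat strictly exceeds the threshold.
    """
    if M < 0:
        raise DomainError("M must be >= 0")
    if transformation not in ("auto", "raw", "log"):
        raise DomainError(f"unknown transformation {transformation!r}")

    removed: tuple = ()
    if alpha_outlier is not None:
        data, removed = screen_outliers(data, alpha_outlier)
    n, R = data.n, data.R

    threshold = None
    source = "simulation"
    if lookup_table is not None:
        threshold = lookup_zeta_upper(lookup_table, n, R, M)
        if threshold is not None:
            source = "lookup"
    if threshold is None:
        threshold = zeta_upper(n, R, M, reps=reps, seed=seed)

    zeta_raw = zeta_log = None
    if transformation == "auto":
        chosen, est, values = select_transformation(data)
        zeta_raw = values.get("raw")
        zeta_log = values.get("log")
    elif transformation == "log":
        chosen, est = "log", zeta_full(log_transform(data))
        zeta_log = est.zeta
    else:
        chosen, est = "raw", zeta_full(data)
        zeta_raw = est.zeta

    return DecisionResult(
        zeta_hat=est.zeta,
        zeta_upper=threshold,
        M=M,
        n=n,
        R=R,
        transformation=chosen,
        excessive=bool(est.zeta > threshold),
        outliers_removed=removed,
        zeta_raw=zeta_raw,
        zeta_log=zeta_log,
        threshold_source=source,
        estimate=est,
    )
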