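"""Cluster-bootstrap inference on the DINS estimator.

Replicate measurements of one clinical sample form a cluster, so
resampling must keep clusters intact: samples are drawn with replacement
and each drawn sample carries all of its replicate rows.  Duplicated
samples receive fresh identifiers so the resampled design keeps exactly
n samples (the estimator depends on n and nR through its degrees of
freedom).  Inference uses the bootstrap percentile interval (BPCI); the
interval endpoints are plain type-7 quantiles of the replicate vector.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ComparisonData, DinsError, DomainError
from .estimator import zeta_batch, zeta_full, zeta_simplified

__all__ = ["BootstrapResult", "cluster_resample", "bootstrap_zeta"]


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate, resample distribution and BPCI for one comparison."""

    point_estimate: float
    replicates: np.ndarray
    bpci_lower: float
    bpci_upper: float
    alpha: float
    B: int
    n_failures: int
    seed: int | None
    comparison: str = ""
    unstable: bool = False  # > 10% of resamples failed

    @property
    def summary(self) -> dict[str, float]:
        """Distribution summaries of the replicate vector.

        Kurtosis is non-excess (normal = 3); MAD is scaled to be
        consistent with the SD under normality.
        """
        z = self.replicates
        return {
            "mean": float(np.mean(z)),
            "sd": float(np.std(z, ddof=1)),
            "cv": float(np.std(z, ddof=1) / np.mean(z)),
            "skewness": float(stats.skew(z)),
            "kurtosis": float(stats.kurtosis(z, fisher=False)),
            "mad": float(stats.median_abs_deviation(z, scale="normal")),
            "q1": float(np.quantile(z, 0.25)),
            "median": float(np.quantile(z, 0.5)),
            "q3": float(np.quantile(z, 0.75)),
            "min": float(np.min(z)),
            "max": float(np.max(z)),
        }

    def to_row(self) -> dict[str, float | str]:
        """One row in the per-comparison report layout."""
        s = self.summary
        return {
            "comparison": self.comparison,
            "zeta": self.point_estimate,
            "lower": self.bpci_lower,
            "upper": self.bpci_upper,
            "mean": s["mean"],
            "SD": s["sd"],
            "skewness": s["skewness"],
            "kurtosis": s["kurtosis"],
            "MAD": s["mad"],
            "Q1": s["q1"],
            "median": s["median"],
            "Q3": s["q3"],
            "min": s["min"],
            "max": s["max"],
        }

    def to_json(self) -> str:
        d = {
            "comparison": self.comparison,
            "point_estimate": self.point_estimate,
            "bpci_lower": self.bpci_lower,
            "bpci_upper": self.bpci_upper,
            "alpha": self.alpha,
            "B": self.B,
            "n_failures": self.n_failures,
            "seed": self.seed,
            "unstable": self.unstable,
            "summary": self.summary,
        }
        return json.dumps(d, indent=2)


def cluster_resample(
    data: ComparisonData, rng: np.random.Generator | int | None = None
) -> ComparisonData:
    """One cluster resample: n samples drawn with replacement.

    Each drawn sample contributes all of its replicate rows; duplicated
    draws get fresh unique sample ids so the resample again has exactly n
    distinct samples.  With a single cluster the resample equals the
    original data.
    """
    rng = np.random.default_rng(rng)
    ids = np.unique(data.sample_ids)
    n = len(ids)
    drawn = rng.integers(0, n, size=n)
    rows_by_sample = {
        s: np.flatnonzero(data.sample_ids == s) for s in ids.tolist()
    }
    idx_parts, new_ids = [], []
    for new_id, j in enumerate(drawn.tolist(), start=1):
        rows = rows_by_sample[ids[j]]
        idx_parts.append(rows)
        new_ids.append(np.full(len(rows), new_id))
    idx = np.concatenate(idx_parts)
    return dataclasses.replace(
        data,
        sample_ids=np.concatenate(new_ids),
        replicate_ids=data.replicate_ids[idx],
        x=data.x[idx],
        y=data.y[idx],
    )


def _balanced_arrays(data: ComparisonData) -> tuple[np.ndarray, np.ndarray] | None:
    """(n, R) arrays of x and y if the data are balanced and complete."""
    ids, inv = np.unique(data.sample_ids, return_inverse=True)
    n = len(ids)
    counts = np.bincount(inv, minlength=n)
    R = counts[0]
    if R < 2 or not (counts == R).all():
        return None
    if not (np.isfinite(data.x).all() and np.isfinite(data.y).all()):
        return None
    order = np.lexsort((data.replicate_ids, inv))
    return data.x[order].reshape(n, R), data.y[order].reshape(n, R)


def bootstrap_zeta(
    data: ComparisonData,
    B: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    form: str = "full",
    comparison: str = "",
) -> BootstrapResult:
    """Cluster-bootstrap distribution of zeta-hat with a BPCI.

    The estimator is recomputed on each of B cluster resamples with
    predictor/response roles re-assigned per resample.  Resamples on
    which the estimator is undefined (degenerate designs) are redrawn, up
    to 10*B attempts; remaining failures are counted, and the result is
    marked unstable when they exceed 10% of B.
    """
    if B < 100:
        raise DomainError("bootstrap needs B >= 100 resamples")
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must lie in (0, 1)")
    estimator = zeta_full if form == "full" else zeta_simplified
    point = estimator(data).zeta
    rng = np.random.default_rng(seed)

    arrays = _balanced_arrays(data)
    n_failures = 0
    if arrays is not None:
        x, y = arrays
        n = x.shape[0]
        draws = rng.integers(0, n, size=(B, n))
        reps = zeta_batch(x[draws], y[draws], form=form)
        bad = ~np.isfinite(reps)
        attempts = 0
        while bad.any() and attempts < 9 * B:
            k = int(bad.sum())
            redraws = rng.integers(0, n, size=(k, n))
            reps[bad] = zeta_batch(x[redraws], y[redraws], form=form)
            bad = ~np.isfinite(reps)
            attempts += k
        n_failures = int(bad.sum())
        reps = reps[np.isfinite(reps)]
    else:
        vals = []
        attempts = 0
        while len(vals) < B and attempts < 10 * B:
            attempts += 1
            try:
                vals.append(estimator(cluster_resample(data, rng)).zeta)
            except DinsError:
                n_failures += 1
        reps = np.asarray(vals)
    if reps.size == 0:
        raise DomainError("all bootstrap resamples failed")
    lower = float(np.quantile(reps, alpha / 2))
    upper = float(np.quantile(reps, 1 - alpha / 2))
    return BootstrapResult(
        point_estimate=point,
        replicates=reps,
        bpci_lower=lower,
        bpci_upper=upper,
        alpha=alpha,
        B=B,
        n_failures=n_failures,
        seed=seed,
        comparison=comparison or f"{data.device_a} - {data.device_b}",
        unstable=n_failures > 0.1 * B,
    )


def results_to_table(results: list[BootstrapResult]) -> pd.DataFrame:
    """Stack per-comparison bootstrap reports into one table."""
    return pd.DataFrame([r.to_row() for r in results])
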