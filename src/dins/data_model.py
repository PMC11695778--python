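"""Domain types and I/O for replicated two-device method-comparison tables.

A method-comparison study measures each of ``n`` clinical samples ``R``
times on two in vitro diagnostic measurement devices (IVD-MDs).  The
long-format table has one row per (sample, replicate) with one numeric
column per device.  Missing replicates are allowed and preserved as NaN;
they are never dropped silently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "DinsError",
    "FormatError",
    "IntegrityError",
    "DomainError",
    "InsufficientReplicationError",
    "DegenerateDesignError",
    "ComparisonData",
    "LatentModelParams",
    "read_comparison_table",
    "write_comparison_table",
    "log_transform",
]

SAMPLE_COL = "SampleID"
REPLICATE_COL = "ReplicateID"


class DinsError(ValueError):
    """Base class for all domain errors raised by this package."""


class FormatError(DinsError):
    """The input file does not have the expected layout or dtypes."""


class IntegrityError(DinsError):
    """The data violate a structural invariant (e.g. duplicated rows)."""


class DomainError(DinsError):
    """A value is outside the mathematical domain of an operation."""


class InsufficientReplicationError(DinsError):
    """No sample carries enough replicates for a pooled variance."""


class DegenerateDesignError(DinsError):
    """The regression design is degenerate (too few pairs, constant x)."""


@dataclass(frozen=True)
class ComparisonData:
    """Replicated paired measurements for one device pair.

    Parameters
    ----------
    sample_ids
        Sample identifier per row (clinical sample i in 1..n).
    replicate_ids
        Replicate identifier per row (r in 1..R).
    x, y
        Measurements of device A and device B per (i, r), in the same
        (arbitrary) concentration units.  NaN marks a missing replicate.
    device_a, device_b
        Column names of the two devices, kept for reporting.
    """

    sample_ids: np.ndarray
    replicate_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    device_a: str = "X"
    device_b: str = "Y"
    # Measured concentrations must be strictly positive; data on a log (or
    # otherwise transformed) scale are exempt from that check.
    require_positive: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", np.asarray(self.sample_ids))
        object.__setattr__(self, "replicate_ids", np.asarray(self.replicate_ids))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        self._validate()

    # -- structural properties ------------------------------------------------

    @property
    def n(self) -> int:
        """Number of distinct clinical samples."""
        return len(np.unique(self.sample_ids))

    @property
    def R(self) -> int:
        """Nominal number of replicates per sample (the maximum observed)."""
        _, counts = np.unique(self.sample_ids, return_counts=True)
        return int(counts.max())

    @property
    def n_complete_pairs(self) -> int:
        """Rows where both devices have a non-missing measurement."""
        return int(np.sum(np.isfinite(self.x) & np.isfinite(self.y)))

    def __len__(self) -> int:
        return len(self.sample_ids)

    # -- validation -----------------------------------------------------------

    def _validate(self) -> None:
        m = len(self.sample_ids)
        if not (len(self.replicate_ids) == len(self.x) == len(self.y) == m):
            raise FormatError("sample_ids, replicate_ids, x, y must share length")
        if m == 0:
            raise FormatError("empty comparison table")
        keys = list(zip(self.sample_ids.tolist(), self.replicate_ids.tolist()))
        if len(set(keys)) != m:
            dup = sorted({k for k in keys if keys.count(k) > 1})[0]
            raise IntegrityError(
                f"duplicated (SampleID, ReplicateID) pair {dup!r}"
            )
        for name, v in (("x", self.x), ("y", self.y)):
            bad = np.isinf(v)
            if self.require_positive:
                bad |= np.isfinite(v) & (v <= 0)
            if bad.any():
                raise DomainError(
                    f"{name} contains non-finite or non-positive measurements"
                )
        if self.n < 2:
            raise IntegrityError("at least 2 distinct samples are required")
        for v in (self.x, self.y):
            if not _has_replicated_sample(self.sample_ids, v):
                raise InsufficientReplicationError(
                    "no sample has >= 2 non-missing replicates on each device"
                )

    # -- conversions ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                SAMPLE_COL: self.sample_ids,
                REPLICATE_COL: self.replicate_ids,
                self.device_a: self.x,
                self.device_b: self.y,
            }
        )

    def swapped(self) -> "ComparisonData":
        """Interchange the two devices (x <-> y)."""
        return dataclasses.replace(
            self, x=self.y, y=self.x, device_a=self.device_b, device_b=self.device_a
        )

    def with_values(self, x: np.ndarray, y: np.ndarray) -> "ComparisonData":
        return dataclasses.replace(self, x=np.asarray(x, float), y=np.asarray(y, float))


def _has_replicated_sample(sample_ids: np.ndarray, values: np.ndarray) -> bool:
    ok = np.isfinite(values)
    ids, inv = np.unique(sample_ids, return_inverse=True)
    counts = np.bincount(inv[ok], minlength=len(ids))
    return bool((counts >= 2).any())


@dataclass(frozen=True)
class LatentModelParams:
    """Parameters of the latent measurement model.

    The true concentration of sample i is tau_i ~ Uniform(c_lower, c_upper);
    the second device measures xi_i = beta0 + beta1 * tau_i.  Each device
    adds zero-mean normal error whose standard deviation is its repeatability
    coefficient of variation times the mid-interval concentration.
    """

    beta0: float = 0.0
    beta1: float = 1.0
    c_lower: float = 5.0
    c_upper: float = 90.0
    cv_x: float = 0.01
    cv_y: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.c_lower < self.c_upper):
            raise DomainError("need 0 < c_lower < c_upper")
        if self.cv_x <= 0 or self.cv_y <= 0:
            raise DomainError("device CVs must be positive")

    @property
    def mean_concentration(self) -> float:
        return 0.5 * (self.c_lower + self.c_upper)

    @property
    def sd_x(self) -> float:
        """Repeatability SD of device A (CV times mid-interval level)."""
        return self.cv_x * self.mean_concentration

    @property
    def sd_y(self) -> float:
        return self.cv_y * self.mean_concentration


# -- reading and writing ------------------------------------------------------


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_comparison_table(
    path: str | Path, device_a: str, device_b: str
) -> ComparisonData:
    """Read a long-format CSV/TSV comparison table.

    The file must contain ``SampleID``, ``ReplicateID`` and the two named
    numeric device columns (case-sensitive).  The separator (comma or tab)
    is auto-detected from the header line.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    required = [SAMPLE_COL, REPLICATE_COL, device_a, device_b]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path.name}")
    for col in (device_a, device_b):
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            raise FormatError(
                f"non-numeric measurement in column {col!r}, "
                f"row {int(newly_bad.idxmax())}"
            )
        df[col] = coerced
    return ComparisonData(
        sample_ids=df[SAMPLE_COL].to_numpy(),
        replicate_ids=df[REPLICATE_COL].to_numpy(),
        x=df[device_a].to_numpy(float),
        y=df[device_b].to_numpy(float),
        device_a=device_a,
        device_b=device_b,
    )


def write_comparison_table(data: ComparisonData, path: str | Path, sep: str = ",") -> None:
    """Write the same long-format layout that :func:`read_comparison_table` reads."""
    data.to_frame().to_csv(path, sep=sep, index=False)


def log_transform(data: ComparisonData) -> ComparisonData:
    """Elementwise natural log of both devices; identifiers unchanged.

    Raises
    ------
    DomainError
        If any non-missing measurement is non-positive.
    """
    for name, v in (("x", data.x), ("y", data.y)):
        if (np.isfinite(v) & (v <= 0)).any():
            raise DomainError(f"log transform requires positive {name} values")
    out = data.with_values(np.log(data.x), np.log(data.y))
    return dataclasses.replace(out, require_positive=False)


def list_device_columns(path: str | Path) -> list[str]:
    """All non-identifier columns of a comparison table (for pairwise loops)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), nrows=0)
    return [c for c in df.columns if c not in (SAMPLE_COL, REPLICATE_COL)]
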