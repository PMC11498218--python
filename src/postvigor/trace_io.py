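"""Reading, validating and preprocessing posting-trace data.

A trace is one user's time-ordered sequence of posts, each with a UTC
timestamp and a like count.  Preprocessing follows the conventions used for
Instagram trace datasets: rows without a parseable timestamp are dropped at
read time, carousel posts (runs of rows sharing one timestamp) are collapsed
to their first row, users with fewer than ten posts are excluded, and
inter-post latencies are expressed in days with the first latency undefined.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400.0
#: Latencies that survive carousel collapsing but are still zero (or below the
#: timestamp resolution) are clamped to this floor, in days, so the
#: exponential log-density stays finite.
LATENCY_FLOOR_DAYS = 1e-3

_REQUIRED_COLUMNS = ("user_id", "timestamp", "likes")


@dataclass
class UserTrace:
    """One user's ordered posts with optional derived latencies.

    Attributes
    ----------
    user_id : str
        Opaque user identifier.
    timestamps : numpy.ndarray of datetime64
        Post times (UTC), nondecreasing.
    likes : numpy.ndarray of int
        Non-negative like counts, aligned with ``timestamps``.
    latencies : numpy.ndarray of float or None
        Inter-post intervals in days; ``latencies[0]`` is NaN (the first
        latency is undefined).  ``None`` until :func:`compute_latencies`.
    """

    user_id: str
    timestamps: np.ndarray
    likes: np.ndarray
    latencies: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.likes = np.asarray(self.likes, dtype=np.int64)
        if self.timestamps.shape != self.likes.shape:
            raise ValueError("timestamps and likes must be aligned")
        if np.any(self.likes < 0):
            raise ValueError("like counts must be non-negative")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) < np.timedelta64(0, "s")):
            raise ValueError("timestamps must be nondecreasing; sort before constructing")
        if self.latencies is not None:
            self.latencies = np.asarray(self.latencies, dtype=float)
            if self.latencies.shape != self.timestamps.shape:
                raise ValueError("latencies must be aligned with posts")

    @property
    def n_posts(self) -> int:
        return int(self.timestamps.size)


@dataclass(frozen=True)
class ReadReport:
    """Row accounting for one read: total rows and rows dropped for a
    missing/unparseable timestamp."""

    n_rows: int
    n_dropped_missing_timestamp: int


def _frame_to_traces(df: pd.DataFrame) -> tuple[list[UserTrace], ReadReport]:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    n_rows = len(df)
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    dropped = int(ts.isna().sum())
    if dropped:
        logger.warning("dropped %d row(s) with missing/unparseable timestamp", dropped)
    keep = ~ts.isna()
    df = df.loc[keep].copy()
    df["timestamp"] = ts[keep].dt.tz_convert("UTC").dt.tz_localize(None)
    traces: list[UserTrace] = []
    for user_id, grp in df.groupby("user_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        traces.append(
            UserTrace(
                user_id=str(user_id),
                timestamps=grp["timestamp"].to_numpy(dtype="datetime64[s]"),
                likes=grp["likes"].to_numpy(dtype=np.int64),
            )
        )
    return traces, ReadReport(n_rows=n_rows, n_dropped_missing_timestamp=dropped)


def read_trace(
    path: str | Path, fmt: str | None = None, with_report: bool = False
) -> list[UserTrace] | tuple[list[UserTrace], ReadReport]:
    """Read per-user traces from a CSV or JSONL file.

    The file has one row/object per post with keys ``user_id``, ``timestamp``
    (ISO-8601) and ``likes``.  Rows whose timestamp is missing or unparseable
    are dropped with a warning; each user's posts are returned time-sorted.
    Lines starting with ``#`` in CSV files are treated as comments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    if fmt == "csv":
        try:
            df = pd.read_csv(path, comment="#", dtype={"user_id": str})
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=list(_REQUIRED_COLUMNS))
    elif fmt == "jsonl":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        df = pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) if not rows else None)
    else:
        raise ValueError(f"unknown trace format: {fmt!r}")
    if df.empty:
        traces, report = [], ReadReport(0, 0)
    else:
        traces, report = _frame_to_traces(df)
    return (traces, report) if with_report else traces


def traces_to_frame(cohort: Iterable[UserTrace]) -> pd.DataFrame:
    """Flatten a cohort into the standard one-row-per-post table."""
    parts = []
    for tr in cohort:
        parts.append(
            pd.DataFrame(
                {
                    "user_id": tr.user_id,
                    "timestamp": pd.Series(tr.timestamps).dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "likes": tr.likes,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=list(_REQUIRED_COLUMNS))
    return pd.concat(parts, ignore_index=True)


def write_trace(
    cohort: Iterable[UserTrace],
    path: str | Path,
    fmt: str | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a cohort to CSV or JSONL (inverse of :func:`read_trace`)."""
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    df = traces_to_frame(cohort)
    if fmt == "csv":
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                rec["likes"] = int(rec["likes"])
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown trace format: {fmt!r}")


def collapse_carousel(trace: UserTrace) -> UserTrace:
    """Collapse runs of posts sharing an identical timestamp to their first.

    Carousel posts are recorded as several rows with one timestamp and one
    like count; only the first row of each run is kept.  Idempotent.
    """
    if trace.n_posts <= 1:
        return replace(trace, latencies=None)
    keep = np.ones(trace.n_posts, dtype=bool)
    keep[1:] = trace.timestamps[1:] != trace.timestamps[:-1]
    return UserTrace(trace.user_id, trace.timestamps[keep], trace.likes[keep])


def filter_users(cohort: Sequence[UserTrace], min_posts: int = 10) -> list[UserTrace]:
    """Drop users with fewer than ``min_posts`` posts (default 10)."""
    if min_posts < 1:
        raise ValueError("min_posts must be >= 1")
    kept = [tr for tr in cohort if tr.n_posts >= min_posts]
    n_removed = len(cohort) - len(kept)
    if n_removed:
        logger.info("filter_users: removed %d of %d users (< %d posts)", n_removed, len(cohort), min_posts)
    if not kept and len(cohort) > 0:
        logger.warning("filter_users: all %d users below the %d-post threshold", len(cohort), min_posts)
    return kept


def compute_latencies(trace: UserTrace, floor: float = LATENCY_FLOOR_DAYS) -> UserTrace:
    """Derive inter-post latencies in days; the first latency is NaN.

    Zero or sub-resolution gaps that survive carousel collapsing are clamped
    to ``floor`` days.
    """
    lat = np.full(trace.n_posts, np.nan)
    if trace.n_posts > 1:
        gaps = np.diff(trace.timestamps).astype("timedelta64[s]").astype(float) / SECONDS_PER_DAY
        lat[1:] = np.maximum(gaps, floor)
    return replace(trace, latencies=lat)


def preprocess_cohort(
    cohort: Sequence[UserTrace],
    min_posts: int = 10,
    floor: float = LATENCY_FLOOR_DAYS,
) -> list[UserTrace]:
    """Carousel-collapse, filter by post count, and compute latencies."""
    collapsed = [collapse_carousel(tr) for tr in cohort]
    return [compute_latencies(tr, floor=floor) for tr in filter_users(collapsed, min_posts)]
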