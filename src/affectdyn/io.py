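"""Reading and writing affect series and result tables.

Series files are delimited text with a header and the required columns
``subject_id``, ``time`` (minutes from study start, or ISO timestamps),
``pa`` and ``na``.  PA/NA values may be on the unit interval or on the
0-100 slider scale; the scale is auto-detected per file and 0-100 input
is rescaled (with a logged notice).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .series import AffectTimeSeries

__all__ = ["read_series", "write_series", "fit_table", "stats_table"]

logger = logging.getLogger("affectdyn")

REQUIRED_COLUMNS = ("subject_id", "time", "pa", "na")


def _times_to_minutes(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, errors="raise")
    t0 = parsed.min()
    return ((parsed - t0).dt.total_seconds() / 60.0).to_numpy()


def read_series(path, dialect: str | None = None) -> list[AffectTimeSeries]:
    """Read per-subject affect series from a delimited text file.

    ``dialect`` is the field separator (default: sniffed from the file
    suffix, comma for .csv, tab for .tsv).  Values outside both accepted
    ranges and duplicate timestamps within a subject raise, naming the
    offending rows.
    """
    path = Path(path)
    sep = dialect or ("\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    vals = df[["pa", "na"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        bad = np.nonzero(~np.isfinite(vals).all(axis=1))[0]
        raise ValueError(f"non-finite pa/na values at rows {bad[:5].tolist()}")
    if vals.max() > 1.0 + 1e-12:
        if vals.min() < 0 or vals.max() > 100.0:
            bad = np.nonzero((vals < 0) | (vals > 100.0))[0]
            raise ValueError(
                f"pa/na values outside both [0,1] and [0,100] at rows {bad[:5].tolist()}"
            )
        logger.info("detected 0-100 slider scale in %s; rescaling to [0, 1]", path)
        df = df.assign(pa=df["pa"] / 100.0, na=df["na"] / 100.0)
    elif vals.min() < 0:
        bad = np.nonzero((vals < 0).any(axis=1))[0]
        raise ValueError(f"negative pa/na values at rows {bad[:5].tolist()}")

    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        times = _times_to_minutes(grp["time"])
        order = np.argsort(times, kind="stable")
        times = times[order]
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"duplicate or non-increasing times for subject {sid!r}")
        y = grp[["pa", "na"]].to_numpy(dtype=float)[order]
        day = (
            grp["day"].to_numpy(dtype=int)[order]
            if "day" in grp.columns
            else None
        )
        out.append(AffectTimeSeries(times, y, subject_id=str(sid), day=day))
    return out


def write_series(series_list: Sequence[AffectTimeSeries], path, dialect: str | None = None) -> None:
    """Write subject series to one delimited file (lossless roundtrip)."""
    path = Path(path)
    sep = dialect or ("\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    frames = [
        pd.DataFrame(
            {
                "subject_id": s.subject_id,
                "time": s.times,
                "day": s.day,
                "pa": s.y[:, 0],
                "na": s.y[:, 1],
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def fit_table(results) -> pd.DataFrame:
    """Flatten FitResults into one row per (subject, family)."""
    rows = []
    for subject_id, res in results:
        row = {
            "subject_id": subject_id,
            "family": res.family,
            "min_log_lik": res.min_log_lik,
            "n_obs": res.n_obs,
            "seed": res.seed,
            "constraint_mode": res.constraint_mode,
            "converged": res.converged,
        }
        est = res.estimates
        if res.family == "aim":
            row.update(
                lambda1=est.lambda1, lambda2=est.lambda2, lambda12=est.lambda12,
                theta1=est.theta1, theta2=est.theta2, n1=est.n1, n2=est.n2,
                diffusion=est.diffusion,
            )
        else:
            b = est.drift_matrix
            c = est.diffusion_chol
            row.update(
                mu1=est.mu[0], mu2=est.mu[1],
                b11=b[0, 0], b12=b[0, 1], b21=b[1, 0], b22=b[1, 1],
                c11=c[0, 0], c21=c[1, 0], c22=c[1, 1], bounded=est.bounded,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def stats_table(series_list: Sequence[AffectTimeSeries]) -> pd.DataFrame:
    """FeatureStats per subject as a flat table."""
    from .features import summary_stats
    from dataclasses import asdict

    rows = []
    for s in series_list:
        row = {"subject_id": s.subject_id}
        row.update(asdict(summary_stats(s)))
        rows.append(row)
    return pd.DataFrame(rows)
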