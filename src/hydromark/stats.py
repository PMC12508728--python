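"""Descriptive maximum-change statistics and paired tests.

Per session the marker's baseline is the mean of pre-ingestion samples and
the "maximum change" is the post-ingestion sample farthest from baseline in
absolute value, reported signed — so stiffness, which falls after drinking,
yields negative changes.  Across participants each marker x volume cell is
summarised as mean ± SD of absolute and relative change plus a two-sided
paired t-test of baseline vs extremum values.  No multiplicity correction is
applied across the marker x volume grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import Marker, MarkerSeries

__all__ = ["ChangeSummary", "max_change", "paired_t", "summarize_cohort"]


@dataclass
class ChangeSummary:
    """One marker x volume row of the descriptive table."""

    marker: Marker
    volume: float
    abs_changes: np.ndarray  # signed, per participant (marker units)
    rel_changes: np.ndarray  # signed, per participant (%)
    t_at: np.ndarray  # time of extremum per participant (s)
    abs_mean: float
    abs_sd: float
    rel_mean: float
    rel_sd: float
    p_value: float


def max_change(series: MarkerSeries) -> tuple[float, float, float]:
    """Signed maximum change from baseline of one series.

    Baseline is the mean of t < 0 samples.  Over t > 0 samples the index
    maximising ``|v - baseline|`` (earliest on ties) defines the extremum;
    returns ``(v* - baseline, 100 (v* - baseline)/baseline, t*)``.
    """
    pre = series.pre
    if len(pre) == 0:
        raise ValueError("series has no pre-ingestion samples")
    post = series.post_mask
    if int(np.sum(post)) < 2:
        raise ValueError("series needs at least two post-ingestion samples")
    b = float(np.mean(pre))
    if b == 0.0:
        raise ValueError("baseline is zero; relative change undefined")
    dev = series.values[post] - b
    i = int(np.argmax(np.abs(dev)))  # argmax returns the first maximum
    return float(dev[i]), float(100.0 * dev[i] / b), float(series.times[post][i])


def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Classical two-sided paired t-test (n - 1 df) of matched samples."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    if len(pre) < 2:
        raise ValueError("paired t-test needs at least two pairs")
    if np.var(post - pre, ddof=1) == 0.0:
        raise ValueError("zero-variance differences; t statistic undefined")
    res = sps.ttest_rel(post, pre)
    return float(res.statistic), float(res.pvalue)


def summarize_cohort(cohort, markers=None, volumes=None) -> list[ChangeSummary]:
    """Descriptive table rows: one per marker x volume.

    For each cell, per-participant signed maximum changes and the paired
    test of baselines against each participant's own extremum value.
    """
    markers = list(markers) if markers is not None else list(Marker)
    volumes = list(volumes) if volumes is not None else cohort.volumes
    rows: list[ChangeSummary] = []
    for m in markers:
        for vol in volumes:
            abs_c, rel_c, t_at, bases, peaks = [], [], [], [], []
            for part in cohort.participants:
                s = cohort.series(part.id, vol, m)
                a, r, t = max_change(s)
                b = float(np.mean(s.pre))
                abs_c.append(a)
                rel_c.append(r)
                t_at.append(t)
                bases.append(b)
                peaks.append(b + a)
            if len(abs_c) < 2:
                raise ValueError("need at least 2 participants per volume")
            abs_c = np.array(abs_c)
            rel_c = np.array(rel_c)
            try:
                _, p = paired_t(np.array(bases), np.array(peaks))
            except ValueError:
                p = float("nan")
            rows.append(
                ChangeSummary(
                    marker=m, volume=vol,
                    abs_changes=abs_c, rel_changes=rel_c, t_at=np.array(t_at),
                    abs_mean=float(np.mean(abs_c)), abs_sd=float(np.std(abs_c, ddof=1)),
                    rel_mean=float(np.mean(rel_c)), rel_sd=float(np.std(rel_c, ddof=1)),
                    p_value=float(p),
                )
            )
    return rows


def summary_frame(rows: list[ChangeSummary]) -> pd.DataFrame:
    """Flatten summaries to the descriptive-table DataFrame."""
    return pd.DataFrame(
        {
            "marker": [r.marker.value for r in rows],
            "volume_L": [r.volume for r in rows],
            "abs_mean": [r.abs_mean for r in rows],
            "abs_sd": [r.abs_sd for r in rows],
            "rel_mean_pct": [r.rel_mean for r in rows],
            "rel_sd_pct": [r.rel_sd for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
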