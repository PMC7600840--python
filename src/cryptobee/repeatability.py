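"""Observer repeatability of the malar-ratio measurements.

Repeat measurements by the same observer, and measurements of the same
bees by different observers, are compared with Pearson correlations
(t-statistics on n-2 df).  A second diagnostic correlates the SD of a
specimen's repeated measurements with their mean, to check whether small
bees are measured less reliably.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .morphometrics import RATIO_NAMES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float


def pearson_test(x, y) -> CorrelationResult:
    """Sample Pearson r with its t-test: t = r sqrt(df) / sqrt(1 - r^2), df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r=float(np.sign(r)), t=float(np.sign(r) * np.inf),
                                 df=df, p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * st.t.sf(abs(t), df)
    return CorrelationResult(r=r, t=float(t), df=df, p=float(p))


def sd_vs_mean(replicates: pd.DataFrame, value: str) -> CorrelationResult:
    """Correlation between per-specimen replicate SD and replicate mean.

    ``replicates`` is a long table with a ``specimen_id`` column and the
    measurement in column ``value``.  Specimens with a single replicate
    are excluded (logged).
    """
    counts = replicates.groupby("specimen_id")[value].count()
    singles = counts[counts < 2].index
    if len(singles):
        logger.info("sd_vs_mean: excluding %d single-replicate specimens", len(singles))
    kept = replicates[~replicates["specimen_id"].isin(singles)]
    if kept["specimen_id"].nunique() < 3:
        raise ValueError("need >= 3 specimens with >= 2 replicates")
    g = kept.groupby("specimen_id")[value]
    return pearson_test(g.mean().to_numpy(), g.std(ddof=1).to_numpy())


def _corr_row(comparison, measurement, x, y):
    try:
        res = pearson_test(x, y)
        return {"comparison": comparison, "measurement": measurement,
                "r": res.r, "t": res.t, "df": res.df, "p": res.p}
    except ValueError:
        return {"comparison": comparison, "measurement": measurement,
                "r": np.nan, "t": np.nan, "df": np.nan, "p": np.nan}


def repeatability_report(replicate_table: pd.DataFrame) -> pd.DataFrame:
    """Within- and between-observer correlation table for each ratio.

    Expects the tidy replicate format of the synthetic generator
    (``specimen_id, observer, rep, mr1, mr3, mrl``); measurement columns
    that an observer did not record may be NaN and yield NA rows.

    Within-observer rows correlate an observer's first and second
    replicate per specimen; between-observer rows correlate per-specimen
    replicate means of the two observers; SD-vs-mean rows pool both
    observers' replicates per specimen.
    """
    observers = sorted(replicate_table["observer"].unique())
    rows = []
    for obs in observers:
        sub = replicate_table[replicate_table["observer"] == obs]
        wide = {rep: grp.set_index("specimen_id")
                for rep, grp in sub.groupby("rep")}
        for m in RATIO_NAMES:
            if len(wide) < 2:
                rows.append(_corr_row(f"Within {obs}", m, [], []))
                continue
            r1, r2 = (wide[k] for k in sorted(wide)[:2])
            common = r1.index.intersection(r2.index)
            x, y = r1.loc[common, m], r2.loc[common, m]
            mask = x.notna() & y.notna()
            rows.append(_corr_row(f"Within {obs}", m, x[mask], y[mask]))
    for a, b in itertools.combinations(observers, 2):
        sub = replicate_table[replicate_table["observer"].isin([a, b])]
        means = sub.groupby(["specimen_id", "observer"])[list(RATIO_NAMES)].mean()
        for m in RATIO_NAMES:
            wide = means[m].unstack("observer")
            mask = wide[a].notna() & wide[b].notna()
            rows.append(_corr_row(f"Between {a} vs {b}", m,
                                  wide.loc[mask, a], wide.loc[mask, b]))
        for m in RATIO_NAMES:
            sub_m = sub[["specimen_id", m]].dropna()
            try:
                res = sd_vs_mean(sub_m, m)
                rows.append({"comparison": f"SD vs mean ({a} vs {b})", "measurement": m,
                             "r": res.r, "t": res.t, "df": res.df, "p": res.p})
            except ValueError:
                rows.append({"comparison": f"SD vs mean ({a} vs {b})", "measurement": m,
                             "r": np.nan, "t": np.nan, "df": np.nan, "p": np.nan})
    return pd.DataFrame(rows)
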