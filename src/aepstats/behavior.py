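"""Behavioral 2AFC scoring: d' sensitivity, t-tests and brain-behavior
correlations.

A trial is a hit when an "mba" token (-20 ms voice-onset time) is labeled
"mba", and a correct rejection when a "ba" token (-10 ms VOT) is labeled
"ba".  Sensitivity is the equal-variance Gaussian d' = z(H) - z(FA) with
rates clamped to [1/(2N), 1 - 1/(2N)] so 0/1 proportions stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

__all__ = ["Counts", "score_identification", "dprime", "dprime_table",
           "paired_t", "independent_t", "correlate_dprime_p2"]


@dataclass(frozen=True)
class Counts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


def score_identification(log: pd.DataFrame) -> Counts:
    """Count hits / misses / false alarms / correct rejections from a trial
    log with ``stimulus`` and ``response`` columns in {mba, ba}."""
    valid = {"mba", "ba"}
    for col in ("stimulus", "response"):
        bad = ~log[col].isin(valid)
        if bad.any():
            i = int(log.index[bad][0])
            raise ValueError(
                f"malformed {col} at trial index {i}: {log.loc[i, col]!r}")
    signal = log["stimulus"] == "mba"
    said_mba = log["response"] == "mba"
    return Counts(hits=int((signal & said_mba).sum()),
                  misses=int((signal & ~said_mba).sum()),
                  false_alarms=int((~signal & said_mba).sum()),
                  correct_rejections=int((~signal & ~said_mba).sum()))


def dprime(counts: Counts, edge_correction: bool = True) -> float:
    """Equal-variance signal-detection sensitivity z(H) - z(FA)."""
    n_s, n_n = counts.n_signal, counts.n_noise
    if n_s == 0 or n_n == 0:
        raise ConfigError("need trials in both stimulus classes")
    h = counts.hits / n_s
    fa = counts.false_alarms / n_n
    if edge_correction:
        h = float(np.clip(h, 1 / (2 * n_s), 1 - 1 / (2 * n_s)))
        fa = float(np.clip(fa, 1 / (2 * n_n), 1 - 1 / (2 * n_n)))
    return float(stats.norm.ppf(h) - stats.norm.ppf(fa))


def dprime_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, group, session) d' from a study-level trial log."""
    rows = []
    for (subject, group, session), log in behavior.groupby(
            ["subject", "group", "session"], sort=True):
        c = score_identification(log)
        rows.append(dict(subject=subject, group=int(group),
                         session=int(session), hits=c.hits, misses=c.misses,
                         false_alarms=c.false_alarms,
                         correct_rejections=c.correct_rejections,
                         dprime=dprime(c)))
    return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray, tail: str = "two-sided") -> dict:
    """Paired t-test; tail in {'two-sided', 'greater', 'less'} refers to
    the mean of x - y.  Zero-variance differences are reported as a
    degenerate case rather than an infinite statistic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ConfigError("paired test needs two matched vectors, n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return dict(t=0.0, df=n - 1, p=1.0, tail=tail, degenerate=False)
        return dict(t=np.nan, df=n - 1, p=np.nan, tail=tail, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    if tail == "two-sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ConfigError(f"unknown tail {tail!r}")
    return dict(t=float(t), df=df, p=float(p), tail=tail, degenerate=False)


def independent_t(x: np.ndarray, y: np.ndarray,
                  tail: str = "two-sided") -> dict:
    """Two-sample pooled-variance t-test, df = n1 + n2 - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigError("need n >= 2 per group")
    res = stats.ttest_ind(x, y, equal_var=True,
                          alternative={"two-sided": "two-sided",
                                       "greater": "greater",
                                       "less": "less"}[tail])
    return dict(t=float(res.statistic), df=len(x) + len(y) - 2,
                p=float(res.pvalue), tail=tail, degenerate=False)


def correlate_dprime_p2(dp: pd.DataFrame, p2: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between per-subject d' and mean P2 amplitude
    (190-290 ms window) for every session pairing and location.

    dp: columns subject, session, dprime.
    p2: columns subject, session, location, amplitude.
    """
    rows = []
    for loc in sorted(p2["location"].unique()):
        p2_loc = p2[p2["location"] == loc]
        for s_dp in sorted(dp["session"].unique()):
            a = dp[dp["session"] == s_dp].set_index("subject")["dprime"]
            for s_p2 in sorted(p2_loc["session"].unique()):
                b = (p2_loc[p2_loc["session"] == s_p2]
                     .set_index("subject")["amplitude"])
                common = a.index.intersection(b.index)
                if len(common) < 3:
                    continue
                x, y = a[common].to_numpy(), b[common].to_numpy()
                if x.std() == 0 or y.std() == 0:
                    rows.append(dict(location=loc, dprime_session=s_dp,
                                     p2_session=s_p2, n=len(common),
                                     r=np.nan, p=np.nan, degenerate=True))
                    continue
                r, p = stats.pearsonr(x, y)
                rows.append(dict(location=loc, dprime_session=s_dp,
                                 p2_session=s_p2, n=len(common),
                                 r=float(r), p=float(p), degenerate=False))
    return pd.DataFrame(rows)
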