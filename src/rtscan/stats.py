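"""Cohort stratification by read-through burden and supporting statistics.

Samples are split into 'high' and 'low' read-through strata using a cutoff on
the number of genes called with read-through (default: more than 200 genes =
high). Survival of the two strata is compared with the Kaplan-Meier
product-limit estimator and the two-group log-rank test; categorical
contrasts (e.g. mutation-status labels vs stratum) use Fisher's exact test,
and metagene region comparisons use Student's t-test, paired across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank


@dataclass
class CohortStratification:
    cutoff_genes: int
    counts: dict[str, int]          # sample_id -> n_readthrough_genes
    assignments: dict[str, str]     # sample_id -> 'high' | 'low'

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(s, self.counts[s], self.assignments[s]) for s in sorted(self.counts)]
        return pd.DataFrame(rows, columns=["sample_id", "n_readthrough_genes", "stratum"])


def stratify_by_readthrough(counts: Mapping[str, int], cutoff_genes: int = 200) -> CohortStratification:
    """Assign 'high' to samples with strictly more than ``cutoff_genes`` read-through genes."""
    assignments = {s: ("high" if n > cutoff_genes else "low") for s, n in counts.items()}
    return CohortStratification(cutoff_genes, dict(counts), assignments)


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with time/event columns or a sequence of (time, event)."""
    if isinstance(records, pd.DataFrame):
        time = records["time_days" if "time_days" in records else "time"].to_numpy(float)
        event = records["event"].to_numpy()
    else:
        arr = np.asarray(list(records), dtype=float)
        if arr.size == 0:
            return np.zeros(0), np.zeros(0, dtype=bool)
        time, event = arr[:, 0], arr[:, 1]
    event = np.asarray(event).astype(bool)
    if np.any(time < 0):
        raise ValueError("survival times must be non-negative")
    return time.astype(float), event


def kaplan_meier(records) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival curve S(t) over the distinct observed times.

    ``records`` is a DataFrame with ``time``/``time_days`` and ``event``
    columns, or a sequence of (time, event) tuples. Returns (times, survival),
    with survival evaluated just after each time point; S starts at 1 at t=0.
    """
    time, event = _as_arrays(records)
    if time.size == 0:
        raise ValueError("kaplan_meier needs at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Ties are handled with the standard hypergeometric variance at tied event
    times. Undefined (raises) when neither group has any observed event.
    """
    ta, ea = _as_arrays(group_a)
    tb, eb = _as_arrays(group_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank undefined: no observed events in either group")
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table; p=1 when a margin is zero."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def region_ttest(test_values: Sequence[float], control_values: Sequence[float],
                 paired: bool = True) -> tuple[float, float]:
    """Student's t-test for metagene region means (paired across genes by default).

    Returns (t, p); (nan, nan) when the (difference) variance is zero, which is
    flagged with a warning by scipy.
    """
    x = np.asarray(test_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length vectors")
        if len(x) < 2:
            raise ValueError("need at least 2 observations")
        if np.all(x == y):
            return 0.0, 1.0  # identical vectors: no difference by convention
        res = sps.ttest_rel(x, y)
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need at least 2 observations per group")
        res = sps.ttest_ind(x, y)
    return float(res.statistic), float(res.pvalue)


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival table (sample_id, time_days, event[, stratum]) TSV."""
    df = pd.read_csv(path, sep="\t")
    df["event"] = df["event"].astype(int).astype(bool)
    return df


def survival_by_stratum(survival: pd.DataFrame,
                        stratification: CohortStratification) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = survival.copy()
    df["stratum"] = df["sample_id"].map(stratification.assignments)
    high = df[df["stratum"] == "high"]
    low = df[df["stratum"] == "low"]
    return high, low
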