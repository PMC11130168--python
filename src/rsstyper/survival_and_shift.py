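"""Survival analysis and pre/post-treatment subtype-shift tabulation.

Kaplan-Meier product-limit estimation and the k-group log-rank test are
implemented from their defining formulas since they are the package's
prognosis surface; the clinical-table conventions (stage imputation from TNM
fields, tied events processed before tied censorings) are made explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "TransitionTable",
    "impute_stage",
    "impute_stage_frame",
    "km_estimate",
    "logrank_test",
    "subtype_shift_table",
]

CLINICAL_COLUMNS = ["time_months", "event"]


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA


def impute_stage(record) -> object:
    """Overall stage with the N/M fallback rule.

    If the overall stage is recorded it is returned unchanged. Otherwise the
    patient is called stage 3 when the nodal stage is positive and there is no
    distant metastasis (N > 0 and M = 0); in every other case the stage stays
    missing.
    """
    stage = record.get("stage") if hasattr(record, "get") else record["stage"]
    if not _is_missing(stage):
        return stage
    n = record.get("N") if hasattr(record, "get") else record["N"]
    m = record.get("M") if hasattr(record, "get") else record["M"]
    if not _is_missing(n) and not _is_missing(m) and n > 0 and m == 0:
        return 3
    return pd.NA


def impute_stage_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorised stage imputation over a clinical table."""
    return pd.Series(
        [impute_stage(row) for _, row in df.iterrows()], index=df.index, name="stage"
    )


def _check_records(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if len(time) == 0:
        raise ValueError("need at least 1 record")
    if (time <= 0).any() or not np.isfinite(time).all():
        raise ValueError("survival times must be positive and finite")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return time, event.astype(int)


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i with
    d_i events among n_i at risk. Subjects censored exactly at an event time
    stay at risk for that time (events are processed first). Returns one row
    per distinct event time: time, n_at_risk, n_events, survival.
    """
    time, event = _check_records(time, event)
    rows = []
    surv = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append({"time": t, "n_at_risk": at_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(time, event, group) -> dict:
    """k-group log-rank test.

    At every distinct event time the observed events per group are compared
    with their expectation under the multivariate hypergeometric law; the
    statistic (O - E)' V^{-1} (O - E) over the first k - 1 groups is referred
    to chi-square with k - 1 degrees of freedom. Returns statistic, df and p.
    """
    time, event = _check_records(time, event)
    group = np.asarray(group)
    levels = np.array(sorted(pd.unique(group)))
    k = len(levels)
    if k < 2:
        raise ValueError("log-rank needs at least 2 groups")
    for lv in levels:
        if (group == lv).sum() == 0:
            raise ValueError(f"group {lv} has no subjects")
    if event.sum() == 0:
        raise ValueError("log-rank needs at least 1 event")

    member = group[:, None] == levels[None, :]  # n x k
    o_minus_e = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_g = member[at_risk].sum(axis=0).astype(float)
        d = float(((time == t) & (event == 1)).sum())
        d_g = member[(time == t) & (event == 1)].sum(axis=0).astype(float)
        e_g = n_g * d / n
        o_minus_e += d_g - e_g
        if n > 1:
            scale = d * (n - d) / (n - 1) / n**2
            V += scale * (np.diag(n_g * n) - np.outer(n_g, n_g))

    z = o_minus_e[: k - 1]
    v = V[: k - 1, : k - 1]
    stat = float(z @ np.linalg.pinv(v) @ z) if np.any(z) else 0.0
    stat = max(stat, 0.0)
    return {
        "statistic": stat,
        "df": k - 1,
        "p": float(chi2.sf(stat, k - 1)),
        "groups": levels.tolist(),
    }


@dataclass
class TransitionTable:
    """Pre-subtype x post-subtype pair counts with post-subtype fractions."""

    counts: pd.DataFrame
    post_fraction: pd.Series

    @property
    def n_pairs(self) -> int:
        return int(self.counts.to_numpy().sum())


def subtype_shift_table(
    pre_labels: pd.Series, post_labels: pd.Series, pairs: dict[str, str]
) -> TransitionTable:
    """Tabulate subtype transitions across matched pre/post sample pairs.

    ``pairs`` maps pre-sample id to post-sample id; both sides must carry a
    label. Returns the pre x post count matrix and the fraction of pairs
    landing in each post subtype.
    """
    pre_labels = pd.Series(pre_labels)
    post_labels = pd.Series(post_labels)
    for pre_id, post_id in pairs.items():
        if pre_id not in pre_labels.index:
            raise ValueError(f"unpaired or unlabelled pre sample: {pre_id}")
        if post_id not in post_labels.index:
            raise ValueError(f"unpaired or unlabelled post sample: {post_id}")

    levels = sorted(
        set(pre_labels.loc[list(pairs)].unique())
        | set(post_labels.loc[list(pairs.values())].unique())
    )
    counts = pd.DataFrame(0, index=levels, columns=levels, dtype=int)
    for pre_id, post_id in pairs.items():
        counts.loc[pre_labels[pre_id], post_labels[post_id]] += 1
    total = counts.to_numpy().sum()
    post_fraction = (
        counts.sum(axis=0) / total if total else counts.sum(axis=0).astype(float)
    )
    counts.index.name = "pre"
    counts.columns.name = "post"
    return TransitionTable(counts=counts, post_fraction=post_fraction.rename("fraction"))
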