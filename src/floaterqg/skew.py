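"""Reproductive-skew descriptors for annual reproductive success (ARS).

Per mating-behaviour class (all / territorial / floater) this module
computes the distribution descriptors of per-season fledgling counts and
two skew statistics:

* the opportunity for selection ``I = Var(ARS) / mean(ARS)^2`` — the
  variance in relative fitness, an upper bound on the strength of
  selection (Crow's index);
* Morisita's index ``I_delta = N * sum x(x-1) / (X (X-1))`` with
  ``X = sum x`` — 1 for a random (Poisson-like) allocation of offspring
  over observations, up to N when one observation holds all offspring.

Moments use the population (divide-by-N) denominator by default, under
which the moment-based reconstruction of Morisita's index is an exact
algebraic identity with the count-based form.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SkewSummary",
    "describe_ars",
    "opportunity_for_selection",
    "morisita_index",
    "morisita_from_moments",
    "pooled_moments",
    "skew_table",
]


@dataclass
class SkewSummary:
    """One row of a Table-3-style per-class ARS summary."""

    class_label: str
    obs: int
    n_males: int
    median: float
    q1: float
    q3: float
    prop_zeros: float
    mean: float
    var: float
    opportunity: float
    morisita: float

    def as_dict(self) -> dict:
        return asdict(self)


def opportunity_for_selection(mean: float, var: float) -> float:
    """Standardized variance in reproductive success, I = Var / mean^2."""
    if mean <= 0:
        raise ValueError("opportunity for selection undefined for mean <= 0")
    if var < 0:
        raise ValueError("variance must be non-negative")
    return var / mean**2


def morisita_index(counts: Sequence[int]) -> float:
    """Morisita's dispersion index from raw per-observation counts."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two observations")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total < 2:
        raise ValueError("Morisita's index undefined for total count < 2")
    n = x.size
    return n * float((x * (x - 1.0)).sum()) / (total * (total - 1.0))


def morisita_from_moments(n: int, mean: float, var: float) -> float:
    """Morisita's index reconstructed from (N, mean, variance).

    Uses ``sum x^2 = N (var + mean^2)`` (divide-by-N variance) and
    ``X = N mean``; exactly equals :func:`morisita_index` on the counts
    the moments came from.  Useful for auditing published summary rows.
    """
    if n < 2:
        raise ValueError("need at least two observations")
    if mean <= 0:
        raise ValueError("Morisita reconstruction undefined for mean <= 0")
    total = n * mean
    if total < 2:
        raise ValueError("Morisita's index undefined for total count < 2")
    sum_x_xm1 = n * (var + mean**2) - total
    return n * sum_x_xm1 / (total * (total - 1.0))


def describe_ars(
    counts: Sequence[int],
    class_label: str = "all",
    male_ids: Sequence[str] | None = None,
    *,
    ddof: int = 0,
) -> SkewSummary:
    """Summarize one class of per-observation ARS counts.

    Quartiles use linear interpolation (numpy's default, R type 7);
    ``ddof=0`` gives the population variance under which the skew
    statistics are mutually consistent (``ddof=1`` available for the
    sample-variance convention).
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty ARS vector")
    if np.any(x < 0) or np.any(x != np.round(x)):
        raise ValueError("ARS counts must be non-negative integers")
    n = int(x.size)
    mean = float(x.mean())
    var = float(x.var(ddof=ddof)) if n > ddof else 0.0
    q1, med, q3 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    opp = opportunity_for_selection(mean, var) if mean > 0 else (0.0 if var == 0 else np.nan)
    mor = morisita_index(x) if x.sum() >= 2 else np.nan
    n_males = len(set(male_ids)) if male_ids is not None else n
    return SkewSummary(
        class_label=class_label,
        obs=n,
        n_males=n_males,
        median=med,
        q1=q1,
        q3=q3,
        prop_zeros=float((x == 0).mean()),
        mean=mean,
        var=var,
        opportunity=opp,
        morisita=mor,
    )


def pooled_moments(
    ns: Sequence[int], means: Sequence[float], variances: Sequence[float]
) -> tuple[int, float, float]:
    """Combine per-class (N, mean, variance) into pooled moments.

    Uses the exact weighted-moment identity under the divide-by-N
    variance convention: the pooled mean is the weighted mean and the
    pooled variance adds the between-class spread.  Lets published
    per-class summary rows be checked against their pooled row.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if ns.size == 0 or np.any(ns <= 0):
        raise ValueError("class sizes must be positive")
    n = ns.sum()
    mean = float((ns * means).sum() / n)
    var = float((ns * (variances + (means - mean) ** 2)).sum() / n)
    return int(n), mean, var


def skew_table(
    records: pd.DataFrame,
    *,
    response: str = "ars",
    class_column: str = "status",
    id_column: str = "male_id",
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-class and pooled ARS summaries as a Table-3-shaped frame.

    ``records`` is a male-season phenotype table with one row per
    (male, season).  Rows: all, then each class in sorted order.
    """
    if records.empty:
        raise ValueError("empty phenotype table")
    rows = [
        describe_ars(
            records[response].to_numpy(),
            "all",
            records[id_column].to_numpy(),
            ddof=ddof,
        )
    ]
    for label in sorted(records[class_column].unique(), reverse=True):
        sub = records[records[class_column] == label]
        rows.append(
            describe_ars(sub[response].to_numpy(), str(label), sub[id_column].to_numpy(), ddof=ddof)
        )
    df = pd.DataFrame([r.as_dict() for r in rows])
    df["iqr"] = df.apply(lambda r: f"{r.q1:g}-{r.q3:g}", axis=1)
    cols = [
        "class_label", "obs", "n_males", "median", "iqr", "prop_zeros",
        "mean", "var", "opportunity", "morisita",
    ]
    return df[cols]
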