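"""MQTL x trait binary incidence matrix and co-localization statistics.

The presence matrix scores each consolidated locus 0/1 for every trait with
at least one member QTL of that trait.  Co-localization of a trait with a
target trait is the percentage of the target's MQTLs that also carry the
trait, truncated (not rounded) to an integer.  The association test is the
published single-cell construction: the expected number of doubly-positive
MQTLs is ``n_trait * (n_target / N)`` and the statistic
``(n_both - expected)^2 / expected`` is referred to chi-squared with 1 df.
A standard 2x2 contingency chi-squared is exposed separately as a
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .meta_analysis import MetaQtl

__all__ = [
    "build_presence_matrix",
    "colocalization_frequency",
    "ColocalizationResult",
    "chi2_association",
    "chi2_contingency_2x2",
    "ols_r2_percent",
    "regression_coloc",
    "colocalization_report",
]

#: the four target traits of the co-localization analysis
TARGET_TRAITS = ("GPC", "GZnC", "GFeC", "GY")


def build_presence_matrix(mqtls: Sequence[MetaQtl]) -> pd.DataFrame:
    """Binary incidence DataFrame: rows = MQTL names, columns = trait codes.

    Column sums are the per-trait MQTL counts.  Duplicate MQTL names raise;
    every row has at least one positive cell (an MQTL always carries the
    traits of its members).
    """
    names = [m.name for m in mqtls]
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate MQTL names in input")
    traits = sorted({t for m in mqtls for t in m.traits})
    data = np.zeros((len(mqtls), len(traits)), dtype=int)
    col = {t: j for j, t in enumerate(traits)}
    for i, m in enumerate(mqtls):
        for t in m.traits:
            data[i, col[t]] = 1
    return pd.DataFrame(data, index=names, columns=traits)


def _column(matrix: pd.DataFrame, trait: str) -> pd.Series:
    if trait not in matrix.columns:
        raise InvalidInputError(f"trait {trait!r} absent from the matrix")
    return matrix[trait]


def colocalization_frequency(matrix: pd.DataFrame, trait: str, target: str) -> int:
    """Integer percent of the target trait's MQTLs that also carry ``trait``.

    ``100 * n_both / n_target`` truncated toward zero; the denominator is
    the *target* (second-named) trait's column sum.
    """
    a = _column(matrix, trait)
    b = _column(matrix, target)
    n_target = int(b.sum())
    if n_target == 0:
        raise InvalidInputError(f"target {target!r} has no MQTLs: frequency undefined")
    n_both = int((a & b).sum())
    return int(100 * n_both / n_target)


@dataclass(frozen=True)
class ColocalizationResult:
    trait: str
    target: str
    n_trait: int
    n_target: int
    n_both: int
    frequency_percent: int
    expected_both: float
    chi2: float
    df: int = 1
    more_than_expected: bool = False


def chi2_association(matrix: pd.DataFrame, trait: str, target: str) -> ColocalizationResult:
    """Single-cell 1-df chi-squared of observed vs expected co-localizations.

    ``expected = n_trait * n_target / N``; an expected of zero is reported
    as not applicable (chi2 = NaN).
    """
    a = _column(matrix, trait)
    b = _column(matrix, target)
    n = len(matrix)
    if n == 0:
        raise InvalidInputError("empty matrix")
    n_trait = int(a.sum())
    n_target = int(b.sum())
    n_both = int((a & b).sum())
    expected = n_trait * (n_target / n)
    chi2 = float("nan") if expected == 0 else (n_both - expected) ** 2 / expected
    freq = int(100 * n_both / n_target) if n_target else 0
    return ColocalizationResult(
        trait=trait,
        target=target,
        n_trait=n_trait,
        n_target=n_target,
        n_both=n_both,
        frequency_percent=freq,
        expected_both=float(expected),
        chi2=float(chi2),
        more_than_expected=bool(n_both > expected),
    )


def chi2_contingency_2x2(matrix: pd.DataFrame, trait: str, target: str) -> dict[str, float]:
    """Orthodox 2x2 independence chi-squared (no continuity correction);
    diagnostic companion to :func:`chi2_association`."""
    a = _column(matrix, trait).to_numpy(bool)
    b = _column(matrix, target).to_numpy(bool)
    table = np.array(
        [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ]
    )
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return {"statistic": float(stat), "df": int(df), "p_value": float(p)}


def ols_r2_percent(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Simple OLS of ``y`` on ``x``; R^2 reported as a percentage.

    A constant response has R^2 = 0 by convention; a constant predictor is
    an error (the slope is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise InvalidInputError("need >= 3 paired points")
    if np.std(x) == 0:
        raise InvalidInputError("zero variance in predictor: regression undefined")
    if np.std(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "r2_percent": 0.0, "n": int(x.size)}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2_percent": float(res.rvalue**2 * 100.0),
        "n": int(x.size),
    }


def regression_coloc(matrix: pd.DataFrame, target: str) -> dict[str, float]:
    """OLS of per-trait co-localization frequency on per-trait MQTL count.

    One point per non-target trait with a defined frequency against
    ``target``; returns slope, intercept and R^2 as a percentage.
    """
    xs, ys = [], []
    for trait in matrix.columns:
        if trait == target:
            continue
        try:
            freq = colocalization_frequency(matrix, trait, target)
        except InvalidInputError:
            continue
        xs.append(int(matrix[trait].sum()))
        ys.append(freq)
    if len(xs) < 3:
        raise InvalidInputError("need >= 3 traits with defined frequencies")
    return ols_r2_percent(xs, ys)


def colocalization_report(
    matrix: pd.DataFrame, targets: Sequence[str] = TARGET_TRAITS
) -> pd.DataFrame:
    """All trait x target association rows in one table."""
    rows = []
    for target in targets:
        if target not in matrix.columns:
            continue
        for trait in matrix.columns:
            if trait == target:
                continue
            r = chi2_association(matrix, trait, target)
            rows.append(
                {
                    "trait": r.trait,
                    "target": r.target,
                    "n_trait": r.n_trait,
                    "n_target": r.n_target,
                    "n_both": r.n_both,
                    "freq_pct": r.frequency_percent,
                    "expected": r.expected_both,
                    "chi2": r.chi2,
                    "flag": "more_than_expected" if r.more_than_expected else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trait", "target", "n_trait", "n_target", "n_both",
            "freq_pct", "expected", "chi2", "flag",
        ],
    )
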