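"""The directional test: mean property change and a two-tailed one-sample t.

Each replacement contributes one signed delta ``X_i`` under a chosen scale;
the test asks whether the mean delta differs from zero (H0: mu = 0).  With
``n`` deltas, ``t = mean / (sd / sqrt(n))`` where ``sd`` uses the ``n - 1``
denominator, and the two-tailed p comes from the exact Student-t
distribution with ``n - 1`` degrees of freedom.

The two-tailed p is invariant under the sign convention; ``t``, ``mean`` and
``net_change`` negate with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .property_table import TO_MINUS_FROM, PropertyLibrary, PropertyScale, delta
from .replacement_io import ReplacementList

__all__ = [
    "DeltaVector",
    "DirectionalTestResult",
    "deltas_for",
    "t_test",
    "run_panel",
    "MIN_N_ADVISORY",
]

#: Results with fewer replacements than this carry a low-power warning flag.
MIN_N_ADVISORY = 5


@dataclass(frozen=True)
class DeltaVector:
    """Ordered signed property changes, one per replacement, under one scale."""

    values: tuple[float, ...]
    scale_symbol: str
    convention: str = TO_MINUS_FROM

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("delta vector must contain at least one value")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("delta vector contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DirectionalTestResult:
    """One (property, replacement set) cell of the directional analysis.

    ``direction`` is ``"increase"``/``"decrease"`` when the two-tailed p
    clears ``alpha`` with a nonzero mean, else ``"none"``.  ``degenerate``
    marks n = 1 or zero-variance inputs, where the t statistic is not
    informative.  ``p_adjusted`` is filled only by :func:`run_panel` when
    multiple-testing adjustment is requested.
    """

    scale_symbol: str
    n: int
    mean: float
    sd: float
    se: float
    t: float
    df: int
    p_two_tailed: float
    net_change: float
    direction: str
    degenerate: bool = False
    low_power: bool = False
    convention: str = TO_MINUS_FROM
    p_adjusted: float | None = None


def deltas_for(
    replacements: ReplacementList,
    scale: PropertyScale,
    convention: str = TO_MINUS_FROM,
) -> DeltaVector:
    """Delta vector for a replacement list under one scale, order preserved."""
    if len(replacements) == 0:
        raise ValueError("empty replacement list: no deltas to compute")
    values = tuple(delta(scale, r.from_res, r.to_res, convention) for r in replacements)
    return DeltaVector(values, scale.symbol, convention)


def t_test(deltas: DeltaVector, alpha: float = 0.05) -> DirectionalTestResult:
    """Two-tailed one-sample t-test of H0: mean delta = 0.

    Degenerate inputs are flagged rather than rejected: with n = 1 the p is
    NaN; with zero variance the p is 1 (mean = 0) or 0 (mean != 0).
    """
    x = np.asarray(deltas.values, dtype=float)
    n = x.size
    mean = float(x.mean())
    net = float(x.sum())
    if n == 1:
        return DirectionalTestResult(
            deltas.scale_symbol, 1, mean, float("nan"), float("nan"),
            float("nan"), 0, float("nan"), net, "none",
            degenerate=True, low_power=True, convention=deltas.convention,
        )
    sd = float(x.std(ddof=1))
    se = sd / math.sqrt(n)
    df = n - 1
    if se == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
        degenerate = True
    else:
        t = mean / se
        p = 2.0 * float(_stats.t.sf(abs(t), df))
        degenerate = False
    if p < alpha and mean != 0.0:
        direction = "increase" if mean > 0 else "decrease"
    else:
        direction = "none"
    return DirectionalTestResult(
        deltas.scale_symbol, n, mean, sd, se, t, df, p, net, direction,
        degenerate=degenerate, low_power=n < MIN_N_ADVISORY,
        convention=deltas.convention,
    )


def run_panel(
    replacements: ReplacementList,
    library: PropertyLibrary,
    convention: str = TO_MINUS_FROM,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[DirectionalTestResult]:
    """Run the test once per scale in library order.

    Per-scale failures (e.g. an empty replacement list) propagate as
    exceptions before any test runs; scales never silently vanish from the
    output.  With ``adjust=True`` a Benjamini-Hochberg adjusted p column is
    appended to every non-degenerate result; raw p-values are untouched.
    """
    results = [
        t_test(deltas_for(replacements, scale, convention), alpha=alpha)
        for scale in library
    ]
    if adjust:
        idx = [i for i, r in enumerate(results) if not math.isnan(r.p_two_tailed)]
        if idx:
            adj = _stats.false_discovery_control(
                np.array([results[i].p_two_tailed for i in idx]), method="bh"
            )
            for i, q in zip(idx, adj):
                results[i] = replace(results[i], p_adjusted=float(q))
    return results


def t_test_from_values(
    values: Sequence[float],
    scale_symbol: str = "",
    convention: str = TO_MINUS_FROM,
    alpha: float = 0.05,
) -> DirectionalTestResult:
    """Convenience wrapper: run :func:`t_test` on raw delta values."""
    return t_test(DeltaVector(tuple(float(v) for v in values), scale_symbol, convention), alpha)
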