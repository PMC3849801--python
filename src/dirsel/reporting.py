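"""Render property-by-partition result matrices and per-pair reports.

The text grid uses a signed significance notation: one symbol per
significance tier met, ``+`` for a positive mean change and ``-`` for a
negative one, so ``++`` reads "increase, p below the second tier".  Default
tiers are p < 0.1 / 0.05 / 0.01.  Rendering is pure: the same results always
produce byte-identical documents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .directional_test import DirectionalTestResult, deltas_for
from .property_table import PropertyLibrary, PropertyScale, TO_MINUS_FROM
from .replacement_io import ReplacementList

__all__ = [
    "DEFAULT_TIERS",
    "SignificanceCell",
    "symbolize",
    "matrix_report",
    "pair_report",
    "NUMERIC_FIELDS",
]

#: Default significance tiers, strictly decreasing.
DEFAULT_TIERS = (0.1, 0.05, 0.01)

#: Numeric result fields carried by TSV and JSON outputs, in column order.
NUMERIC_FIELDS = ("n", "mean", "sd", "se", "t", "df", "p_two_tailed", "net_change")


@dataclass(frozen=True)
class SignificanceCell:
    """One rendered cell: symbol string, p, and the sign of the mean change."""

    symbol_string: str
    p: float
    direction: int  # sign of the mean delta: -1, 0, +1


def _check_tiers(tiers: Sequence[float]) -> None:
    if not tiers or list(tiers) != sorted(tiers, reverse=True) or len(set(tiers)) != len(tiers):
        raise ValueError(f"tiers must be strictly decreasing, got {tiers!r}")


def symbolize(
    result: DirectionalTestResult,
    tiers: Sequence[float] = DEFAULT_TIERS,
) -> SignificanceCell:
    """Map a test result to its signed symbol string under the given tiers.

    ``k`` symbols where k is the number of tiers the p-value clears; empty
    when p is at or above the loosest tier.  Degenerate results render as
    ``NA``.
    """
    _check_tiers(tiers)
    if result.degenerate or math.isnan(result.p_two_tailed):
        reason = "n=1" if result.n == 1 else "zero variance"
        return SignificanceCell(f"NA ({reason})", result.p_two_tailed, _sign(result.mean))
    k = sum(result.p_two_tailed < tier for tier in tiers)
    sign = _sign(result.mean)
    glyph = "+" if sign > 0 else "-"
    return SignificanceCell(glyph * k if sign != 0 else "", result.p_two_tailed, sign)


def _sign(x: float) -> int:
    if math.isnan(x) or x == 0:
        return 0
    return 1 if x > 0 else -1


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, int):
        return str(x)
    if math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return format(x, ".12g")


def _result_record(scale: PropertyScale, res: DirectionalTestResult) -> dict:
    rec = {
        "symbol": scale.symbol,
        "name": scale.name,
        "category": scale.category,
        "n": res.n,
        "mean": res.mean,
        "sd": res.sd,
        "se": res.se,
        "t": res.t,
        "df": res.df,
        "p_two_tailed": res.p_two_tailed,
        "net_change": res.net_change,
        "direction": res.direction,
        "degenerate": res.degenerate,
        "low_power": res.low_power,
    }
    if res.p_adjusted is not None:
        rec["p_adjusted"] = res.p_adjusted
    return rec


def matrix_report(
    results: Mapping[str, Sequence[DirectionalTestResult]],
    library: PropertyLibrary,
    fmt: str = "tsv",
    tiers: Sequence[float] = DEFAULT_TIERS,
) -> str:
    """Render results keyed by partition name into one document.

    Rows follow library order grouped by category; partitions appear in the
    mapping's order.  ``tsv`` and ``json`` carry the full numeric fields,
    ``grid`` carries the signed symbol strings.
    """
    partitions = list(results)
    by_part: dict[str, dict[str, DirectionalTestResult]] = {
        pname: {r.scale_symbol: r for r in rs} for pname, rs in results.items()
    }
    if fmt == "tsv":
        has_adj = any(
            r.p_adjusted is not None for rs in results.values() for r in rs
        )
        cols = ["category", "symbol", "name", "partition", *NUMERIC_FIELDS, "direction"]
        if has_adj:
            cols.insert(cols.index("net_change"), "p_adjusted")
        lines = ["\t".join(cols)]
        for scale in library:
            for pname in partitions:
                res = by_part[pname].get(scale.symbol)
                if res is None:
                    continue
                rec = _result_record(scale, res)
                rec["partition"] = pname
                rec.setdefault("p_adjusted", None)
                lines.append("\t".join(_fmt(rec[c]) if c in NUMERIC_FIELDS or c == "p_adjusted"
                                        else str(rec[c]) for c in cols))
        return "\n".join(lines) + "\n"
    if fmt == "json":
        records = []
        for pname in partitions:
            for r in results[pname]:
                if r.scale_symbol not in library:
                    continue
                rec = _result_record(library[r.scale_symbol], r)
                rec["partition"] = pname
                # 12 significant digits, matching the TSV rendering
                for k in (*NUMERIC_FIELDS, "p_adjusted"):
                    if k in rec:
                        rec[k] = _json_num(rec[k])
                records.append(rec)
        doc = {"partitions": partitions, "results": records}
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if fmt == "grid":
        width = max([len("Property"), *(len(s.symbol) for s in library)]) + 2
        cell_w = max([10, *(len(p) + 2 for p in partitions)])
        header = "Property".ljust(width) + "".join(p.ljust(cell_w) for p in partitions)
        lines = [header, "-" * len(header)]
        current_cat = None
        for scale in library:
            if scale.category != current_cat:
                current_cat = scale.category
                lines.append(f"[{current_cat}]")
            row = scale.symbol.ljust(width)
            for pname in partitions:
                res = by_part[pname].get(scale.symbol)
                cell = symbolize(res, tiers).symbol_string if res is not None else ""
                row += cell.ljust(cell_w)
            lines.append(row.rstrip())
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}; use tsv, json, or grid")


def _json_num(x):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    if isinstance(x, float) and math.isinf(x):
        return "inf" if x > 0 else "-inf"
    if isinstance(x, int):
        return x
    return float(format(x, ".12g"))


def pair_report(
    replacements: ReplacementList,
    scale: PropertyScale,
    convention: str = TO_MINUS_FROM,
) -> str:
    """Per-replacement delta listing for one scale, with a net-change footer."""
    dv = deltas_for(replacements, scale, convention)
    lines = [f"site\tfrom\tto\tdelta_{scale.symbol}"]
    for r, x in zip(replacements, dv.values):
        lines.append(f"{r.site}\t{r.from_res}\t{r.to_res}\t{x:+.1f}")
    lines.append(f"Net Change =\t\t\t{sum(dv.values):+.1f}")
    return "\n".join(lines) + "\n"
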