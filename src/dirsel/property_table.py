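"""Quantitative amino-acid property scales and signed per-replacement deltas.

A :class:`PropertyScale` maps each of the 20 standard amino acids to a real
number quantifying one physicochemical attribute (hydropathy, polarity,
buriedness, ...).  The built-in :func:`builtin_library` panel holds 25
representative scales spanning eight categories; further scales can be read
from AAindex1 flat files with :func:`load_aaindex`.

The observation unit of the directional test is the signed *delta* of a scale
across one amino-acid replacement, computed by :func:`delta`.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "AA_ORDER",
    "STANDARD_AA",
    "CATEGORIES",
    "TO_MINUS_FROM",
    "FROM_MINUS_TO",
    "PropertyScale",
    "PropertyLibrary",
    "AAindexParseError",
    "NonStandardResidueError",
    "builtin_library",
    "delta",
    "load_aaindex",
    "write_aaindex",
    "library_to_tsv",
    "library_from_tsv",
]

#: Canonical AAindex residue order for the two 10-value rows of an entry.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset(AA_ORDER)

#: Closed vocabulary of scale categories used by the built-in panel.
CATEGORIES = (
    "Hydrophobicity",
    "Ionization Constants",
    "Molecular Size & Composition",
    "Non-bonded Energy",
    "Polarity & Polarizability",
    "Secondary Structure",
    "Solvent Accessibility",
    "Tertiary Structure",
)

#: Sign conventions for :func:`delta`.  ``to_minus_from`` is the default:
#: value of the derived residue minus value of the ancestral residue.
TO_MINUS_FROM = "to_minus_from"
FROM_MINUS_TO = "from_minus_to"
_CONVENTIONS = (TO_MINUS_FROM, FROM_MINUS_TO)


class AAindexParseError(ValueError):
    """Malformed AAindex1 record; carries the entry id and line number."""

    def __init__(self, message: str, record_id: str = "?", line: int | None = None):
        self.record_id = record_id
        self.line = line
        where = f" (record {record_id}" + (f", line {line})" if line else ")")
        super().__init__(message + where)


class NonStandardResidueError(ValueError):
    """A residue outside the 20 standard amino acids was passed to ``delta``."""


@dataclass(frozen=True)
class PropertyScale:
    """One named quantitative scale over the 20 standard amino acids.

    Parameters
    ----------
    symbol : str
        Short unique identifier (e.g. ``"h"``, ``"Hp"``, ``"pK'"``).
    name : str
        Full property name.
    category : str
        One of the eight panel categories (see :data:`CATEGORIES`); free
        text is accepted for externally loaded scales.
    unit : str
        Unit string, may be empty for dimensionless scales.
    values : Mapping[str, float]
        Total map from one-letter codes to finite reals; exactly 20 keys.
    source : str
        Citation or database-entry identifier the values were taken from.
    """

    symbol: str
    name: str
    category: str
    unit: str
    values: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != STANDARD_AA:
            missing = sorted(STANDARD_AA - keys)
            extra = sorted(keys - STANDARD_AA)
            raise ValueError(
                f"scale {self.symbol!r} must map exactly the 20 standard "
                f"amino acids (missing {missing}, unexpected {extra})"
            )
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"scale {self.symbol!r} has non-finite value for {aa}")

    def value(self, residue: str) -> float:
        """Scale value for a standard one-letter residue code."""
        try:
            return self.values[residue]
        except KeyError:
            raise NonStandardResidueError(
                f"{residue!r} is not a standard amino acid; filter replacements "
                "containing gaps or ambiguity codes before computing deltas"
            ) from None


class PropertyLibrary:
    """An ordered collection of :class:`PropertyScale` with unique symbols."""

    def __init__(self, scales: Iterable[PropertyScale]):
        self._scales = list(scales)
        self._by_symbol: dict[str, PropertyScale] = {}
        for s in self._scales:
            if s.symbol in self._by_symbol:
                raise ValueError(f"duplicate scale symbol {s.symbol!r}")
            self._by_symbol[s.symbol] = s

    def __iter__(self) -> Iterator[PropertyScale]:
        return iter(self._scales)

    def __len__(self) -> int:
        return len(self._scales)

    def __getitem__(self, symbol: str) -> PropertyScale:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            known = ", ".join(self.symbols())
            raise KeyError(f"unknown property symbol {symbol!r}; known: {known}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def symbols(self) -> list[str]:
        return [s.symbol for s in self._scales]

    def subset(self, symbols: Iterable[str]) -> "PropertyLibrary":
        return PropertyLibrary(self[sym] for sym in symbols)


def delta(
    scale: PropertyScale,
    from_res: str,
    to_res: str,
    convention: str = TO_MINUS_FROM,
) -> float:
    """Signed property change implied by one ``from_res -> to_res`` replacement.

    Under ``to_minus_from`` (default) the delta is
    ``value(to_res) - value(from_res)``, i.e. derived minus ancestral; under
    ``from_minus_to`` the global sign flips.  Antisymmetric in its residue
    arguments under either convention.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")
    d = scale.value(to_res) - scale.value(from_res)
    return -d if convention == FROM_MINUS_TO else d


# ---------------------------------------------------------------------------
# Built-in panel

_builtin_cache: PropertyLibrary | None = None


def builtin_library() -> PropertyLibrary:
    """The built-in panel of 25 representative scales (8 categories).

    Values are sourced from the AAindex entries recorded in each scale's
    ``source`` field; entries marked ``(proxy)`` stand in for cited scales
    absent from AAindex.  The hydropathy scale ``h`` (Kyte-Doolittle) is the
    reference scale used by the worked-example fixtures.
    """
    global _builtin_cache
    if _builtin_cache is None:
        text = resources.files("dirsel.data").joinpath("builtin_scales.tsv").read_text()
        _builtin_cache = library_from_tsv(io.StringIO(text))
    return _builtin_cache


def library_from_tsv(stream: IO[str]) -> PropertyLibrary:
    """Read a library from the TSV export format (see :func:`library_to_tsv`)."""
    header = stream.readline().rstrip("\n").split("\t")
    expected = ["symbol", "name", "category", "unit", "source", *AA_ORDER]
    if header != expected:
        raise ValueError(f"bad library TSV header: {header[:6]}...")
    scales = []
    for line in stream:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sym, name, cat, unit, source = parts[:5]
        vals = dict(zip(AA_ORDER, map(float, parts[5:])))
        scales.append(PropertyScale(sym, name, cat, unit, vals, source))
    return PropertyLibrary(scales)


def library_to_tsv(library: PropertyLibrary, stream: IO[str]) -> None:
    """Write a library as TSV: symbol, name, category, unit, source, 20 values."""
    stream.write("\t".join(["symbol", "name", "category", "unit", "source", *AA_ORDER]) + "\n")
    for s in library:
        vals = "\t".join(format(s.values[aa], "g") for aa in AA_ORDER)
        stream.write(f"{s.symbol}\t{s.name}\t{s.category}\t{s.unit}\t{s.source}\t{vals}\n")


# ---------------------------------------------------------------------------
# AAindex1 flat-file format


def load_aaindex(stream: IO[str], category: str = "AAindex") -> PropertyLibrary:
    """Parse AAindex1 flat-file records into a :class:`PropertyLibrary`.

    Each record contributes one scale keyed by its ``H`` accession.  Records
    with any ``NA`` amino-acid value are skipped with a warning, as the
    directional test needs a total map over the 20 standard residues.

    Raises
    ------
    AAindexParseError
        On malformed records, naming the offending record and line.
    """
    scales: list[PropertyScale] = []
    rec_id = "?"
    desc = ""
    in_values = False
    value_rows: list[list[str]] = []
    lineno = 0

    def finish(at_line: int) -> None:
        nonlocal rec_id, desc, in_values, value_rows
        if rec_id == "?":
            return
        tokens = [t for row in value_rows for t in row]
        if len(tokens) != 20:
            raise AAindexParseError(
                f"expected 20 amino-acid values, found {len(tokens)}", rec_id, at_line
            )
        if any(t.upper() in ("NA", "NA.") for t in tokens):
            warnings.warn(
                f"AAindex record {rec_id} has missing (NA) values; skipped",
                stacklevel=3,
            )
        else:
            try:
                values = dict(zip(AA_ORDER, map(float, tokens)))
            except ValueError as exc:
                raise AAindexParseError(f"non-numeric value: {exc}", rec_id, at_line) from exc
            scales.append(
                PropertyScale(rec_id, desc or rec_id, category, "", values, f"AAindex:{rec_id}")
            )
        rec_id, desc, in_values, value_rows = "?", "", False, []

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("//"):
            finish(lineno)
            continue
        tag, _, rest = line.partition(" ")
        if line[:1] not in (" ", ""):
            in_values = tag == "I"
        if tag == "H":
            if rec_id != "?":
                raise AAindexParseError("record not terminated by //", rec_id, lineno)
            rec_id = rest.strip()
            if not rec_id:
                raise AAindexParseError("empty H (accession) line", "?", lineno)
        elif tag == "D":
            desc = rest.strip()
        elif tag == "I":
            # Header row "A/L R/K ..." — data follow on continuation lines.
            value_rows = []
        elif line.startswith(" ") and in_values:
            value_rows.append(line.split())
    if rec_id != "?":
        raise AAindexParseError("unterminated final record", rec_id, lineno)
    return PropertyLibrary(scales)


def write_aaindex(library: PropertyLibrary, stream: IO[str]) -> None:
    """Write scales as minimal AAindex1 records (H/D/I lines, `//` terminator)."""
    for s in library:
        stream.write(f"H {s.symbol}\n")
        stream.write(f"D {s.name}\n")
        stream.write("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n")
        row1 = "".join(f"{s.values[aa]:8g}" for aa in AA_ORDER[:10])
        row2 = "".join(f"{s.values[aa]:8g}" for aa in AA_ORDER[10:])
        stream.write(row1 + "\n" + row2 + "\n//\n")
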