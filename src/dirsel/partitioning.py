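"""Pool replacements by whole sequence, sliding windows, or named regions.

Partitions are 1-based inclusive residue intervals.  A replacement belongs
to every partition containing its site, so overlapping windows or regions
share replacements; partitioning never mutates a replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .replacement_io import Replacement, ReplacementList

__all__ = [
    "Partition",
    "whole",
    "sliding_windows",
    "regions",
    "read_region_table",
    "bed_to_region_rows",
]


@dataclass(frozen=True)
class Partition:
    """A named 1-based inclusive residue interval."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid partition {self.name!r}: [{self.start}, {self.end}]")

    def __contains__(self, site: int) -> bool:
        return self.start <= site <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _pool(replacements: ReplacementList, part: Partition) -> ReplacementList:
    reps = tuple(r for r in replacements if r.site in part)
    return ReplacementList(
        reps, replacements.sequence_length, replacements.labels, replacements.filter_report
    )


def whole(replacements: ReplacementList) -> tuple[Partition, ReplacementList]:
    """Single partition spanning the full sequence with every replacement."""
    length = max(replacements.sequence_length, 1)
    part = Partition("whole", 1, length)
    return part, _pool(replacements, part)


def sliding_windows(
    replacements: ReplacementList,
    window_size: int,
    step: int,
) -> list[tuple[Partition, ReplacementList]]:
    """Windows starting at 1, 1+step, ...; generation stops once a window
    reaches the sequence end (that final window is truncated there).

    With step <= window size every site is covered; replacements land in
    every window that contains their site.  A window spanning the whole
    sequence therefore yields exactly one partition.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    length = max(replacements.sequence_length, 1)
    if window_size > length:
        warnings.warn(
            f"window size {window_size} exceeds sequence length {length}; "
            "using a single whole-sequence window"
        )
        return [whole(replacements)]
    out = []
    start = 1
    while start <= length:
        end = min(start + window_size - 1, length)
        part = Partition(f"[{start},{end}]", start, end)
        out.append((part, _pool(replacements, part)))
        if end >= length:
            break
        start += step
    return out


def regions(
    replacements: ReplacementList,
    region_spec: Iterable[tuple[str, int, int] | Sequence],
) -> list[tuple[Partition, ReplacementList]]:
    """Pool replacements into named (possibly overlapping) regions.

    Regions extending past the sequence end are clipped with a warning;
    residues in no region are simply not tested.
    """
    length = max(replacements.sequence_length, 1)
    out = []
    for name, start, end in region_spec:
        start, end = int(start), int(end)
        if end < start:
            raise ValueError(f"region {name!r}: end {end} < start {start}")
        if end > length:
            warnings.warn(f"region {name!r} clipped from {end} to sequence length {length}")
            end = length
            if start > end:
                continue
        part = Partition(str(name), start, end)
        out.append((part, _pool(replacements, part)))
    return out


def read_region_table(stream: IO[str]) -> list[tuple[str, int, int]]:
    """Read a region spec TSV with header ``name  start  end`` (1-based)."""
    header = stream.readline().rstrip("\n").split("\t")
    if header[:3] != ["name", "start", "end"]:
        raise ValueError("region table needs header columns: name, start, end")
    rows = []
    for i, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"region table line {i}: expected 3 columns")
        rows.append((parts[0], int(parts[1]), int(parts[2])))
    return rows


def bed_to_region_rows(stream: IO[str]) -> list[tuple[str, int, int]]:
    """Convert BED lines (0-based, half-open) to 1-based inclusive regions."""
    rows = []
    for i, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"BED line {i}: expected at least 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 and parts[3] else chrom
        rows.append((name, start + 1, end))
    return rows
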