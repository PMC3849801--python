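"""Build per-comparison amino-acid replacement lists from common inputs.

Supported inputs: equal-length aligned protein pairs, protein-coding
nucleotide pairs translated in-package, BLAST tabular output carrying the
aligned query/subject sequences, and externally produced plain replacement
tables (site / from / to), e.g. exported from ancestral-reconstruction tools.

Coordinates are 1-based, inclusive, in the frame of the first (query)
sequence.  Sites with gaps or non-standard residues are excluded — never
imputed — and the exclusions are counted in a :class:`FilterReport`.
"""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio import SeqIO

from .property_table import STANDARD_AA

__all__ = [
    "Replacement",
    "ReplacementList",
    "FilterReport",
    "AlignedPair",
    "translate_cds",
    "diff_aligned",
    "parse_blast_pairs",
    "read_replacement_table",
    "write_replacement_table",
    "fetch_or_load_fasta",
    "DEFAULT_BLAST_FIELDS",
]

_IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class Replacement:
    """One inferred amino-acid difference at a residue site.

    ``site`` is a 1-based residue coordinate; ``from_res``/``to_res`` are
    distinct standard one-letter codes.
    """

    site: int
    from_res: str
    to_res: str

    def __post_init__(self) -> None:
        if self.site < 1:
            raise ValueError(f"site must be >= 1, got {self.site}")
        for res in (self.from_res, self.to_res):
            if res not in STANDARD_AA:
                raise ValueError(f"non-standard residue {res!r} at site {self.site}")
        if self.from_res == self.to_res:
            raise ValueError(f"site {self.site}: from and to residues are identical")


@dataclass(frozen=True)
class FilterReport:
    """Per-comparison accounting of aligned sites.

    Invariant: ``matches + mismatches + filtered == alignment length`` where
    ``filtered = gaps + nonstandard``.
    """

    matches: int = 0
    mismatches: int = 0
    gaps: int = 0
    nonstandard: int = 0

    @property
    def filtered(self) -> int:
        return self.gaps + self.nonstandard

    @property
    def total(self) -> int:
        return self.matches + self.mismatches + self.filtered


@dataclass(frozen=True)
class ReplacementList:
    """Ordered replacements from one pairwise comparison.

    Sites are strictly increasing (one replacement per site) and bounded by
    ``sequence_length``.  ``labels`` names the (from, to) sequences.
    """

    replacements: tuple[Replacement, ...]
    sequence_length: int
    labels: tuple[str, str] = ("seq_a", "seq_b")
    filter_report: FilterReport | None = None

    def __post_init__(self) -> None:
        prev = 0
        for r in self.replacements:
            if r.site <= prev:
                raise ValueError(
                    f"replacement sites must be strictly increasing; "
                    f"site {r.site} follows {prev}"
                )
            prev = r.site
        if self.replacements and self.replacements[-1].site > self.sequence_length:
            raise ValueError(
                f"site {self.replacements[-1].site} exceeds sequence length "
                f"{self.sequence_length}"
            )

    def __len__(self) -> int:
        return len(self.replacements)

    def __iter__(self):
        return iter(self.replacements)

    def sites(self) -> list[int]:
        return [r.site for r in self.replacements]


def translate_cds(nt_sequence: str, genetic_code_id: int = 1) -> str:
    """Translate a coding nucleotide sequence, complete codons only.

    ``genetic_code_id`` is a standard translation-table number (1 = standard,
    5 = invertebrate mitochondrial).  Trailing 1-2 nt are dropped with a
    warning; internal stops translate to ``*`` and are flagged with a
    warning; unresolvable ambiguity codons yield ``X`` with a warning.
    """
    seq = nt_sequence.strip().upper().replace("U", "T")
    if len(seq) < 3:
        raise ValueError("need at least one complete codon (3 nt)")
    bad = sorted(set(seq) - _IUPAC_NT)
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {bad}")
    try:
        CodonTable.unambiguous_dna_by_id[genetic_code_id]
    except KeyError:
        raise ValueError(f"unknown genetic code table {genetic_code_id}") from None
    trailing = len(seq) % 3
    if trailing:
        warnings.warn(f"dropping {trailing} trailing nucleotide(s) (incomplete codon)")
        seq = seq[: len(seq) - trailing]
    protein = str(Seq(seq).translate(table=genetic_code_id))
    if "X" in protein:
        warnings.warn(f"{protein.count('X')} ambiguous codon(s) translated as X")
    if "*" in protein.rstrip("*"):
        warnings.warn("internal stop codon(s) in translation")
    return protein


def diff_aligned(
    seq_a: str,
    seq_b: str,
    labels: tuple[str, str] = ("seq_a", "seq_b"),
) -> ReplacementList:
    """Extract replacements from two equal-length aligned protein sequences.

    One :class:`Replacement` per site where both residues are standard and
    differ; ``from_res`` comes from ``seq_a``, ``to_res`` from ``seq_b``.
    Gapped or non-standard sites are excluded and counted.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}")
    a, b = seq_a.upper(), seq_b.upper()
    matches = mismatches = gaps = nonstandard = 0
    reps: list[Replacement] = []
    for i, (ra, rb) in enumerate(zip(a, b), start=1):
        if ra in "-." or rb in "-.":
            gaps += 1
        elif ra not in STANDARD_AA or rb not in STANDARD_AA:
            nonstandard += 1
        elif ra == rb:
            matches += 1
        else:
            mismatches += 1
            reps.append(Replacement(i, ra, rb))
    report = FilterReport(matches, mismatches, gaps, nonstandard)
    return ReplacementList(tuple(reps), len(a), labels, report)


#: Field layout of ``blastp -outfmt "6 std qseq sseq"``.
DEFAULT_BLAST_FIELDS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qseq", "sseq",
)

_FIELD_ALIASES = {
    "query id": "qseqid", "query acc.": "qseqid", "query acc.ver": "qseqid",
    "subject id": "sseqid", "subject acc.": "sseqid", "subject acc.ver": "sseqid",
    "% identity": "pident", "alignment length": "length", "mismatches": "mismatch",
    "gap opens": "gapopen", "q. start": "qstart", "q. end": "qend",
    "s. start": "sstart", "s. end": "send", "evalue": "evalue",
    "bit score": "bitscore", "query seq": "qseq", "subject seq": "sseq",
}


@dataclass(frozen=True)
class AlignedPair:
    """One BLAST HSP as an aligned (query, subject) sequence pair."""

    labels: tuple[str, str]
    qseq: str
    sseq: str
    qstart: int = 1


def parse_blast_pairs(
    stream: IO[str],
    fields: Sequence[str] | None = None,
) -> list[AlignedPair]:
    """Parse BLAST tabular output into aligned pairs, one per HSP.

    The layout defaults to ``-outfmt "6 std qseq sseq"``
    (:data:`DEFAULT_BLAST_FIELDS`); a ``# Fields:`` comment line (outfmt 7)
    overrides it.  ``qseq``/``sseq`` columns are required.  Coordinates stay
    in the query frame via ``qstart``.
    """
    layout = list(fields) if fields is not None else list(DEFAULT_BLAST_FIELDS)
    pairs: list[AlignedPair] = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.lower().startswith("# fields:"):
                names = [f.strip() for f in line.split(":", 1)[1].split(",")]
                layout = [_FIELD_ALIASES.get(n.lower(), n) for n in names]
            continue
        if "qseq" not in layout or "sseq" not in layout:
            raise ValueError(
                "BLAST tabular input must include aligned-sequence columns "
                "'qseq' and 'sseq' (e.g. -outfmt '6 std qseq sseq')"
            )
        cols = line.split("\t")
        if len(cols) < len(layout):
            raise ValueError(
                f"BLAST row has {len(cols)} columns but {len(layout)} fields "
                f"expected ({' '.join(layout)})"
            )
        row = dict(zip(layout, cols))
        qseq, sseq = row["qseq"], row["sseq"]
        if len(qseq) != len(sseq):
            raise ValueError(
                f"HSP {row.get('qseqid', '?')} vs {row.get('sseqid', '?')}: "
                "qseq and sseq lengths differ"
            )
        pairs.append(
            AlignedPair(
                labels=(row.get("qseqid", "query"), row.get("sseqid", "subject")),
                qseq=qseq,
                sseq=sseq,
                qstart=int(row.get("qstart", 1)),
            )
        )
    return pairs


def read_replacement_table(stream: IO[str]) -> ReplacementList:
    """Read a plain replacement table: TSV with header ``site  from  to``.

    Sites are 1-based; duplicate sites, identical from/to residues, and
    non-standard residues are validation errors.  Three-letter residue names
    (e.g. ``Cys``) are accepted alongside one-letter codes.
    """
    reader = csv.DictReader(stream, delimiter="\t")
    required = {"site", "from", "to"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(f"replacement table needs header columns {sorted(required)}")
    rows = []
    for i, row in enumerate(reader, start=2):
        try:
            site = int(row["site"])
        except ValueError:
            raise ValueError(f"line {i}: non-integer site {row['site']!r}") from None
        rows.append(Replacement(site, _one_letter(row["from"]), _one_letter(row["to"])))
    sites = [r.site for r in rows]
    if len(set(sites)) != len(sites):
        dup = sorted({s for s in sites if sites.count(s) > 1})
        raise ValueError(f"duplicate replacement site(s): {dup}")
    rows.sort(key=lambda r: r.site)
    length = rows[-1].site if rows else 0
    return ReplacementList(tuple(rows), sequence_length=length)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _one_letter(res: str) -> str:
    res = res.strip()
    if len(res) == 1:
        return res.upper()
    try:
        return _THREE_TO_ONE[res.upper()]
    except KeyError:
        raise ValueError(f"unrecognized residue name {res!r}") from None


def write_replacement_table(replacements: Iterable[Replacement], stream: IO[str]) -> None:
    """Write a replacement table in the canonical TSV format (round-trips)."""
    stream.write("site\tfrom\tto\n")
    for r in replacements:
        stream.write(f"{r.site}\t{r.from_res}\t{r.to_res}\n")


def fetch_or_load_fasta(
    path_or_accession: str,
    cache_dir: str | os.PathLike | None = None,
    record_id: str | None = None,
    allow_network: bool = False,
    email: str | None = None,
):
    """Load a FASTA record from a path, a cache directory, or (opt-in) NCBI.

    A readable local path always wins.  Otherwise the argument is treated as
    an accession: ``<cache_dir>/<accession>.fasta`` is used when present, and
    a network fetch is attempted only when ``allow_network`` is set.  For a
    multi-record file, ``record_id`` selects the record; omitting it raises
    an error listing the available ids.
    """
    path = None
    if os.path.exists(path_or_accession):
        path = path_or_accession
    elif cache_dir is not None:
        candidate = os.path.join(cache_dir, f"{path_or_accession}.fasta")
        if os.path.exists(candidate):
            path = candidate
    if path is None:
        if not allow_network:
            raise FileNotFoundError(
                f"no local file or cached FASTA for {path_or_accession!r}; "
                "download it to the cache directory as "
                f"'{path_or_accession}.fasta' or pass allow_network=True"
            )
        from Bio import Entrez

        Entrez.email = email or "dirsel@example.org"
        with Entrez.efetch(
            db="nuccore", id=path_or_accession, rettype="fasta", retmode="text"
        ) as handle:
            records = list(SeqIO.parse(handle, "fasta"))
        if cache_dir is not None:
            os.makedirs(cache_dir, exist_ok=True)
            SeqIO.write(records, os.path.join(cache_dir, f"{path_or_accession}.fasta"), "fasta")
    else:
        records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path_or_accession!r}")
    if record_id is not None:
        for rec in records:
            if rec.id == record_id:
                return rec
        raise ValueError(f"record {record_id!r} not found; ids: {[r.id for r in records]}")
    if len(records) > 1:
        raise ValueError(
            f"{path_or_accession!r} holds {len(records)} records; pass record_id "
            f"to choose one of {[r.id for r in records]}"
        )
    return records[0]
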