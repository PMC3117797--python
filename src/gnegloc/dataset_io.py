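"""Multi-label protein dataset I/O.

Datasets are FASTA files with a structured header carrying the subcellular
location label(s) of each protein::

    >P12345 | Cytoplasm; Periplasm
    MKKLLPT...

The part before ``|`` is the accession; after it comes a ``;``-separated list
of location labels, given either as canonical names (case-insensitive) or as
the integer codes 1..8.  A protein may carry one or more labels; in the
Gram-negative system at most two are observed.

The eight Gram-negative subcellular locations and their codes:

====  ====================
code  location
====  ====================
1     Cell inner membrane
2     Cell outer membrane
3     Cytoplasm
4     Extracellular
5     Fimbrium
6     Flagellum
7     Nucleoid
8     Periplasm
====  ====================
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: canonical code -> name map for the 8 Gram-negative locations
LOCATION_NAMES: dict[int, str] = {
    1: "Cell inner membrane",
    2: "Cell outer membrane",
    3: "Cytoplasm",
    4: "Extracellular",
    5: "Fimbrium",
    6: "Flagellum",
    7: "Nucleoid",
    8: "Periplasm",
}

_NAME_TO_CODE = {name.lower(): code for code, name in LOCATION_NAMES.items()}

#: sequences shorter than this are flagged as likely fragments
FRAGMENT_LENGTH = 50

# 20 standard residues plus the ambiguity/rare letters found in Swiss-Prot
_ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "BJOUXZ")

_FASTA_WRAP = 80

_HEADER_RE = re.compile(r"^>\s*(\S+)\s*\|\s*(.+?)\s*$")


class FastaDialectError(ValueError):
    """Raised when a multi-label FASTA file violates the header dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, residue sequence, and its true location set."""

    accession: str
    sequence: str
    labels: frozenset[int]

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        bad = set(self.sequence) - _ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residue letter(s) {sorted(bad)}"
            )
        if not self.labels:
            raise ValueError(f"{self.accession}: label set must be non-empty")
        if not all(isinstance(c, int) and 1 <= c <= 8 for c in self.labels):
            raise ValueError(
                f"{self.accession}: location codes must be integers in 1..8, "
                f"got {sorted(self.labels)}"
            )


@dataclass
class MultiLabelDataset:
    """Ordered collection of :class:`ProteinRecord` with unique accessions."""

    records: list[ProteinRecord] = field(default_factory=list)
    location_names: dict[int, str] = field(
        default_factory=lambda: dict(LOCATION_NAMES)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession: {rec.accession}")
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    @property
    def locative_count(self) -> int:
        """Total number of (protein, location) memberships.

        A protein residing in two locations counts as two "locative
        proteins", so this is always >= ``len(self)``.
        """
        return sum(len(r.labels) for r in self.records)


def resolve_label(token: str) -> int:
    """Resolve a label token (name or integer code) to a location code."""
    token = token.strip()
    if re.fullmatch(r"\d+", token):
        code = int(token)
        if code not in LOCATION_NAMES:
            raise FastaDialectError(
                f"location code {code} out of range 1..8"
            )
        return code
    key = re.sub(r"\s+", " ", token).lower()
    try:
        return _NAME_TO_CODE[key]
    except KeyError:
        valid = ", ".join(LOCATION_NAMES.values())
        raise FastaDialectError(
            f"unknown location label {token!r}; valid names are: {valid}"
        ) from None


def _parse_header(line: str, lineno: int) -> tuple[str, frozenset[int]]:
    m = _HEADER_RE.match(line)
    if m is None:
        raise FastaDialectError(
            f"line {lineno}: malformed header {line!r} "
            "(expected '>ACCESSION | label1; label2')"
        )
    accession = m.group(1)
    try:
        labels = frozenset(
            resolve_label(tok) for tok in m.group(2).split(";") if tok.strip()
        )
    except FastaDialectError as exc:
        raise FastaDialectError(f"line {lineno}: {exc}") from None
    if not labels:
        raise FastaDialectError(f"line {lineno}: header carries no labels")
    return accession, labels


def read_multilabel_fasta(path: str | Path) -> MultiLabelDataset:
    """Read a multi-label FASTA file into a :class:`MultiLabelDataset`.

    Sequences are uppercased with whitespace stripped; label names are
    resolved case-insensitively; LF and CRLF line endings are both accepted.
    Sequences shorter than 50 residues log a fragment warning (not an error).
    """
    path = Path(path)
    header_lines: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines.append((lineno, line.rstrip("\r\n")))

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for (lineno, header), seqrec in zip(header_lines, SeqIO.parse(fh, "fasta")):
            accession, labels = _parse_header(header, lineno)
            if accession in seen:
                raise FastaDialectError(
                    f"line {lineno}: duplicate accession {accession}"
                )
            seen.add(accession)
            sequence = re.sub(r"\s+", "", str(seqrec.seq)).upper()
            if not sequence:
                raise FastaDialectError(
                    f"line {lineno}: empty sequence for {accession}"
                )
            if len(sequence) < FRAGMENT_LENGTH:
                logger.warning(
                    "%s: sequence has %d residues (<%d); likely a fragment",
                    accession, len(sequence), FRAGMENT_LENGTH,
                )
            records.append(ProteinRecord(accession, sequence, labels))
    return MultiLabelDataset(records)


def write_multilabel_fasta(dataset: MultiLabelDataset, path: str | Path) -> None:
    """Write a dataset in the multi-label FASTA dialect (80-char wrap)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in dataset.records:
            names = "; ".join(
                dataset.location_names[c] for c in sorted(rec.labels)
            )
            fh.write(f">{rec.accession} | {names}\n")
            for start in range(0, len(rec.sequence), _FASTA_WRAP):
                fh.write(rec.sequence[start:start + _FASTA_WRAP] + "\n")


def locative_expand(dataset: MultiLabelDataset) -> list[tuple[str, int]]:
    """Expand a dataset into its (accession, location code) memberships.

    Order follows record order, then ascending code within a record.  The
    length equals ``dataset.locative_count``: e.g. 1,328 single-label plus
    64 double-label proteins expand to 1,456 locative proteins.
    """
    return [
        (rec.accession, code)
        for rec in dataset.records
        for code in sorted(rec.labels)
    ]


def per_location_counts(dataset: MultiLabelDataset) -> dict[int, int]:
    """Number of locative proteins per location code (1..8)."""
    counts = {code: 0 for code in dataset.location_names}
    for rec in dataset.records:
        for code in rec.labels:
            counts[code] += 1
    return counts
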