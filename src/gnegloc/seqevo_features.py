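"""Sequential-evolution (SeqEvo) features from PSI-BLAST PSSMs.

A PSI-BLAST position-specific scoring matrix is an L x 20 table of
substitution propensities, one row per sequence position and one column per
amino-acid type.  Because L varies across proteins, the matrix is condensed
into a size-uniform descriptor: each row is standardised (zero mean, unit
population standard deviation over the 20 types), and the 20 x 20
cross-product D = M' M of the standardised matrix is formed.  D is symmetric,
so its 20 diagonal plus 190 lower-triangular elements — 210 numbers read
row-major, left to right, first row to last — form the SeqEvo vector.  The
descriptor is invariant to the order of the sequence positions.

Recommended external PSSM generation: PSI-BLAST, three iterations,
E-value cutoff 0.001 (docs-only; this module only parses the ASCII output).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: the 20 amino acids in alphabetical single-letter order (column order of
#: the parsed matrix)
ALPHABETICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: column order used by PSI-BLAST's -out_ascii_pssm files
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: SeqEvo descriptor length: 20 diagonal + 190 lower-triangular elements
SEQEVO_DIM = 210

#: row/column indices of the lower triangle of a 20x20 matrix, row-major —
#: (0,0), (1,0), (1,1), (2,0), ... — the serialization order of the vector
LOWER_TRI_INDICES = np.tril_indices(20)


class PSSMParseError(ValueError):
    """Raised on a malformed ASCII PSSM file."""


@dataclass
class PSSM:
    """Raw PSI-BLAST scores: L positions x 20 amino-acid types.

    Columns are in alphabetical single-letter order (A, C, D, ..., Y),
    re-mapped from the file's native column order at parse time.
    """

    accession: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"{self.accession}: PSSM must be L x 20, got {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"{self.accession}: PSSM must have L >= 1 rows")

    @property
    def L(self) -> int:
        return self.scores.shape[0]


@dataclass
class NormalizedPSSM:
    """Standardised PSSM plus the means/SDs used in the transformation."""

    accession: str
    M: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    axis: str = "position"

    @property
    def L(self) -> int:
        return self.M.shape[0]


@dataclass
class SeqEvoVector:
    """The 210-element evolutionary fingerprint of one protein."""

    accession: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (SEQEVO_DIM,):
            raise ValueError(
                f"{self.accession}: SeqEvo vector must have exactly "
                f"{SEQEVO_DIM} elements, got {self.values.shape}"
            )

    def reconstruct(self) -> np.ndarray:
        """Rebuild the symmetric 20x20 cross-product matrix."""
        full = np.zeros((20, 20))
        full[LOWER_TRI_INDICES] = self.values
        return full + full.T - np.diag(np.diag(full))


def parse_ascii_pssm(path: str | Path, accession: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The first 20-column score block (log-odds) is read; columns are
    re-mapped from the file's header order to alphabetical single-letter
    order.  The accession defaults to the file name stem.
    """
    path = Path(path)
    if accession is None:
        accession = path.stem
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()

    aa_set = set(ALPHABETICAL_AA)
    header_idx = None
    col_letters: list[str] = []
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(t in aa_set for t in tokens[:20]):
            header_idx = i
            col_letters = tokens[:20]
            break
    if header_idx is None:
        raise PSSMParseError(f"{path}: no amino-acid column header found")
    if sorted(col_letters) != sorted(ALPHABETICAL_AA):
        raise PSSMParseError(
            f"{path}: line {header_idx + 1}: column header does not cover "
            "the 20 amino acids exactly once"
        )
    # permutation taking file column order -> alphabetical order
    perm = [col_letters.index(a) for a in ALPHABETICAL_AA]

    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        tokens = line.split()
        if not tokens or not tokens[0].lstrip("-").isdigit():
            break  # footer (K/Lambda statistics) or blank line
        if len(tokens) < 22:
            raise PSSMParseError(
                f"{path}: line {lineno}: truncated row "
                f"({len(tokens)} fields, expected >= 22)"
            )
        try:
            scores = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PSSMParseError(
                f"{path}: line {lineno}: non-numeric score ({exc})"
            ) from None
        rows.append(scores)
    if not rows:
        raise PSSMParseError(f"{path}: no score rows found")
    raw = np.asarray(rows, dtype=float)
    return PSSM(accession=accession, scores=raw[:, perm])


def normalize_pssm(p: PSSM, axis: str = "position") -> NormalizedPSSM:
    """Standardise a PSSM to zero mean and unit population SD.

    ``axis="position"`` (default) standardises each row over its 20
    amino-acid scores; ``axis="residue"`` standardises each column over the
    L positions.  Units with zero spread (constant scores) map to all zeros.
    """
    if axis not in ("position", "residue"):
        raise ValueError(f"axis must be 'position' or 'residue', got {axis!r}")
    np_axis = 1 if axis == "position" else 0
    mean = p.scores.mean(axis=np_axis, keepdims=True)
    sd = p.scores.std(axis=np_axis, keepdims=True)  # population SD, divisor n
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(sd > 0, (p.scores - mean) / sd, 0.0)
    return NormalizedPSSM(
        accession=p.accession,
        M=M,
        mean=mean.squeeze(axis=np_axis),
        sd=sd.squeeze(axis=np_axis),
        axis=axis,
    )


def seqevo_vector(m: NormalizedPSSM) -> SeqEvoVector:
    """Condense a standardised PSSM into the 210-element SeqEvo descriptor.

    D = M' M is 20x20 and symmetric positive semidefinite; the vector is
    its lower triangle (diagonal included) read row-major.  Because D is a
    sum over positions, it is mathematically invariant to row order; rows
    are accumulated in a canonical (lexicographically sorted) order so the
    invariance also holds bit-for-bit in floating point.
    """
    order = np.lexsort(m.M.T[::-1])
    M = m.M[order]
    D = M.T @ M
    return SeqEvoVector(accession=m.accession, values=D[LOWER_TRI_INDICES])


def seqevo_from_pssm_file(
    path: str | Path, accession: str | None = None, axis: str = "position"
) -> SeqEvoVector:
    """Parse, standardise and condense a PSSM file in one call."""
    return seqevo_vector(normalize_pssm(parse_ascii_pssm(path, accession), axis))
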