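"""Per-protein feature representation and the self-consistency contract.

A protein is represented either by its GO hit-frequency vector or, when that
vector carries no usable information for the training set at hand, by its
SeqEvo descriptor.  The self-consistency principle requires that a distance
is only ever computed between vectors of the same kind: a GO-mode query is
compared against the GO vectors of the training proteins that have usable
ones, and a SeqEvo-mode query against the SeqEvo vectors of the full
training set.  SeqEvo is the universal fallback, so every training protein
must have a SeqEvo vector; GO vectors are optional per protein.

The module also persists/loads the feature store: a directory holding
``seqevo_vectors.tsv`` (dense, accession + 210 columns),
``go_vectors.tsv`` (sparse accession/rank/value triplets) and
``manifest.json`` (labels, dimensions, classifier configuration).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import sparse

from .go_features import GOVector
from .seqevo_features import SEQEVO_DIM

logger = logging.getLogger(__name__)


class Mode(str, Enum):
    GO = "GO"
    SEQEVO = "SEQEVO"


class ModeMismatchError(ValueError):
    """Raised when vectors of different modes meet in one computation."""


class NoUsableGOTrainingError(ValueError):
    """GO-mode requested but no training protein has a usable GO vector."""


@dataclass(frozen=True)
class FeatureVector:
    """A protein's feature vector in exactly one of the two modes."""

    accession: str
    mode: Mode
    go: GOVector | None = None
    seqevo: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode is Mode.GO and self.go is None:
            raise ValueError(f"{self.accession}: GO mode requires a GO vector")
        if self.mode is Mode.SEQEVO and self.seqevo is None:
            raise ValueError(
                f"{self.accession}: SEQEVO mode requires a SeqEvo vector"
            )


@dataclass
class FeatureContext:
    """Feature vectors, labels and configuration for one training set.

    Every accession must have a SeqEvo vector (the universal fallback);
    GO vectors are stored only for the proteins that have one.  ``go_dim``
    is U, the size of the compressed GO index space.
    """

    accessions: list[str]
    labels: dict[str, frozenset[int]]
    seqevo: dict[str, np.ndarray]
    go: dict[str, GOVector] = field(default_factory=dict)
    go_dim: int = 0
    k: int = 5
    metric: str = "euclidean"
    pssm_norm_axis: str = "position"

    def __post_init__(self) -> None:
        for acc in self.accessions:
            if acc not in self.seqevo:
                raise ValueError(f"{acc}: missing SeqEvo vector "
                                 "(SeqEvo is the universal fallback)")
        self._seqevo_cache: tuple[np.ndarray, np.ndarray] | None = None
        self._go_cache: tuple[list[str], sparse.csr_matrix, np.ndarray] | None = None
        self._go_rank_counts: Counter[int] | None = None

    # -- cached geometry -------------------------------------------------

    def go_accessions(self) -> list[str]:
        """Training accessions with a non-naught GO vector, in training order."""
        return [a for a in self.accessions
                if a in self.go and not self.go[a].is_naught]

    def seqevo_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n x 210 matrix in training order, per-row squared norms)."""
        if self._seqevo_cache is None:
            mat = np.vstack([self.seqevo[a] for a in self.accessions])
            self._seqevo_cache = (mat, np.einsum("ij,ij->i", mat, mat))
        return self._seqevo_cache

    def go_matrix(self) -> tuple[list[str], sparse.csr_matrix, np.ndarray]:
        """(GO-usable accessions, sparse n_go x U matrix, squared norms)."""
        if self._go_cache is None:
            accs = self.go_accessions()
            mat = sparse.lil_matrix((len(accs), max(self.go_dim, 1)))
            for i, acc in enumerate(accs):
                for rank, value in self.go[acc].components.items():
                    mat[i, rank - 1] = value
            csr = mat.tocsr()
            norms = np.asarray(csr.multiply(csr).sum(axis=1)).ravel()
            self._go_cache = (accs, csr, norms)
        return self._go_cache

    def go_rank_counts(self) -> Counter[int]:
        """How many training GO vectors are nonzero at each rank."""
        if self._go_rank_counts is None:
            counts: Counter[int] = Counter()
            for acc in self.go_accessions():
                counts.update(self.go[acc].components)
            self._go_rank_counts = counts
        return self._go_rank_counts

    def go_vector_usable(
        self, v: GOVector, exclude: frozenset[str] | set[str] = frozenset()
    ) -> bool:
        """Usability of a GO vector against the (possibly reduced) training set.

        ``exclude`` removes training proteins (jackknife hygiene): a rank
        only counts as shared if some non-excluded training vector is
        nonzero there.
        """
        if v is None or v.is_naught:
            return False
        counts = self.go_rank_counts()
        go_accs = set(self.go_accessions())
        excluded = [a for a in exclude if a in go_accs]
        for rank in v.components:
            n = counts.get(rank, 0)
            n -= sum(1 for a in excluded if rank in self.go[a].components)
            if n > 0:
                return True
        return False


def represent(
    accession: str,
    ctx: FeatureContext,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> FeatureVector:
    """Choose the representation of a protein under the fallback contract.

    GO mode is used when the protein has a GO vector that is usable against
    the training GO vectors (minus ``exclude``, which should contain the
    protein itself during leave-one-out testing); otherwise SeqEvo mode.
    A missing SeqEvo vector is an error — it is the universal fallback.
    """
    if accession not in ctx.seqevo:
        raise KeyError(f"{accession}: no SeqEvo vector in context")
    gv = ctx.go.get(accession)
    if gv is not None and ctx.go_vector_usable(gv, frozenset(exclude)):
        logger.debug("%s: represented in GO mode", accession)
        return FeatureVector(accession=accession, mode=Mode.GO, go=gv)
    logger.debug("%s: represented in SEQEVO mode (fallback)", accession)
    return FeatureVector(
        accession=accession, mode=Mode.SEQEVO, seqevo=ctx.seqevo[accession]
    )


def represent_query(
    accession: str,
    seqevo: np.ndarray,
    go: GOVector | None,
    ctx: FeatureContext,
) -> FeatureVector:
    """Representation of an external query (not part of the training set)."""
    if go is not None and ctx.go_vector_usable(go):
        return FeatureVector(accession=accession, mode=Mode.GO, go=go)
    return FeatureVector(accession=accession, mode=Mode.SEQEVO, seqevo=seqevo)


def matched_training_vectors(
    query_mode: Mode,
    ctx: FeatureContext,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[tuple[str, frozenset[int], FeatureVector]]:
    """Training vectors expressed in the query's mode (self-consistency).

    GO query -> only training proteins with usable GO vectors, as GO-mode
    vectors; SeqEvo query -> every training protein, as SeqEvo-mode vectors.
    Modes are never mixed within one distance computation.
    """
    out: list[tuple[str, frozenset[int], FeatureVector]] = []
    if query_mode is Mode.GO:
        for acc in ctx.go_accessions():
            if acc in exclude:
                continue
            out.append((acc, ctx.labels[acc],
                        FeatureVector(acc, Mode.GO, go=ctx.go[acc])))
        if not out:
            raise NoUsableGOTrainingError(
                "no GO-usable training proteins; fall back to SEQEVO mode"
            )
    else:
        for acc in ctx.accessions:
            if acc in exclude:
                continue
            out.append((acc, ctx.labels[acc],
                        FeatureVector(acc, Mode.SEQEVO, seqevo=ctx.seqevo[acc])))
    return out


# -- feature store persistence ------------------------------------------

_SEQEVO_FILE = "seqevo_vectors.tsv"
_GO_FILE = "go_vectors.tsv"
_MANIFEST_FILE = "manifest.json"


def save_feature_store(ctx: FeatureContext, directory: str | Path) -> None:
    """Write a feature context as a TSV + JSON feature-store directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    seqevo_df = pd.DataFrame(
        np.vstack([ctx.seqevo[a] for a in ctx.accessions]) if ctx.accessions
        else np.empty((0, SEQEVO_DIM)),
        columns=[f"c{i}" for i in range(SEQEVO_DIM)],
    )
    seqevo_df.insert(0, "accession", ctx.accessions)
    seqevo_df.to_csv(directory / _SEQEVO_FILE, sep="\t", index=False,
                     float_format="%.17g")

    rows = []
    for acc in ctx.accessions:
        gv = ctx.go.get(acc)
        if gv is None:
            continue
        for rank in sorted(gv.components):
            rows.append((acc, rank, gv.components[rank]))
    pd.DataFrame(rows, columns=["accession", "rank", "value"]).to_csv(
        directory / _GO_FILE, sep="\t", index=False, float_format="%.17g"
    )

    manifest = {
        "go_dim": ctx.go_dim,
        "k": ctx.k,
        "metric": ctx.metric,
        "pssm_norm_axis": ctx.pssm_norm_axis,
        "records": [
            {
                "accession": acc,
                "labels": sorted(ctx.labels[acc]),
                "has_go": acc in ctx.go,
            }
            for acc in ctx.accessions
        ],
    }
    with open(directory / _MANIFEST_FILE, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_feature_store(directory: str | Path) -> FeatureContext:
    """Load a feature-store directory back into a :class:`FeatureContext`."""
    directory = Path(directory)
    with open(directory / _MANIFEST_FILE, encoding="utf-8") as fh:
        manifest = json.load(fh)

    seqevo_df = pd.read_csv(directory / _SEQEVO_FILE, sep="\t",
                            float_precision="round_trip")
    seqevo = {
        str(row[0]): np.asarray(row[1:], dtype=float)
        for row in seqevo_df.itertuples(index=False)
    }

    go_dim = int(manifest["go_dim"])
    go_df = pd.read_csv(directory / _GO_FILE, sep="\t",
                        float_precision="round_trip")
    go_components: dict[str, dict[int, float]] = {}
    for acc, rank, value in go_df.itertuples(index=False):
        go_components.setdefault(str(acc), {})[int(rank)] = float(value)

    accessions = [r["accession"] for r in manifest["records"]]
    labels = {
        r["accession"]: frozenset(int(c) for c in r["labels"])
        for r in manifest["records"]
    }
    go = {
        acc: GOVector(comps, go_dim)
        for acc, comps in go_components.items()
    }
    return FeatureContext(
        accessions=accessions,
        labels=labels,
        seqevo=seqevo,
        go=go,
        go_dim=go_dim,
        k=int(manifest["k"]),
        metric=manifest["metric"],
        pssm_norm_axis=manifest["pssm_norm_axis"],
    )
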