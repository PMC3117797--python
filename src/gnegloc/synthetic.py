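"""Synthetic fixtures: datasets, feature geometry, PSSM files, GO tables.

Every input the pipeline consumes can be generated here with controllable
structure, so the whole system is testable without external databases or
BLAST runs.  The generators are pure functions of their spec and seed.

The default dataset composition mirrors the Gram-negative benchmark:
locative counts 557/124/410/133/32/12/8/180 across the 8 locations
(1,456 locative proteins), with 64 of the 1,392 distinct proteins carrying
two labels.

Feature geometry is a Gaussian-blob stand-in for real feature structure:
each location gets a cluster center in a low-dimensional latent space,
placed ``separation x within_spread`` apart along orthogonal axes;
single-label proteins scatter around their center with isotropic noise of
scale ``within_spread``, and dual-label proteins sit at the midpoint of
their two centers.  The latent point is embedded both into the 210-d SeqEvo
layout (leading coordinates) and into a sparse GO layout (components
squashed into [0, 1]).  ``separation`` is the difficulty dial: large values
make the jackknife nearly perfect, zero makes it label-frequency chance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .dataset_io import MultiLabelDataset, ProteinRecord
from .go_features import AnnotationTable, GOCompressMap, GOVector, HomologySet, build_compress_map
from .representation import FeatureContext
from .seqevo_features import (
    ALPHABETICAL_AA,
    PSIBLAST_COLUMN_ORDER,
    SEQEVO_DIM,
    PSSM,
)

#: locative counts of the Gram-negative benchmark, codes 1..8
BENCHMARK_LOCATIVE_COUNTS = (557, 124, 410, 133, 32, 12, 8, 180)

#: fraction of distinct proteins carrying two labels in the benchmark
BENCHMARK_DUAL_FRACTION = 64 / 1392

_AA = np.array(list(ALPHABETICAL_AA))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``locative_counts`` are per-location membership counts (a dual-label
    protein counts once in each of its two locations).  ``dual_label_fraction``
    is the fraction of distinct proteins with two labels; the number of
    distinct proteins follows from the two.  ``separation`` is the
    between-center distance in units of ``within_spread``.
    """

    locative_counts: tuple[int, ...] = BENCHMARK_LOCATIVE_COUNTS
    dual_label_fraction: float = BENCHMARK_DUAL_FRACTION
    separation: float = 5.0
    within_spread: float = 1.0
    latent_dim: int = 8
    go_dim: int = 64
    naught_go_fraction: float = 0.1
    seq_length_range: tuple[int, int] = (50, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.locative_counts) != 8:
            raise ValueError("locative_counts must have 8 entries")
        if any(c < 0 for c in self.locative_counts):
            raise ValueError("locative counts must be >= 0")
        if not (0.0 <= self.dual_label_fraction <= 1.0):
            raise ValueError(
                f"dual_label_fraction must be in [0, 1], "
                f"got {self.dual_label_fraction}"
            )
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.within_spread <= 0:
            raise ValueError("within_spread must be > 0")
        if not (0.0 <= self.naught_go_fraction <= 1.0):
            raise ValueError("naught_go_fraction must be in [0, 1]")
        if self.latent_dim < 8:
            raise ValueError("latent_dim must be >= 8 (one axis per location)")

    @property
    def n_locative(self) -> int:
        return sum(self.locative_counts)

    @property
    def n_dual(self) -> int:
        # n_dual duals + (n_locative - 2*n_dual) singles = n_proteins and
        # n_dual = dual_fraction * n_proteins  =>  solve for n_dual
        f = self.dual_label_fraction
        return int(round(f * self.n_locative / (1.0 + f)))

    @property
    def n_proteins(self) -> int:
        return self.n_locative - self.n_dual

    def scaled(self, n_locative: int) -> "SyntheticSpec":
        """Same composition shape at a smaller total locative count."""
        factor = n_locative / self.n_locative
        counts = tuple(
            max(1, int(round(c * factor))) if c else 0
            for c in self.locative_counts
        )
        return replace(self, locative_counts=counts)


def _random_sequence(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    lo, hi = spec.seq_length_range
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_AA, size=length))


def _assign_label_sets(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[frozenset[int]]:
    """Draw label sets meeting the per-location counts and dual count."""
    remaining = list(spec.locative_counts)
    label_sets: list[frozenset[int]] = []
    for _ in range(spec.n_dual):
        nonzero = [c for c in range(8) if remaining[c] > 0]
        if len(nonzero) < 2:
            raise ValueError(
                "dual_label_fraction infeasible for these locative counts"
            )
        weights = np.array([remaining[c] for c in nonzero], dtype=float)
        first = int(rng.choice(nonzero, p=weights / weights.sum()))
        rest = [c for c in nonzero if c != first]
        weights2 = np.array([remaining[c] for c in rest], dtype=float)
        second = int(rng.choice(rest, p=weights2 / weights2.sum()))
        remaining[first] -= 1
        remaining[second] -= 1
        label_sets.append(frozenset({first + 1, second + 1}))
    for c in range(8):
        label_sets.extend([frozenset({c + 1})] * remaining[c])
    perm = rng.permutation(len(label_sets))
    return [label_sets[i] for i in perm]


def cluster_centers(spec: SyntheticSpec) -> dict[int, np.ndarray]:
    """Ground-truth latent cluster center of each location code.

    ``separation`` is calibrated to the *minimum* center gap over all class
    pairs, dual-label midpoint clusters included: a dual cluster sits halfway
    between its two parents, which is the tightest gap in the constellation,
    so the single-label axes are scaled by sqrt(2) x separation to make that
    gap exactly ``separation x within_spread``.
    """
    scale = spec.separation * spec.within_spread * np.sqrt(2.0)
    centers = {}
    for code in range(1, 9):
        e = np.zeros(spec.latent_dim)
        e[code - 1] = 1.0
        centers[code] = scale * e
    return centers


def make_dataset(
    spec: SyntheticSpec,
) -> tuple[MultiLabelDataset, dict[int, np.ndarray]]:
    """Random multi-label dataset matching the spec's composition.

    Returns the dataset and the ground-truth latent cluster centers used by
    :func:`make_feature_context`.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    label_sets = _assign_label_sets(spec, rng)
    records = [
        ProteinRecord(
            accession=f"SYN{i:05d}",
            sequence=_random_sequence(rng, spec),
            labels=labels,
        )
        for i, labels in enumerate(label_sets)
    ]
    return MultiLabelDataset(records), cluster_centers(spec)


def _latent_points(
    dataset: MultiLabelDataset,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    centers = cluster_centers(spec)
    points = {}
    for rec in dataset.records:
        center = np.mean([centers[c] for c in sorted(rec.labels)], axis=0)
        points[rec.accession] = center + rng.normal(
            0.0, spec.within_spread, spec.latent_dim
        )
    return points


def make_feature_context(
    dataset: MultiLabelDataset, spec: SyntheticSpec
) -> FeatureContext:
    """Embed the latent cluster geometry into SeqEvo and GO layouts.

    SeqEvo vectors carry the latent point in their leading coordinates.
    GO vectors squash each latent coordinate into a [0, 1] component at a
    fixed low rank, so class structure survives in both modes; a
    ``naught_go_fraction`` of proteins get no GO vector at all, exercising
    the SeqEvo fallback.
    """
    rng = np.random.default_rng(spec.seed + 1)
    latent = _latent_points(dataset, spec, rng)
    # squash scale keeps typical coordinates inside [0, 1] without saturating
    squash = 2.0 * (spec.separation * np.sqrt(2.0) + 3.0) * spec.within_spread

    seqevo: dict[str, np.ndarray] = {}
    go: dict[str, GOVector] = {}
    for rec in dataset.records:
        x = latent[rec.accession]
        v = np.zeros(SEQEVO_DIM)
        v[: spec.latent_dim] = x
        seqevo[rec.accession] = v
        if rng.random() >= spec.naught_go_fraction:
            comps = np.clip(0.5 + x / squash, 0.0, 1.0)
            components = {
                j + 1: float(comps[j])
                for j in range(spec.latent_dim)
                if comps[j] > 0.0
            }
            go[rec.accession] = GOVector(components, spec.go_dim)
    return FeatureContext(
        accessions=[rec.accession for rec in dataset.records],
        labels={rec.accession: rec.labels for rec in dataset.records},
        seqevo=seqevo,
        go=go,
        go_dim=spec.go_dim,
    )


def make_ascii_pssm(
    L: int,
    seed: int,
    path: str | Path,
    scores: np.ndarray | None = None,
) -> PSSM:
    """Write a synthetic PSI-BLAST ASCII PSSM file and return its matrix.

    ``scores`` (L x 20, alphabetical column order) defaults to random
    integers in [-10, 10].  The file follows the standard layout — two
    header lines, the residue-letter column header in PSI-BLAST order, one
    row per position with the 20 log-odds scores followed by a 20-column
    percentage block — and parses back with exact score recovery.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    if scores is None:
        scores = rng.integers(-10, 11, size=(L, 20)).astype(float)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (L, 20):
        raise ValueError(f"scores must be {L} x 20, got {scores.shape}")

    # map alphabetical columns into the file's PSI-BLAST column order
    alpha_index = {a: j for j, a in enumerate(ALPHABETICAL_AA)}
    file_cols = [alpha_index[a] for a in PSIBLAST_COLUMN_ORDER]
    residues = rng.choice(_AA, size=L)

    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        header = "           " + "  ".join(PSIBLAST_COLUMN_ORDER)
        fh.write(header + "   " + "  ".join(PSIBLAST_COLUMN_ORDER) + "\n")
        for i in range(L):
            row = scores[i, file_cols]
            logodds = " ".join(f"{int(v):3d}" for v in row)
            pct = " ".join("  0" for _ in range(20))
            fh.write(f"{i + 1:5d} {residues[i]}  {logodds}  {pct}  0.00  0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3188\n")
    return PSSM(accession=path.stem, scores=scores)


def make_annotation_fixture(
    n_reps: int,
    shared_terms: set[int],
    rare_terms: set[int],
    seed: int = 0,
    U: int = 1000,
    query: str = "QUERY",
) -> tuple[HomologySet, AnnotationTable, GOCompressMap]:
    """Homology/annotation fixture with controlled hit structure.

    ``shared_terms`` and ``rare_terms`` are compressed ranks: every
    representative is annotated with each shared term, and each rare term is
    annotated on exactly one representative.  With 47 representatives, two
    shared terms and one rare term, the resulting GO vector has components
    1.0, 1.0 and 1/47 — the hallmark of the hit-frequency formulation.
    """
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    max_rank = max(shared_terms | rare_terms, default=0)
    if max_rank > U:
        raise ValueError(f"rank {max_rank} exceeds U={U}")
    rng = np.random.default_rng(seed)
    cmap = build_compress_map(f"GO:{i:07d}" for i in range(1, U + 1))
    reps = tuple(f"REP{i:04d}" for i in range(n_reps))
    hs = HomologySet(query=query, representatives=reps)
    ann: AnnotationTable = {rep: set() for rep in reps}
    for rank in shared_terms:
        term = cmap.term_at(rank)
        for rep in reps:
            ann[rep].add(term)
    for rank in sorted(rare_terms):
        if n_reps == 0:
            break
        rep = reps[int(rng.integers(0, n_reps))]
        ann[rep].add(cmap.term_at(rank))
    return hs, ann, cmap


def make_raw_inputs(
    dataset: MultiLabelDataset,
    outdir: str | Path,
    seed: int = 0,
    reps_per_protein: int = 5,
    terms_per_label: int = 3,
    naught_fraction: float = 0.0,
) -> dict[str, Path]:
    """Write the full set of raw pipeline inputs for a dataset.

    Emits a GO id list, a homology table, an annotation table and one ASCII
    PSSM per protein under ``outdir``.  Each location gets a block of
    characteristic GO terms transferred through every representative of its
    proteins, and a per-location score pattern perturbs the PSSMs, so both
    feature routes carry label signal.  A ``naught_fraction`` of proteins
    get no homology rows (forcing the SeqEvo fallback).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    n_terms = 8 * terms_per_label
    go_ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    label_terms = {
        code: go_ids[(code - 1) * terms_per_label: code * terms_per_label]
        for code in range(1, 9)
    }
    label_patterns = {
        code: rng.integers(-5, 6, size=20) for code in range(1, 9)
    }

    go_list_path = outdir / "go_list.txt"
    go_list_path.write_text("\n".join(go_ids) + "\n", encoding="utf-8")

    homology_rows: list[str] = []
    annotation_rows: list[str] = []
    for rec in dataset.records:
        if rng.random() < naught_fraction:
            n_reps = 0
        else:
            n_reps = reps_per_protein
        terms = sorted(
            {t for code in rec.labels for t in label_terms[code]}
        )
        for j in range(n_reps):
            rep = f"R_{rec.accession}_{j}"
            homology_rows.append(f"{rec.accession}\t{rep}")
            annotation_rows.extend(f"{rep}\t{t}" for t in terms)
        pattern = np.mean(
            [label_patterns[c] for c in sorted(rec.labels)], axis=0
        )
        L = len(rec.sequence)
        noise = rng.integers(-2, 3, size=(L, 20))
        scores = np.rint(pattern[None, :] + noise)
        make_ascii_pssm(
            L, seed=int(rng.integers(0, 2**31)),
            path=pssm_dir / f"{rec.accession}.pssm", scores=scores,
        )

    homology_path = outdir / "homology.tsv"
    homology_path.write_text(
        "\n".join(homology_rows) + ("\n" if homology_rows else ""),
        encoding="utf-8",
    )
    annotation_path = outdir / "annotations.tsv"
    annotation_path.write_text(
        "\n".join(annotation_rows) + ("\n" if annotation_rows else ""),
        encoding="utf-8",
    )
    return {
        "go_list": go_list_path,
        "homology": homology_path,
        "annotations": annotation_path,
        "pssm_dir": pssm_dir,
    }
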