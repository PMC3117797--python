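# Methods

## Problem and model

`gnegloc` predicts the subcellular location(s) of Gram-negative bacterial
proteins across eight compartments (cell inner membrane, cell outer
membrane, cytoplasm, extracellular, fimbrium, flagellum, nucleoid,
periplasm; codes 1–8). The setting is multi-label: a protein may reside in
one or two compartments simultaneously, and evaluation distinguishes
*distinct* proteins from *locative* proteins — one (protein, location)
membership each, so a two-location protein counts twice. The reference
composition used throughout the synthetic study conditions is 1,392
distinct proteins / 1,456 locative proteins, with per-location locative
counts 557/124/410/133/32/12/8/180 and 64 dual-label proteins.

### Feature representations

**GO hit-frequency vector.** A query is first searched (externally, with
BLAST at E ≤ 0.001) against an annotated protein database; the hits form
its homology set of N representatives. The GO identifiers of a release are
sorted ascending and densely renumbered 1..U (the compression map). The
feature vector assigns rank u the fraction of representatives annotated
with term u — a value in {0, 1/N, …, 1} rather than a presence bit, so a
term hit by all 47 representatives weighs 1.0 while a term hit once weighs
1/47. The vector is *naught* when N = 0 or no hit maps into the index
space.

**SeqEvo descriptor.** The PSI-BLAST PSSM (L×20 log-odds, columns re-mapped
to alphabetical residue order) is standardised per position — each row
shifted and scaled to mean 0, population SD 1 over its 20 entries; rows
with zero spread become zero — and condensed into the 20×20 cross-product
D = MᵀM. D is symmetric PSD, so its 20 diagonal plus 190 lower-triangular
elements, read row-major, form a 210-dimensional length-independent
fingerprint.

**Fallback contract.** GO mode is preferred; a protein whose GO vector is
naught, or whose nonzero ranks are disjoint from the union of nonzero
ranks across the training GO vectors, falls back to SeqEvo. Distances are
only ever computed between same-mode vectors: a GO-mode query is compared
against the GO-usable subset of the training set, a SeqEvo-mode query
against all of it.

### Classifier

Euclidean distance; K nearest training neighbors (default K = 5). The
predicted *cardinality* m equals the number of locations of the single
nearest neighbor. The accumulation-layer scale scores each location
A_i = #neighbors carrying i, and the m highest-scoring codes are returned.

### Evaluation

Leave-one-out (jackknife): each protein is predicted with itself removed
from the candidate pool and, in GO mode, from the usable-GO term union.
Reported are per-location and overall *locative* success (denominator =
locative proteins) and the *absolute-true* rate (exact set match;
denominator = distinct proteins). Because the text source does not pin
down whether per-location numerators count per-site hits or exact-set
matches for dual proteins, the JSON report exposes both numerators.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `K` | 5 | neighbors in the search; the original work does not print its K, so it is exposed as a tunable with a CLI sweep (`jackknife --k ...`) |
| `pssm_norm_axis` | `position` | standardise PSSM rows (per position) or columns (per residue type); the row-wise convention localises the zero-spread degenerate case to one position |
| PSSM score block | log-odds | first 20-column block of the ASCII PSSM (the percentage block is not used) |
| external BLAST E-value | 0.001 (docs-only) | for the user's homology-set and PSI-BLAST runs; the pairwise-identity floor of the homology search is likewise a documented knob of the external step, with no default asserted |

## Numerical choices

- Population SD (divisor n) in PSSM standardisation, recorded so results
  are bit-stable.
- The cross-product accumulates PSSM rows in a canonical
  (lexicographically sorted) order, making the descriptor invariant to
  position permutations bit-for-bit, not merely to rounding.
- Neighbor ties at equal distance resolve by training-file order; equal AL
  scores resolve by smaller summed distance to the carriers, then smaller
  code. Both make predictions deterministic across runs and platforms.
- GO vectors are stored sparse (U ≈ 11,118 with few dozen nonzeros
  typical); sparse distances run over the union of nonzero ranks, which is
  exact. The neighbor search itself is vectorised (dense matrix for
  SeqEvo, CSR for GO) and verified against an exhaustive pairwise-sort
  oracle in the tests.
- A GO-mode query facing fewer than K GO-usable training proteins clamps K
  to the available count with a warning.
- Feature stores round-trip floats exactly (`%.17g` on write, round-trip
  parsing on read).

## Synthetic study conditions

The generator emulates every input the pipeline consumes (multi-label
FASTA, homology and annotation tables, GO id list, ASCII PSSMs) without
external databases. Its defaults reproduce the benchmark composition
above; label sets are drawn to match the per-location locative counts
exactly, with dual-label pairs sampled proportionally to remaining counts.

Feature geometry is a Gaussian-blob stand-in for real feature structure:
each location has a center in an 8-d latent space, single-label proteins
scatter around it with isotropic noise of scale `within_spread`, and
dual-label proteins sit at the midpoint of their two centers. The
`separation` dial is calibrated to the **minimum** center gap over all
class pairs *including the dual midpoint clusters* — the binding gap in
the constellation, since a midpoint lies closer to its parents than any
two single-label centers lie to each other. The latent point is embedded
into the leading SeqEvo coordinates and, squashed into [0, 1], into the
low ranks of a sparse GO layout; a configurable fraction of proteins get
no GO vector, exercising the SeqEvo fallback. At `separation = 0` the
features carry no label signal and the jackknife falls to the level
expected under independence of predictions and truths.

What passing tests on these conditions show: the accounting, the feature
algebra, the neighbor search, the fallback contract and the two metrics
behave exactly as specified, and the pipeline recovers planted cluster
structure (absolute-true ≥ 0.95 at separation 5, chance at 0). What they
do not show: accuracy on real proteins, which depends on the quality of
the external BLAST/PSI-BLAST searches and GO annotation coverage. The
published benchmark rates (overall locative 1331/1456 = 91.4%, absolute
true 1252/1392 = 89.9%) were obtained against historical database releases
and are not reproducible from this repository alone; the synthetic
sequences here are carriers — the features, not the residues, hold the
class signal.

Problem sizes in the default test run and the acceptance script: the full
1,392-protein composition for parameter recovery (the jackknife completes
in about a second), a ~500-locative-protein scaled copy for the
chance-level control, and 30–210-protein scaled copies for the oracle and
CLI checks.

## Known limitations

- The homology set is consumed, not computed: result quality hinges on the
  user's BLAST parameters, which the package can only document.
- The per-location numerator convention for dual proteins is a documented
  reading, not a derivation (both numerators are reported).
- Hybrid GO+SeqEvo representations are deliberately absent: the
  formulation is either/or per protein.
- Only eight Gram-negative compartments are supported; other organisms
  need a different label vocabulary and benchmark.
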