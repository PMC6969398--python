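# Methods

`barcode_assign` implements the standard DNA-barcode identification
workflow for plant barcodes (rbcLa, matK, trnH-psbA): a reference
database of taxonomically labelled sequences, a local-alignment search,
top-hit taxonomy matching with self-hit removal, and aggregation of the
per-query verdicts into correct-assignment rates (CARs).  This note
records the model, the parameters that matter, and the design choices
made where the workflow description left the design open.

## The assignment model

A query sequence q is searched against a one-marker database; the hit
list is sorted by bit score; all hits with `sseqid == qseqid` are
removed (the *self-hit* convention: each specimen is identified by the
rest of the database, a leave-one-record-out design that requires no
re-indexing); the remaining hits sharing the maximal bit score are the
*top hits*.  A species-level match is called when the query's binomial
equals that of the top hit(s); genus-level likewise on the genus.  The
CAR of a group (a family, or everything) for one barcode is

    CAR = 100 * (number of correct assignments) / (number of queries),

rounded half-up to one decimal.  Queries with no surviving hit stay in
the denominator as incorrect.

Label comparison is case-insensitive and treats `_` and ` ` alike;
infraspecific ranks (var., subsp., ...) are ignored, so matching is
strictly at binomial/genus level; "sp."/"cf."/"aff." tokens are rank
markers, not epithets, so genus-only labels can match at genus level but
never at species level.  A small idempotent correction map fixes
misspellings before comparison; the packaged default contains only the
orthographic variant Arrhenaterum → Arrhenatherum that appears in the
study material itself.  Users extend it with a two-column TSV.

### Tie policy

When tied top hits disagree, the match call is governed by a policy:
`any` (default — at least one top hit agrees), `all`, or `majority`.
Top-hit assignment workflows conventionally read "equal to the taxonomy
of the highest scoring hit or hits" permissively, hence `any` as
default; the two stricter policies are exposed and logged because the
choice is consequential exactly in the interesting (complex) cases.
Ties are detected on the bit score at printed precision (1 decimal,
tolerance 0 by default) — what a consumer of tabular BLAST output can
actually see.

## Search engine and score statistics

The engine computes maximal-scoring local alignments under affine gap
costs (gap of length k costs open + k·extend) with literal IUPAC letter
matching: ambiguity codes score as mismatches unless identical (N–N is
a match).  The dynamic programming itself is delegated to Biopython's C
`PairwiseAligner` configured with a custom substitution matrix; its raw
scores are verified in the test suite against an independent,
hand-written quadratic-time Gotoh oracle on hundreds of seeded random
pairs.  Among co-optimal alignments the engine reports the aligner's
first (deterministic) traceback; enumerating all co-optimal alignments
to apply a positional tie-break can be exponential and nothing
downstream depends on the traceback, only on the score.

Candidate pairs are prefiltered by shared exact 11-mers (either strand);
pairs sharing no word are skipped, so a query with no 11-word in common
with any reference returns no hits — a documented sensitivity limit of
word seeding.  `exhaustive=True` disables the prefilter.

Raw scores are converted with Karlin–Altschul statistics,
`bits = (λ·S − ln K)/ln 2` and `E = m·n·2^(−bits)` with m·n the raw
search-space product (no effective-length correction — assignment
depends only on score ranking, and absolute E-values from different
BLAST builds are not comparable anyway).  Two presets are shipped:
`blastn-task` (+2/−3, gap 5/2, λ=0.625, K=0.41 — the default) and
`megablast-like` (+1/−2, linear gap 2, λ=1.28, K=0.46), with the gapped
λ/K taken from the published constants for those score sets.  For
ungapped match/mismatch scoring, `estimate_lambda` solves the
characteristic equation Σ pᵢpⱼ e^{λ sᵢⱼ} = 1 to machine precision
(Brent's method), which the tests pin against the closed form λ = ln 3
for +1/−1 uniform-base scoring.

## Reference filtering and denominators

References (and, by default, queries — they live in the same downloaded
files) are kept when their family is whitelisted, no contaminant flag is
present, and length is strictly greater than 200 bp.  The strict
inequality is deliberate ("longer than 200 bp"); the packaged study
tables make the consequence concrete: of 46 matK sequences obtained, one
(185 bp) falls under the threshold, so grouped matK rates use
denominators of 45 overall / 31 grasses.  `load_study_fractions`
defaults to these filter-aware denominators (that is the convention
under which the published grouped percentages are internally
consistent); `length_filtered=False` returns the printed per-species
fractions unchanged.  Contaminant marking is operationalized as a
configurable set of header flag tokens, since reference databases
annotate this in dialect-specific ways.

## The synthetic generator

The generator emulates the features of a barcode reference database
that the analysis actually depends on, with planted truth:

- **Taxonomy**: two families; the study-shaped preset uses 11 grass-like
  species over 9 genera and 5 legume-like species over 4 genera, three
  specimens per species (16 species, 48 specimens — the study design).
- **Sequences**: one random ancestor per (family, marker) at a length
  drawn from the marker's observed range (rbcLa 470–588, matK 185–888,
  trnH-psbA 268–614 bp), then independent-site substitution down the
  hierarchy.  A branch hits each site with probability h; a hit replaces
  the base uniformly.  Because channels compose multiplicatively in
  f = 1 − (3/4)h, branch rates are calibrated so that the config's
  d_within / d_species / d_genus are the *expected observed pairwise
  divergences* between specimens at each rank — test assertions can
  compare measured Hamming divergence to the parameter directly.
- **Species complex**: a set of genera sharing one ancestor, their
  species branches recalibrated to d_complex.  This reproduces the
  situation of closely related grasses (Festuca–Lolium–Poa) where
  between-species divergence approaches within-species variation.
- **Noise**: uniform N-injection (`ambiguity_rate`) and per-(specimen,
  marker) dropout (`dropout_prob`) emulating repeatedly failed PCR.
- **Query design**: by default the queries *are* the database specimens
  (self-hit removal performs the leave-out), as in the study; a
  `holdout` mode keeps query specimens out of the references entirely.

Defaults of the study preset: d_genus 0.10, d_species 0.03, d_within
0.005 — typical plastid-barcode scales where congeneric species differ
by a few percent and conspecifics by well under one — with dropout 0.10
(the study obtained 130 of 144 specimen×marker combinations ≈ 90%
success) and ambiguity 0.002 (Table-scale N counts).

Two evaluation regimes are fixed on top of the study shape:

- `well_separated_config`: d_species 0.05, d_within 0.002, no complex,
  no ambiguity, no dropout.  Nearest references are conspecific with
  overwhelming probability, so end-to-end species-level CAR should be
  100% — this probes the pipeline plumbing, not biology.
- `species_complex_config`: the grass-like complex collapsed to
  d_complex = d_within = 0.005.  Within-species variation is kept at the
  study level rather than 0.002 deliberately: with near-zero variation
  specimens are frequently byte-identical, every top-score tie contains
  a conspecific, and the `any` policy masks the confusion the complex is
  meant to produce.  At 0.005 the nearest neighbour inside the complex
  is genuinely ambiguous and species-level CAR drops while genus-level
  CAR mostly survives — the qualitative grass/legume contrast.

Both regimes disable dropout and ambiguity because they probe assignment
recovery; dropout yield is tested separately (expected record count at
the study preset ≈ 130, the study's scale).

What passing synthetic tests do *not* show: real reference databases
contain misidentified records, uneven taxon sampling, indels and
alignment-length heterogeneity, and contamination; the generator's
uniform-base, indel-free, balanced design makes planted-truth recovery a
necessary, not sufficient, condition for field performance.

## Numerical choices and degenerate inputs

- Rounding of percentages: decimal half-up at 1 decimal (banker's
  rounding would mis-render some published cells).
- Bit scores are emitted at 1 decimal, percent identity at 2 — the
  tabular dialect's precision; tie detection operates on the printed
  precision.
- Alignments with raw score ≤ 0 produce no hit; a query whose hits are
  all self-hits is `no_hit` and counts as incorrect.
- Empty sequences, empty databases, marker-mixed searches, unknown
  policies/levels, non-idempotent correction maps and count-inconsistent
  rate rows all raise typed exceptions rather than propagating NaNs.
- Determinism: the generator is byte-reproducible per seed; assignment
  verdicts are invariant under permutation of the hit table; the search
  sorts ties by subject ID.

## Scale of the shipped analyses

The study-scale runs (48 specimens × 3 markers, all-vs-all search) take
about a minute each on one core; the acceptance script performs two such
runs plus the fixture arithmetic.  The oracle-equivalence suite uses 200
random pairs up to 200 bp, where the quadratic-time reference DP is
exact and fast.  These sizes were chosen to keep the full validation
loop interactive while exercising every stage at the study's own scale.

## Known limitations

- The engine is not a bit-for-bit blastn: no X-dropoff heuristics, no
  composition-based statistics, no effective-length correction.  E-value
  magnitudes are therefore indicative only; rankings are exact for the
  pairs aligned.
- Gapped λ/K come from a preset constant table; only ungapped λ is
  computed from first principles.
- The taxonomy layer does no synonym resolution beyond the correction
  map; genus-level aggregation of real data inherits whatever splitting
  or lumping the reference database uses.
- The published genus-level grouped percentages cannot be recomputed
  from per-species printed data (no genus-level fractions exist) and are
  not reproduced here.
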