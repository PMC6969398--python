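# barcode-assign

Taxonomic assignment of plant DNA barcodes (rbcLa, matK, trnH-psbA) by
top-hit matching against a reference database, with correct-assignment-
rate (CAR) reporting and a synthetic database generator for end-to-end
validation.

The package is aimed at people evaluating which barcode locus best
discriminates a set of species — e.g. forage grasses and legumes in
grassland biodiversity monitoring — and at anyone who needs a tested,
scriptable version of the classic BLAST-and-match identification loop.

## The method

Given a per-marker reference database of sequences labelled
`record_id|Genus_species|marker` and a set of query sequences:

1. **Reformat & filter** — headers are canonicalized; references are
   kept if their family is whitelisted, they carry no contaminant flag,
   and their length L satisfies L > 200 bp.
2. **Search** — each query is locally aligned (affine-gap
   Smith–Waterman semantics) against its marker's database on both
   strands; raw scores S become bit scores and E-values via
   Karlin–Altschul statistics, `bits = (λS − ln K)/ln 2`,
   `E = mn·2^(−bits)`; hits are exchanged in the 12-column BLAST tabular
   (outfmt 6) format, so externally produced hit tables drop in
   unchanged.
3. **Match** — self-hits (subject = query record) are removed; the
   highest-bit-score hit or hits are selected; a species (genus) match
   is called when the query's binomial (genus) equals the top hits'
   under a tie policy (`any`/`all`/`majority`), after misspelling
   correction.
4. **Rates** — verdicts are tallied per (family, species, marker) and
   aggregated: `CAR = 100 · Σ correct / Σ queries`, half-up, 1 decimal.

A synthetic-data module simulates reference databases with a calibrated
family → genus → species → specimen divergence ladder (parameters are
expected pairwise divergences, directly comparable to measured Hamming
distances), optional species complexes, N-injection and PCR dropout, so
the whole pipeline can be scored against planted truth.

## Worked example

The packaged study tables (48 specimens of 16 forage species, three
barcodes each) ship with the package.  Aggregating the per-species
assignment fractions:

```python
from barcode_assign import OVERALL, aggregate_rate, load_study_fractions

table = load_study_fractions()
for marker in ("rbcLa", "matK", "trnH-psbA"):
    print(marker,
          aggregate_rate(table, OVERALL, marker),
          aggregate_rate(table, "Poaceae", marker),
          aggregate_rate(table, "Fabaceae", marker))
```

prints

```
rbcLa 62.8 46.4 93.3
matK 51.1 48.4 57.1
trnH-psbA 78.0 65.4 100.0
```

— the species-level CAR (%) overall, for grasses, and for legumes.
trnH-psbA identifies every legume query but only ~65% of grass queries;
the closely related Festuca/Lolium/Poa species account for most grass
failures.  More narrative scripts live in `examples/` (sequence
accounting, search + assignment on a toy database, synthetic
well-separated vs species-complex evaluation); each prints the numbers
it computes and a line on what they mean.

A thin CLI wraps the same functions:

```
barcode-assign simulate --seed 1 --out-dir sim/
barcode-assign search --queries sim/queries_rbcLa.fasta \
    --db sim/reference_rbcLa.fasta --out hits.tsv
barcode-assign assign --hits hits.tsv --queries sim/queries_rbcLa.fasta --out a.tsv
barcode-assign rates --from-fractions --out-dir results/
```

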