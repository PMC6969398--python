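"""Aggregate the packaged per-species fractions into summary CARs.

The packaged fraction table records, for each of 16 forage species and
each barcode (rbcLa, matK, trnH-psbA), how many of its query sequences
were assigned to the correct species.  Aggregating with length-filtered
denominators yields the familiar overall/grasses/legumes percentages.
"""

from barcode_assign import OVERALL, aggregate_rate, load_study_fractions

table = load_study_fractions()
print(f"{'barcode':<10} {'overall':>8} {'grasses':>8} {'legumes':>8}")
for marker in ("rbcLa", "matK", "trnH-psbA"):
    row = [aggregate_rate(table, g, marker)
           for g in (OVERALL, "Poaceae", "Fabaceae")]
    print(f"{marker:<10} {row[0]:>8} {row[1]:>8} {row[2]:>8}")

# Each number is a correct-assignment rate in percent: the share of query
# sequences whose top database hit(s) carried the right species name.
# trnH-psbA identifies every legume query (100.0) but only about two
# thirds of the grasses — the Festuca/Lolium/Poa complex drags it down.
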