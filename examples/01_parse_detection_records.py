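"""Parse raw detection records into a clean samples x indicators matrix.

Builds a handful of raw surveillance rows — including a left-censored
result, replicate plate counts, and a 'Not Detected' entry — and shows how
the preprocessing rules turn them into numeric detection values.
"""

from tabgra import RawRecord, assemble_matrix


def rec(no, sample, item, result, limit, sdl, unit):
    return RawRecord(no, sample, "2018-01-31", "Bacon", item, result, limit, sdl, unit)


records = [
    rec(1, "4", "benzoic acid", "<0.005", "shall not be used", 0.005, "g/kg"),
    rec(2, "4", "total arsenic", "0.0875", "0.5", 0.04, "mg/kg"),
    rec(3, "4", "total bacterial count", "100", "10,000", None, "CFU/g"),
    rec(4, "5", "benzoic acid", "0.0025", "shall not be used", 0.005, "g/kg"),
    rec(5, "5", "total arsenic", "Not Detected", "0.5", 0.04, "mg/kg"),
    rec(6, "5", "total bacterial count", "80; 70; 90;50; 180", "10,000", None, "CFU/g"),
]

result = assemble_matrix(records, ["benzoic acid", "total arsenic",
                                   "total bacterial count"])
print(result.matrix.to_frame())
print()
for spec in result.specs:
    print(f"{spec.name}: limit {spec.max_limit} {spec.unit} ({spec.limit_source})")

# The censored '<0.005' is stripped to its reporting bound 0.005; the
# 'Not Detected' arsenic is filled with half its 0.04 detection limit
# (0.02); the five plate counts reduce to their maximum, 180.  Benzoic acid
# is not permitted at all, so its hazard denominator falls back to the
# assay detection limit.
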