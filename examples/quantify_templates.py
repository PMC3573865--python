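"""Turn fluorometric readings of a cleaned PCR product into absolute copies.

A 100-bp amplicon measured in triplicate at ~10 ng/µL contains ~9.7e10
double-stranded molecules per µL — the number that makes template inputs
comparable across targets, genes and species.
"""

from plexcal import ConcentrationMeasurement, Fragment, quantify_stock

fragment = Fragment(id="demo_amplicon", sequence="ATGC" * 25)
measurement = ConcentrationMeasurement("demo_amplicon", replicates=(9.8, 10.0, 10.2))

stock = quantify_stock(fragment, measurement)

print(f"fragment: {fragment.id}, {fragment.length_bp} bp "
      f"({fragment.n_at} A-T pairs, {fragment.n_gc} G-C pairs)")
print(f"molecular weight: {stock.molecular_weight:,.1f} g/mol")
print(f"mean concentration: {stock.measurement.q_mean:.2f} ng/uL "
      f"(replicate CV {stock.measurement.cv:.2%})")
print(f"double-stranded copies: {stock.copies_per_ul:.3e} per uL")
print()
print("The copy number, not the ng/uL, is what downstream PCRs see: equal")
print("copies per target make primer-efficiency comparisons meaningful.")
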