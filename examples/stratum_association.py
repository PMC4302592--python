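"""Test whether escape from XCI is depleted in the old X stratum.

Uses the published opossum counts: 5 of 52 old-stratum genes escape,
against an expectation of 7 (scaled from the whole-X escape rate of
24/176).  The two-sided Fisher exact test (minimum-likelihood rule) on
observed-vs-expected shows no association: escape is as common in the
oldest stratum as on the X overall — unlike the human X, where the
conserved region escapes far less than the whole-X rate predicts.
"""

from xcitrio import escape_enrichment, expected_escapers, percent

table, expected, p = escape_enrichment(5, 52, 24, 176)
print(f"whole-X escape rate: {24}/{176} = {percent(24, 176)}%")
print(f"expected old-stratum escapers: {expected} of 52")
print(f"observed: 5 of 52")
print(f"contingency table: {table.rows}")
print(f"Fisher exact (two-sided): p = {p:.4f}")
print()
print(f"human X conserved region, for contrast: "
      f"{percent(30, 462, ndigits=1)}% escape observed vs "
      f"{expected_escapers(462, 0.15)}/462 expected at the whole-X rate of 15%")
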