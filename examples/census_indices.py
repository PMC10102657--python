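"""Landrace census diversity: a dominance-structured on-farm census.

Builds a small census in which one landrace dominates (as is typical for
a shifting-cultivation field where one favourite is planted widely) and
prints the standard diversity indices.
"""

from germdiv import LandraceCensus, diversity_indices

census = LandraceCensus(
    "jhum-field",
    [
        ("Rengama", 47),
        ("Tamachongkham", 36),
        ("Tasakrek", 12),
        ("minor-1", 1.67),
        ("minor-2", 1.67),
        ("minor-3", 1.66),
    ],
)

idx = diversity_indices(census)
print(f"site            : {idx.site_label}")
print(f"richness S      : {idx.richness}")
print(f"Simpson (1-sum p^2): {idx.simpson:.2f}")
print(f"Shannon H       : {idx.shannon:.2f}")
print(f"Pielou evenness : {idx.evenness:.2f}")
print()
print(
    "A Simpson value of "
    f"{idx.simpson:.2f} means two plants drawn at random belong to "
    "different landraces ~63% of the time; the low evenness reflects the "
    "dominance of a single landrace."
)
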