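"""Pathway over-representation of a divergent-gene foreground.

Reproduces the arithmetic of a classic over-representation table: a
foreground of 848 genes drawn against a 19,662-gene background, with one
small pathway strongly over-represented (9 observed vs 1.12 expected).
"""

from sweepscan.enrichment import (
    bonferroni,
    expected_count,
    overrepresentation_test,
)

background, foreground = 19662, 848
rows = [
    ("adrenaline/noradrenaline biosynthesis", 26, 9),
    ("axon guidance (netrin)", 38, 7),
    ("dopamine receptor signalling", 51, 8),
    ("GnRH receptor pathway", 225, 19),
]

pvals = []
print(f"{'pathway':40s} {'K':>4} {'obs':>4} {'exp':>6} {'p':>10}")
for name, size, observed in rows:
    exp = expected_count(background, size, foreground)
    p = overrepresentation_test(background, size, foreground, observed)
    pvals.append(p)
    print(f"{name:40s} {size:4d} {observed:4d} {exp:6.2f} {p:10.3g}")

adjusted = bonferroni(pvals)
print("\nBonferroni-adjusted p-values:",
      ", ".join(f"{p:.3g}" for p in adjusted))
print(
    "\n'exp' is sample_size * K / background — the expected number of\n"
    "pathway members in a random foreground of this size; p is the\n"
    "binomial upper tail P(X >= obs)."
)
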