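"""Per-site Weir & Cockerham Fst from genotype counts.

Builds a handful of two-population genotype configurations and prints the
variance components and theta-hat for each. A site where the populations
are fixed for opposite alleles gives theta = 1; identical configurations
give a non-positive estimate (the estimator is unbiased, not clamped).
"""

from sweepscan import wc_fst_site

configs = [
    ("fixed difference (67 dogs hom-alt vs 7 wolves hom-ref)",
     (0, 0, 67), (7, 0, 0)),
    ("strong differentiation", (0, 2, 2), (4, 0, 0)),
    ("identical in both populations", (10, 5, 5), (10, 5, 5)),
    ("monomorphic everywhere", (20, 0, 0), (7, 0, 0)),
]

for label, dogs, wolves in configs:
    a, b, c, theta = wc_fst_site(dogs, wolves)
    print(f"{label}:")
    print(f"  a={a:.4f}  b={b:.4f}  c={c:.4f}  theta={theta:.4f}")

print(
    "\n'a' is the among-population variance component; theta = a/(a+b+c).\n"
    "NaN marks sites where the estimator is undefined (no variation)."
)
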