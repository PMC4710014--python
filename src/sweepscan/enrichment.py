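"""Pathway over-representation of divergent-gene sets.

The sampling unit is the gene: given a background list of M genes of which
K belong to a pathway, and a foreground of n genes of which k are in the
pathway, the default statistic is the binomial upper tail
P(X >= k), X ~ Binomial(n, K/M) — the classic behaviour of pathway
over-representation tools. A hypergeometric (one-sided Fisher exact) mode
is available. Family-wise error is controlled by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

#: pseudo-pathway for genes with no annotation; excluded from testing and
#: from the Bonferroni test count
UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class PathwayTable:
    """Pathway membership over a background gene universe."""

    pathways: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"pathway {name!r} contains genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def background_size(self) -> int:
        return len(self.background)

    @classmethod
    def from_tsv(
        cls, path: str | Path, background: Iterable[str] | None = None
    ) -> "PathwayTable":
        """Two-column (pathway, gene) TSV. The background defaults to the
        union of all listed genes."""
        pathways: dict[str, set[str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pathway, gene = line.split("\t")
            pathways.setdefault(pathway, set()).add(gene)
        bg = frozenset(background) if background is not None else frozenset(
            g for genes in pathways.values() for g in genes
        )
        return cls({k: frozenset(v) for k, v in pathways.items()}, bg)


def expected_count(
    background_size: int, pathway_size: int, sample_size: int
) -> float:
    """Expected number of pathway genes in a random sample of
    ``sample_size`` genes from the background."""
    if background_size == 0:
        raise ValueError("background_size must be positive")
    if pathway_size > background_size or sample_size > background_size:
        raise ValueError("pathway and sample must fit inside the background")
    return sample_size * pathway_size / background_size


def overrepresentation_test(
    background_size: int,
    pathway_size: int,
    sample_size: int,
    observed: int,
    mode: str = "binomial",
) -> float:
    """One-sided p-value for seeing >= ``observed`` pathway genes.

    mode="binomial": P(X >= k), X ~ Bin(sample_size, pathway_size/background).
    mode="hypergeometric": one-sided Fisher exact tail.
    """
    if observed > pathway_size:
        raise ValueError("observed cannot exceed pathway size")
    if observed > sample_size:
        raise ValueError("observed cannot exceed sample size")
    if observed <= 0:
        return 1.0
    if mode == "binomial":
        p = pathway_size / background_size
        return float(stats.binom.sf(observed - 1, sample_size, p))
    if mode == "hypergeometric":
        return float(
            stats.hypergeom.sf(
                observed - 1, background_size, pathway_size, sample_size
            )
        )
    raise ValueError(f"unknown mode {mode!r}")


def bonferroni(pvalues: Sequence[float]) -> list[float]:
    """min(1, p * m) for m tests."""
    m = len(pvalues)
    return [min(1.0, p * m) for p in pvalues]


def enrichment_table(
    table: PathwayTable,
    foreground: Iterable[str],
    mode: str = "binomial",
) -> pd.DataFrame:
    """Per-pathway over-representation results, most significant first.

    Columns mirror the classic tool layout: reference count, observed count,
    expected, fold enrichment, direction (+/-), raw and Bonferroni-adjusted
    p. The Unclassified pseudo-pathway, if present, is reported with counts
    but no p-value and does not contribute to the correction.
    """
    fg = frozenset(foreground)
    stray = fg - table.background
    if stray:
        raise ValueError(
            f"foreground genes missing from background: {sorted(stray)[:5]}"
        )
    n = len(fg)
    M = table.background_size
    rows = []
    tested = [name for name in table.pathways if name != UNCLASSIFIED]
    for name in tested:
        genes = table.pathways[name]
        K = len(genes)
        k = len(genes & fg)
        expected = expected_count(M, K, n)
        rows.append(
            {
                "pathway": name,
                "ref_count": K,
                "observed": k,
                "expected": expected,
                "fold_enrichment": (k / expected) if expected > 0 else float("nan"),
                "direction": "+" if k >= expected else "-",
                "p_value": overrepresentation_test(M, K, n, k, mode=mode),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = bonferroni(df["p_value"].tolist())
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    if UNCLASSIFIED in table.pathways:
        genes = table.pathways[UNCLASSIFIED]
        K, k = len(genes), len(genes & fg)
        extra = pd.DataFrame(
            [
                {
                    "pathway": UNCLASSIFIED,
                    "ref_count": K,
                    "observed": k,
                    "expected": expected_count(M, K, n),
                    "fold_enrichment": float("nan"),
                    "direction": "-",
                    "p_value": float("nan"),
                    "p_adjusted": float("nan"),
                }
            ]
        )
        df = pd.concat([df, extra], ignore_index=True)
    return df
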