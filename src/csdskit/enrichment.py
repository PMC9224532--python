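"""Over-representation analysis (ORA) with an enrichment ratio.

For a significant-gene list of size n drawn from a genome of N genes, a
gene-ontology-style family of M genes with m of the significant genes
mapped to it has enrichment ratio

    ER = (m * N) / (M * n)

i.e. the observed mapped count over its expectation under random draws.
Statistical over-representation is scored with the upper-tail
hypergeometric probability P(X >= m).  Defaults follow the reference
design: n = 25 significant genes and a mouse genome of N = 18,985.

Note the genome-wide universe is anticonservative when the assay itself
covered only a small gene panel; the universe is configurable and the
default is reported in every result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DEFAULT_GENOME_SIZE",
    "DEFAULT_SIGNIFICANT_N",
    "GeneSetCollection",
    "RedundancyMap",
    "enrichment_ratio",
    "hypergeom_test",
    "run_ora",
    "redundancy_map",
]

logger = logging.getLogger(__name__)

DEFAULT_GENOME_SIZE = 18_985  # approximate Mus musculus gene count
DEFAULT_SIGNIFICANT_N = 25


@dataclass
class GeneSetCollection:
    """GO-style gene families over a genome of ``genome_size`` genes."""

    families: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    genome_size: int = DEFAULT_GENOME_SIZE

    def __post_init__(self):
        for fam, members in self.families.items():
            if not members:
                raise ValueError(f"family {fam!r} is empty")
            self.families[fam] = frozenset(members)
        largest = max(len(m) for m in self.families.values())
        if self.genome_size < largest:
            raise ValueError("genome_size smaller than the largest family")

    @classmethod
    def from_gmt(cls, path, genome_size: int = DEFAULT_GENOME_SIZE
                 ) -> "GeneSetCollection":
        """Read a standard GMT file (name, description, tab-sep members)."""
        families, names = {}, {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            fam, desc, *members = fields
            families[fam] = frozenset(g for g in members if g)
            names[fam] = desc
        return cls(families=families, names=names, genome_size=genome_size)

    def to_gmt(self, path) -> None:
        lines = [
            "\t".join([fam, self.names.get(fam, fam), *sorted(members)])
            for fam, members in self.families.items()
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def enrichment_ratio(
    m: int,
    M: int,
    n: int = DEFAULT_SIGNIFICANT_N,
    N: int = DEFAULT_GENOME_SIZE,
) -> float:
    """ER = (m*N)/(M*n): observed over expected mapped genes; 0 when m=0."""
    if M <= 0 or n <= 0:
        raise ZeroDivisionError("ER undefined for an empty family or list")
    if not (0 <= m <= min(M, n)) or M > N or n > N:
        raise ValueError(f"inconsistent counts m={m}, M={M}, n={n}, N={N}")
    if m == 0:
        return 0.0
    return (m * N) / (M * n)


def hypergeom_test(m: int, M: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(X >= m), X ~ Hypergeom(N, M, n)."""
    if not (0 <= m <= min(M, n)) or M > N or n > N or min(M, n, N) < 0:
        raise ValueError(f"inconsistent margins m={m}, M={M}, n={n}, N={N}")
    if m == 0:
        return 1.0
    return float(sps.hypergeom.sf(m - 1, N, M, n))


def run_ora(
    significant_genes,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """ORA of a significant-gene set against every family in a collection.

    Returns one row per family with m, M, n, N, ER and the hypergeometric
    p, sorted by p ascending then ER descending; a ``significant`` flag
    marks p < alpha (on BH-adjusted p when ``bh``).  Genes absent from
    every family are listed in the frame's ``attrs['unmapped']``.
    """
    sig = frozenset(significant_genes)
    if not sig:
        raise ValueError("significant gene set is empty")
    if not collection.families:
        raise ValueError("empty gene-set collection")
    n = len(sig)
    N = collection.genome_size
    logger.info("ORA universe: N=%d genes (configurable; genome-wide "
                "default is anticonservative for small assay panels)", N)
    rows = []
    for fam, members in collection.families.items():
        m = len(sig & members)
        M = len(members)
        rows.append({
            "family": fam,
            "name": collection.names.get(fam, fam),
            "m": m, "M": M, "n": n, "N": N,
            "ER": enrichment_ratio(m, M, n, N),
            "p": hypergeom_test(m, M, n, N),
        })
    table = pd.DataFrame(rows).sort_values(
        ["p", "ER"], ascending=[True, False], kind="mergesort"
    ).set_index("family")
    if bh:
        p = table["p"].to_numpy()
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 1.0
        for rank in range(p.size, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * p.size / rank)
            adj[i] = running
        table["p_adjusted"] = adj
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    mapped = frozenset().union(*collection.families.values())
    table.attrs["unmapped"] = sorted(sig - mapped)
    return table


@dataclass
class RedundancyMap:
    """Gene membership counts and inclusion relations over top-K families."""

    top_k: int
    gene_counts: pd.Series  # significant gene -> number of top-K families
    membership: pd.DataFrame  # genes x families boolean
    inclusions: list[tuple[str, str]]  # (A, B) with members(A) <= members(B)


def redundancy_map(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    significant_genes,
    top_k: int = 50,
) -> RedundancyMap:
    """Map significant genes across the top-K enriched families.

    Counts, for each significant gene, how many of the ``top_k``
    best-ranked families contain it (a gene in none is "unmapped",
    0/top_k), and flags inclusion relations A <= B among those families;
    identical families are flagged in both directions.
    """
    if top_k > len(results):
        raise ValueError("top_k exceeds the number of scored families")
    top = results.index[:top_k].tolist()
    sig = sorted(frozenset(significant_genes))
    membership = pd.DataFrame(
        {fam: [g in collection.families[fam] for g in sig] for fam in top},
        index=sig,
    )
    counts = membership.sum(axis=1)
    inclusions = [
        (a, b)
        for a in top
        for b in top
        if a != b and collection.families[a] <= collection.families[b]
    ]
    return RedundancyMap(
        top_k=top_k,
        gene_counts=counts,
        membership=membership,
        inclusions=inclusions,
    )
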