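"""Shared k-mer analysis of inter-gene sequence identity.

Homologous gene families defeat short-read alignment exactly where genes
share long identical subsequences.  Transforming each gene's alleles into the
set of all distinct k-mers at read-scale k (50/150/250) and intersecting
those sets across genes quantifies how much of a gene's sequence space is
non-diagnostic at a given read length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allele_db import AlleleDatabase, AlleleSequence


def distinct_kmers(alleles: list[AlleleSequence] | list[str], k: int) -> set[str]:
    """Union of all length-``k`` substrings over the alleles of one gene.

    Windows containing ``N`` are excluded: an unknown base cannot certify
    sequence identity.  K-mers are taken on the given strand only (allele
    sequences are co-oriented).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: set[str] = set()
    for a in alleles:
        seq = a.seq if isinstance(a, AlleleSequence) else a
        n = len(seq)
        if n < k:
            continue
        if "N" not in seq:
            out.update(seq[i:i + k] for i in range(n - k + 1))
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        bad = (arr == ord("N")).astype(np.int32)
        # window contains N iff the running count differs across the window
        cs = np.concatenate([[0], np.cumsum(bad)])
        ok = cs[k:] - cs[:-k] == 0
        out.update(seq[i:i + k] for i in np.flatnonzero(ok))
    return out


@dataclass
class KmerSharingMatrix:
    """Pairwise shared distinct-k-mer counts and per-gene proportions."""

    k: int
    genes: list[str]
    totals: dict[str, int]                      # distinct k-mers per gene
    shared: pd.DataFrame                        # genes x genes shared counts
    shared_with_any: dict[str, int]             # |kmers(g) & union(others)|

    def proportion(self, gene_a: str, gene_b: str) -> float:
        t = self.totals[gene_a]
        return self.shared.loc[gene_a, gene_b] / t if t else 0.0

    def proportion_with_any(self, gene: str) -> float:
        t = self.totals[gene]
        return self.shared_with_any[gene] / t if t else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (gene_a, gene_b, k, shared, total_a, proportion_a)."""
        rows = []
        for ga in self.genes:
            for gb in self.genes:
                if ga == gb:
                    continue
                rows.append({
                    "gene_a": ga, "gene_b": gb, "k": self.k,
                    "shared": int(self.shared.loc[ga, gb]),
                    "total_a": self.totals[ga],
                    "proportion_a": self.proportion(ga, gb),
                })
        return pd.DataFrame(rows)


def sharing_matrix(db: AlleleDatabase, k: int, *, by: str = "group") -> KmerSharingMatrix:
    """Shared distinct k-mers between every pair of genes (or major groups).

    The aggregate statistic for gene g is ``|kmers(g) & union(kmers(h))|``
    over all other genes h, mirroring the per-gene "shared with any other
    gene" bar; the matrix holds the pairwise intersections.
    """
    units = db.group_names if by == "group" else sorted(db.groups)
    if len(units) < 2:
        raise ValueError("sharing_matrix needs at least two genes")
    kmers: dict[str, set[str]] = {}
    for u in units:
        alleles = (
            db.alleles_of_group(u) if by == "group"
            else [a for a in db.alleles.values() if a.gene == u]
        )
        kmers[u] = distinct_kmers(alleles, k)

    shared = pd.DataFrame(0, index=units, columns=units, dtype=int)
    for i, ga in enumerate(units):
        for gb in units[i + 1:]:
            n = len(kmers[ga] & kmers[gb])
            shared.loc[ga, gb] = n
            shared.loc[gb, ga] = n
    shared_any = {}
    for ga in units:
        union_others: set[str] = set()
        for gb in units:
            if gb != ga:
                union_others |= kmers[gb]
        shared_any[ga] = len(kmers[ga] & union_others)
    return KmerSharingMatrix(
        k=k, genes=list(units),
        totals={u: len(kmers[u]) for u in units},
        shared=shared, shared_with_any=shared_any,
    )
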