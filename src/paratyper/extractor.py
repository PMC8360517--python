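"""Locus read extraction: pre-filter sample reads to the target gene family.

Whole-genome or target-capture FASTQ is filtered by a permissive alignment
against full-haplotype reference sequences of the locus; a read pair is
retained when at least one mate places on any haplotype.  The extractor cap
(10 mismatches per 150 bp) is deliberately looser than the genotyping
aligner so that reads from divergent alleles are not lost -- filtration is
recall-critical.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .allele_db import STATE_NATIVE, AlleleSequence, Feature
from .align_core import AlignParams, ReadBatch, ReferenceIndex, align
from .simulate import ReadPairBatch

EXTRACTOR_PARAMS = AlignParams(seed_len=31, seed_stride=10, max_mismatch=10)


def haplotype_references(seqs: dict[str, str]) -> list[AlleleSequence]:
    """Wrap raw haplotype sequences as reference records."""
    refs = []
    for name, seq in sorted(seqs.items()):
        refs.append(AlleleSequence(
            gene=name, major_group=name, allele_name=f"{name}*0010101",
            seq=seq,
            states=np.full(len(seq), STATE_NATIVE, dtype=np.uint8),
            features=(Feature("gene", 0, len(seq)),),
        ))
    return refs


def load_haplotype_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class ExtractionResult:
    batch: ReadPairBatch
    n_input_pairs: int
    n_retained_pairs: int

    @property
    def retention(self) -> float:
        return self.n_retained_pairs / self.n_input_pairs if self.n_input_pairs else 0.0


def extract_reads(
    pairs: ReadPairBatch,
    haplotype_refs: Sequence[AlleleSequence] | ReferenceIndex,
    params: AlignParams | None = None,
) -> ExtractionResult:
    """Retain read pairs with at least one mate aligning to any haplotype.

    Pair integrity is preserved: mates are kept or dropped together, and the
    output is a subset of the input in input order.
    """
    index = (
        haplotype_refs if isinstance(haplotype_refs, ReferenceIndex)
        else ReferenceIndex(haplotype_refs, params or EXTRACTOR_PARAMS)
    )
    n = len(pairs)
    if n == 0:
        return ExtractionResult(ReadPairBatch([], [], []), 0, 0)
    reads = ReadBatch.from_pairs(pairs.names, pairs.r1, pairs.r2)
    result = align(reads, index, mode="any", params=params or EXTRACTOR_PARAMS)
    hit_rows = np.unique(result.read_rows)
    keep = np.zeros(n, dtype=bool)
    # row i is mate 1 of pair i; row i+n is mate 2
    keep[hit_rows[hit_rows < n]] = True
    keep[hit_rows[hit_rows >= n] - n] = True
    idx = np.flatnonzero(keep)
    out = ReadPairBatch(
        names=[pairs.names[i] for i in idx],
        r1=[pairs.r1[i] for i in idx],
        r2=[pairs.r2[i] for i in idx],
    )
    return ExtractionResult(out, n_input_pairs=n, n_retained_pairs=len(idx))


# -- FASTQ plumbing ---------------------------------------------------------

def read_fastq_pair(path1: str | Path, path2: str | Path) -> ReadPairBatch:
    """Load a FASTQ pair; mate files must list the same reads in order."""
    def _iter(path):
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(str(path), "rt") as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq.upper()

    names: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    for (n1, s1), (n2, s2) in zip(_iter(path1), _iter(path2), strict=True):
        base1 = n1[:-2] if n1.endswith(("/1", "/2")) else n1
        base2 = n2[:-2] if n2.endswith(("/1", "/2")) else n2
        if base1 != base2:
            raise ValueError(f"mismatched mate files: {n1!r} vs {n2!r}")
        names.append(base1)
        r1.append(s1)
        r2.append(s2)
    return ReadPairBatch(names, r1, r2)


def write_retention_table(result: ExtractionResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("n_input_pairs\tn_retained_pairs\tretention\n")
        fh.write(
            f"{result.n_input_pairs}\t{result.n_retained_pairs}\t"
            f"{result.retention:.6f}\n"
        )
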