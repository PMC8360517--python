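"""Alignment backend: exhaustive/best read placement, unique-read
classification and depth-table construction.

The built-in aligner is a seeded, ungapped matcher designed for desk-scale
references (tens to hundreds of allele sequences): 31-mer seeds are indexed
at every reference position, query seeds are taken at a short stride, and
each candidate diagonal is verified by vectorized mismatch counting with a
per-read mismatch cap.  Uncharacterized reference positions (``N``) match
any base at zero penalty.  In *exhaustive* mode every placement within the
mismatch cap is recorded; in *best* mode only the top-scoring placement set
is kept.  An adapter for standard SAM from an external aligner provides the
same record stream for production-scale data.

Placements of alleles are projected onto the gene/major-group coordinate
frame (the columns of the gene's extended multiple sequence alignment) to
build per-group depth tables spanning the -1000 bp 5'UTR through the
+1000 bp 3'UTR, with independent counters for A, C, G, T, deletion and
insertion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .allele_db import AlleleDatabase, AlleleSequence, ReferenceSet

_N = ord("N")
_PAD = ord("X")
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNX", b"TGCANX"):
    _COMP[_a] = _b

#: depth-table variant row order
VARIANTS = ("A", "C", "G", "T", "-", "+")
_VAR_INDEX = {ord(v): i for i, v in enumerate("ACGT")}
_BASE_ROW = np.full(256, -1, dtype=np.int8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_ROW[_a] = _i


@dataclass
class AlignParams:
    """Aligner tuning: 31-mer seeds at stride 10, 6 mismatches per 150 bp.

    The seed stride guarantees full sensitivity up to 3 mismatches for
    150-200 bp reads (pigeonhole over overlapping seeds); beyond that,
    sensitivity is near-complete at sequencing error rates.
    """

    seed_len: int = 31
    seed_stride: int = 10
    max_mismatch: int = 6


@dataclass
class ReadBatch:
    """Flattened reads: one row per mate, fixed-width encoded matrix."""

    names: list[str]
    mates: np.ndarray          # int8, 1 or 2
    seqs: np.ndarray           # (n, read_len) uint8
    lengths: np.ndarray        # int32 actual lengths (rows padded with X)

    @classmethod
    def from_sequences(
        cls, names: Sequence[str], seqs: Sequence[str],
        mates: Sequence[int] | None = None,
    ) -> "ReadBatch":
        n = len(seqs)
        width = max((len(s) for s in seqs), default=0)
        mat = np.full((n, width), _PAD, dtype=np.uint8)
        lens = np.zeros(n, dtype=np.int32)
        for i, s in enumerate(seqs):
            b = np.frombuffer(s.encode(), dtype=np.uint8)
            mat[i, :len(b)] = b
            lens[i] = len(b)
        m = np.asarray(mates if mates is not None else [1] * n, dtype=np.int8)
        return cls(names=list(names), mates=m, seqs=mat, lengths=lens)

    @classmethod
    def from_pairs(cls, names: Sequence[str], r1: Sequence[str], r2: Sequence[str]) -> "ReadBatch":
        return cls.from_sequences(
            list(names) + list(names), list(r1) + list(r2),
            [1] * len(names) + [2] * len(names),
        )

    def __len__(self) -> int:
        return len(self.names)

    def sequence(self, row: int) -> str:
        return self.seqs[row, :self.lengths[row]].tobytes().decode()


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-allele placement with per-position differences."""

    read_id: str
    mate: int
    reference: str
    offset: int
    strand: str
    n_mismatch: int
    substitutions: tuple[tuple[int, str], ...]  # (ref position, read base)

    @property
    def score(self) -> int:
        return -self.n_mismatch


class ReferenceIndex:
    """Seed index over a reference allele set (every position indexed)."""

    def __init__(self, refs: ReferenceSet | Sequence[AlleleSequence],
                 params: AlignParams | None = None):
        alleles = tuple(refs.alleles if isinstance(refs, ReferenceSet) else refs)
        if not alleles:
            raise ValueError("empty reference set")
        self.params = params or AlignParams()
        self.alleles = alleles
        self.names = [a.allele_name for a in alleles]
        self.groups = [a.major_group for a in alleles]
        k = self.params.seed_len
        pad = 2 * max(200, k)
        parts = [np.full(pad, _PAD, dtype=np.uint8)]
        starts = []
        cursor = pad
        for a in alleles:
            starts.append(cursor)
            arr = np.frombuffer(a.seq.encode(), dtype=np.uint8)
            parts.append(arr)
            cursor += len(arr)
            parts.append(np.full(pad, _PAD, dtype=np.uint8))
            cursor += pad
        self.concat = np.concatenate(parts)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray([len(a.seq) for a in alleles], dtype=np.int64)

        seeds: dict[bytes, list[int]] = {}
        data = self.concat.tobytes()
        bad = (self.concat == _N) | (self.concat == _PAD)
        # positions whose k-window is clean (no N, no pad)
        cs = np.concatenate([[0], np.cumsum(bad.astype(np.int32))])
        ok = np.flatnonzero(cs[k:] - cs[:-k] == 0)
        for p in ok:
            key = data[p:p + k]
            bucket = seeds.get(key)
            if bucket is None:
                seeds[key] = [int(p)]
            else:
                bucket.append(int(p))
        self.seeds = {key: np.asarray(v, dtype=np.int64) for key, v in seeds.items()}

    def locate(self, global_pos: int) -> tuple[int, int]:
        ref = int(np.searchsorted(self.starts, global_pos, side="right") - 1)
        return ref, int(global_pos - self.starts[ref])


@dataclass
class AlignmentResult:
    """Column-oriented placement table over a ReadBatch and a ReferenceIndex."""

    index: ReferenceIndex
    reads: ReadBatch
    read_rows: np.ndarray    # int32 row into reads
    ref_ids: np.ndarray      # int32 index into index.alleles
    offsets: np.ndarray      # int32 position on the reference
    strands: np.ndarray      # int8 +1 / -1
    mismatches: np.ndarray   # int16

    def __len__(self) -> int:
        return len(self.read_rows)

    def aligned_read(self, i: int) -> np.ndarray:
        row = self.read_rows[i]
        seq = self.reads.seqs[row, :self.reads.lengths[row]]
        return seq if self.strands[i] > 0 else _COMP[seq][::-1]

    def records(self) -> Iterator[AlignmentRecord]:
        for i in range(len(self)):
            ref = self.index.alleles[self.ref_ids[i]]
            rarr = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
            aligned = self.aligned_read(i)
            off = int(self.offsets[i])
            window = rarr[off:off + len(aligned)]
            diff = np.flatnonzero((window != aligned) & (window != _N))
            yield AlignmentRecord(
                read_id=self.reads.names[self.read_rows[i]],
                mate=int(self.reads.mates[self.read_rows[i]]),
                reference=ref.allele_name,
                offset=off,
                strand="+" if self.strands[i] > 0 else "-",
                n_mismatch=int(self.mismatches[i]),
                substitutions=tuple(
                    (off + int(p), chr(aligned[p])) for p in diff
                ),
            )

    def to_frame(self):
        """Placement table as a DataFrame (read, mate, reference, offset,
        strand, mismatches) — the documented TSV serialization."""
        import pandas as pd

        return pd.DataFrame({
            "read": [self.reads.names[r] for r in self.read_rows],
            "mate": self.reads.mates[self.read_rows],
            "reference": [self.index.names[i] for i in self.ref_ids],
            "offset": self.offsets,
            "strand": np.where(self.strands > 0, "+", "-"),
            "mismatches": self.mismatches,
        })

    def subset(self, keep: np.ndarray) -> "AlignmentResult":
        return AlignmentResult(
            index=self.index, reads=self.reads,
            read_rows=self.read_rows[keep], ref_ids=self.ref_ids[keep],
            offsets=self.offsets[keep], strands=self.strands[keep],
            mismatches=self.mismatches[keep],
        )

    def restrict_to_alleles(self, allele_names: Iterable[str]) -> "AlignmentResult":
        """Placements on a subset of the reference.

        Because exhaustive mode records *every* qualified placement, an
        exhaustive alignment restricted to a reference subset equals an
        exhaustive alignment against that subset.
        """
        wanted = set(allele_names)
        mask = np.isin(
            self.ref_ids, [i for i, n in enumerate(self.index.names) if n in wanted]
        )
        return self.subset(mask)

    def best_only(self) -> "AlignmentResult":
        """Keep, per read row, only the minimum-mismatch placements."""
        if len(self) == 0:
            return self
        order = np.lexsort((self.mismatches, self.read_rows))
        rr, mm = self.read_rows[order], self.mismatches[order]
        first = np.concatenate([[True], rr[1:] != rr[:-1]])
        best = mm[np.flatnonzero(first)]
        # map each record to its read's best score
        group_id = np.cumsum(first) - 1
        keep_sorted = mm == best[group_id]
        keep = np.zeros(len(self), dtype=bool)
        keep[order] = keep_sorted
        return self.subset(keep)


def align(
    reads: ReadBatch,
    refs: ReferenceSet | ReferenceIndex | Sequence[AlleleSequence],
    mode: str = "exhaustive",
    params: AlignParams | None = None,
) -> AlignmentResult:
    """Align every read against the reference set.

    ``exhaustive`` records every placement within the mismatch cap;
    ``best`` keeps only the top-scoring placement set per read; ``any``
    stops at the first qualifying placement per read (used for permissive
    filtering where only presence matters).  Reads shorter than the seed
    length are never placed.
    """
    if mode not in ("exhaustive", "best", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    index = refs if isinstance(refs, ReferenceIndex) else ReferenceIndex(refs, params)
    p = index.params if params is None else params
    k, stride, cap = p.seed_len, p.seed_stride, p.max_mismatch

    concat = index.concat
    seeds = index.seeds
    starts, lengths = index.starts, index.lengths
    out_rows: list[np.ndarray] = []
    out_refs: list[np.ndarray] = []
    out_pos: list[np.ndarray] = []
    out_strand: list[np.ndarray] = []
    out_mm: list[np.ndarray] = []

    n_reads = len(reads)
    seq_mat = reads.seqs
    lens = reads.lengths
    any_mode = mode == "any"
    for row in range(n_reads):
        rl = int(lens[row])
        if rl < k:
            continue
        fwd = seq_mat[row, :rl]
        offs = list(range(0, rl - k + 1, stride))
        if offs[-1] != rl - k:
            offs.append(rl - k)
        placed = False
        for strand, arr in ((1, fwd), (-1, _COMP[fwd][::-1])):
            if placed and any_mode:
                break
            data = arr.tobytes()
            cand: set[int] = set()
            for off in offs:
                hits = seeds.get(data[off:off + k])
                if hits is not None:
                    for h in hits:
                        cand.add(int(h) - off)
            if not cand:
                continue
            cpos = np.fromiter(cand, dtype=np.int64, count=len(cand))
            win = concat[cpos[:, None] + np.arange(rl)]
            mm = ((win != arr) & (win != _N)).sum(axis=1)
            ok = np.flatnonzero(mm <= cap)
            if len(ok) == 0:
                continue
            cpos, mm = cpos[ok], mm[ok]
            ridx = np.searchsorted(starts, cpos, side="right") - 1
            local = cpos - starts[ridx]
            inside = (local >= 0) & (local + rl <= lengths[ridx])
            if not inside.all():
                cpos, mm, ridx, local = (
                    cpos[inside], mm[inside], ridx[inside], local[inside]
                )
            if len(cpos) == 0:
                continue
            if any_mode:
                cpos, mm, ridx, local = cpos[:1], mm[:1], ridx[:1], local[:1]
                placed = True
            n = len(cpos)
            out_rows.append(np.full(n, row, dtype=np.int32))
            out_refs.append(ridx.astype(np.int32))
            out_pos.append(local.astype(np.int32))
            out_strand.append(np.full(n, strand, dtype=np.int8))
            out_mm.append(mm.astype(np.int16))

    if out_rows:
        result = AlignmentResult(
            index=index, reads=reads,
            read_rows=np.concatenate(out_rows),
            ref_ids=np.concatenate(out_refs),
            offsets=np.concatenate(out_pos),
            strands=np.concatenate(out_strand),
            mismatches=np.concatenate(out_mm),
        )
    else:
        empty = np.empty(0, dtype=np.int32)
        result = AlignmentResult(
            index=index, reads=reads, read_rows=empty,
            ref_ids=empty.copy(), offsets=empty.copy(),
            strands=np.empty(0, dtype=np.int8),
            mismatches=np.empty(0, dtype=np.int16),
        )
    return result.best_only() if mode == "best" else result


# ---------------------------------------------------------------------------
# Unique-read classification
# ---------------------------------------------------------------------------

@dataclass
class UniqueClassification:
    unique_rows: dict[str, np.ndarray]   # group -> read rows unique to it
    cross_rows: np.ndarray               # read rows with placements in >1 group
    counts: dict[str, int]

    def n_cross(self) -> int:
        return len(self.cross_rows)


def classify_unique(
    result: AlignmentResult, grouping: Mapping[str, str] | None = None
) -> UniqueClassification:
    """Partition aligned reads into per-group unique sets and a cross set.

    A read is unique to group G iff *all* its recorded placements lie on
    alleles of G.  ``grouping`` maps allele name -> group and defaults to
    each reference allele's own major group.
    """
    if grouping is None:
        group_of_ref = np.asarray(
            [index_group for index_group in result.index.groups]
        )
    else:
        group_of_ref = np.asarray(
            [grouping[name] for name in result.index.names]
        )
    group_names, gcodes = np.unique(group_of_ref, return_inverse=True)
    if len(result) == 0:
        return UniqueClassification(
            unique_rows={g: np.empty(0, dtype=np.int64) for g in group_names},
            cross_rows=np.empty(0, dtype=np.int64),
            counts={g: 0 for g in group_names},
        )
    rec_groups = gcodes[result.ref_ids]
    pairs = result.read_rows.astype(np.int64) * len(group_names) + rec_groups
    uniq_pairs = np.unique(pairs)
    pair_reads = uniq_pairs // len(group_names)
    pair_groups = uniq_pairs % len(group_names)
    reads_u, n_groups = np.unique(pair_reads, return_counts=True)
    single = n_groups == 1
    cross_rows = reads_u[~single]
    unique_rows: dict[str, np.ndarray] = {}
    single_reads = reads_u[single]
    # group of each single-group read: first (only) pair entry
    first_idx = np.searchsorted(pair_reads, single_reads)
    single_groups = pair_groups[first_idx]
    for gi, g in enumerate(group_names):
        unique_rows[g] = single_reads[single_groups == gi]
    counts = {g: int(len(unique_rows[g])) for g in group_names}
    return UniqueClassification(
        unique_rows=unique_rows, cross_rows=cross_rows, counts=counts
    )


def filter_proper_pairs(
    result: AlignmentResult, window: tuple[int, int] = (100, 1000)
) -> AlignmentResult:
    """Drop placements whose aligned mate contradicts fragment geometry.

    A placement is kept if the other mate of the same read has no placements
    at all (unpaired placements are allowed) or has one on the same reference
    with opposite strand within the fragment window.
    """
    reads = result.reads
    n_pairs = len(reads) // 2 if (np.sort(np.unique(reads.mates)) == [1, 2]).all() else None
    if n_pairs is None or len(result) == 0:
        return result
    # pair id: same name index for mate1 (row) and mate2 (row + n_pairs)
    pair_of_row = np.where(
        np.arange(len(reads)) < n_pairs, np.arange(len(reads)),
        np.arange(len(reads)) - n_pairs,
    )
    pid = pair_of_row[result.read_rows]
    mate = reads.mates[result.read_rows]
    keep = np.ones(len(result), dtype=bool)
    by_pair: dict[int, list[int]] = {}
    for i, p in enumerate(pid):
        by_pair.setdefault(int(p), []).append(i)
    lo, hi = window
    for p, idxs in by_pair.items():
        m1 = [i for i in idxs if mate[i] == 1]
        m2 = [i for i in idxs if mate[i] == 2]
        if not m1 or not m2:
            continue
        for side, other in ((m1, m2), (m2, m1)):
            for i in side:
                ok = False
                for j in other:
                    if (result.ref_ids[i] == result.ref_ids[j]
                            and result.strands[i] != result.strands[j]):
                        span = abs(int(result.offsets[j]) - int(result.offsets[i]))
                        if lo <= span + 150 and span + 150 <= hi:
                            ok = True
                            break
                if not ok:
                    keep[i] = False
    return result.subset(keep)


# ---------------------------------------------------------------------------
# Group coordinate frames and depth tables
# ---------------------------------------------------------------------------

@dataclass
class GroupFrame:
    """Coordinate frame of one gene/major group: extended MSA columns."""

    group: str
    n_cols: int
    body_start: int                       # column of the first gene-body base
    colmaps: dict[str, np.ndarray]        # allele -> ungapped pos -> column
    symbols: dict[str, np.ndarray]        # allele -> per-column byte (ACGTN-)
    states: dict[str, np.ndarray]         # allele -> per-column state

    def signed_positions(self) -> np.ndarray:
        return np.arange(self.n_cols) - self.body_start


def group_frame(db: AlleleDatabase, group: str) -> GroupFrame:
    """Build the group frame from the (imputed, extended) gene MSA."""
    gene = db.gene_of_group(group)
    msa = db.msas[gene]
    members = [a.allele_name for a in db.alleles_of_group(group)]
    members = [m for m in members if m in msa.rows]
    if not members:
        raise ValueError(f"group {group}: no MSA rows")
    colmaps = {m: msa.column_map(m) for m in members}
    symbols = {
        m: np.frombuffer(msa.rows[m].encode(), dtype=np.uint8) for m in members
    }
    states = {
        m: msa.row_states.get(
            m, np.full(msa.n_cols, 1, dtype=np.uint8)
        ) for m in members
    }
    rep = db.alleles[members[0]]
    try:
        utr5_end = rep.feature_of_kind("5UTR").end
    except KeyError:
        utr5_end = 0
    body_start = (
        int(colmaps[members[0]][utr5_end]) if 0 < utr5_end < len(rep.seq) else 0
    )
    return GroupFrame(
        group=group, n_cols=msa.n_cols, body_start=body_start,
        colmaps=colmaps, symbols=symbols, states=states,
    )


@dataclass
class DepthTable:
    """Per-position variant depth counts over a group frame."""

    group: str
    counts: np.ndarray        # (6, n_cols) int32, rows follow VARIANTS
    body_start: int
    n_reads: int = 0
    n_dropped: int = 0        # placements outside the frame

    def total_depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def build_depth_table(
    result: AlignmentResult,
    frame: GroupFrame,
    read_rows: np.ndarray | None = None,
) -> DepthTable:
    """Accumulate per-position variant depths for one group.

    Each read contributes once: among its placements on the group's alleles
    the minimum-mismatch one is projected onto the frame (ties break on
    allele name order then offset).  Frame columns where the placed allele
    has a gap are counted as deletions.
    """
    member_ids = [
        i for i, n in enumerate(result.index.names) if n in frame.colmaps
    ]
    counts = np.zeros((6, frame.n_cols), dtype=np.int32)
    if not member_ids or len(result) == 0:
        return DepthTable(frame.group, counts, frame.body_start)
    in_group = np.isin(result.ref_ids, member_ids)
    if read_rows is not None:
        in_group &= np.isin(result.read_rows, read_rows)
    idxs = np.flatnonzero(in_group)
    if len(idxs) == 0:
        return DepthTable(frame.group, counts, frame.body_start)
    # order placements by (read, mismatches, ref name, offset); keep first per read
    sub = result.subset(idxs)
    name_rank = np.argsort(np.argsort(result.index.names))  # identity mapping helper
    order = np.lexsort(
        (sub.offsets, name_rank[sub.ref_ids], sub.mismatches, sub.read_rows)
    )
    rr = sub.read_rows[order]
    first = np.concatenate([[True], rr[1:] != rr[:-1]])
    chosen = order[first]

    n_dropped = 0
    for i in chosen:
        ref_name = result.index.names[sub.ref_ids[i]]
        colmap = frame.colmaps[ref_name]
        off = int(sub.offsets[i])
        aligned = sub.aligned_read(i)
        rl = len(aligned)
        if off + rl > len(colmap):
            n_dropped += 1
            continue
        cols = colmap[off:off + rl]
        rows_ = _BASE_ROW[aligned]
        valid = rows_ >= 0
        np.add.at(counts, (rows_[valid], cols[valid]), 1)
        span = cols[-1] - cols[0] + 1
        if span > rl:  # allele gaps inside the placement -> deletions
            covered = np.zeros(span, dtype=bool)
            covered[cols - cols[0]] = True
            gap_cols = cols[0] + np.flatnonzero(~covered)
            counts[4, gap_cols] += 1
    return DepthTable(
        frame.group, counts, frame.body_start,
        n_reads=int(len(chosen) - n_dropped), n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------

def write_sam(result: AlignmentResult, path: str | Path) -> None:
    """Serialize placements as SAM (one line per placement, NM tag set)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": n, "LN": int(l)}
            for n, l in zip(result.index.names, result.index.lengths)
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i in range(len(result)):
            a = pysam.AlignedSegment(fh.header)
            row = result.read_rows[i]
            a.query_name = result.reads.names[row]
            seq = result.aligned_read(i)
            a.query_sequence = seq.tobytes().decode()
            a.reference_id = int(result.ref_ids[i])
            a.reference_start = int(result.offsets[i])
            a.cigarstring = f"{len(seq)}M"
            flag = 0
            if result.strands[i] < 0:
                flag |= 0x10
            if result.reads.mates[row] == 1:
                flag |= 0x40 | 0x1
            else:
                flag |= 0x80 | 0x1
            a.flag = flag
            a.mapping_quality = 255
            a.set_tag("NM", int(result.mismatches[i]))
            fh.write(a)


def read_sam(path: str | Path, refs: ReferenceSet | Sequence[AlleleSequence]) -> AlignmentResult:
    """Adapt an external aligner's SAM into the internal placement table.

    Only ungapped (all-M CIGAR) records are imported; reads are rebuilt from
    the SAM itself.
    """
    import pysam

    index = ReferenceIndex(refs)
    name_to_id = {n: i for i, n in enumerate(index.names)}
    names: list[str] = []
    seqs: list[str] = []
    mates: list[int] = []
    rows: list[int] = []
    ref_ids: list[int] = []
    offsets: list[int] = []
    strands: list[int] = []
    mism: list[int] = []
    row_of: dict[tuple[str, int], int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name not in name_to_id:
                continue
            if rec.cigartuples and any(op != 0 for op, _ in rec.cigartuples):
                continue
            mate = 2 if rec.is_read2 else 1
            key = (rec.query_name, mate)
            if key not in row_of:
                seq = rec.query_sequence
                if rec.is_reverse:
                    seq = _COMP[np.frombuffer(seq.encode(), dtype=np.uint8)][::-1]
                    seq = seq.tobytes().decode()
                row_of[key] = len(names)
                names.append(rec.query_name)
                seqs.append(seq)
                mates.append(mate)
            rows.append(row_of[key])
            ref_ids.append(name_to_id[rec.reference_name])
            offsets.append(rec.reference_start)
            strands.append(-1 if rec.is_reverse else 1)
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            mism.append(int(nm))
    reads = ReadBatch.from_sequences(names, seqs, mates)
    return AlignmentResult(
        index=index, reads=reads,
        read_rows=np.asarray(rows, dtype=np.int32),
        ref_ids=np.asarray(ref_ids, dtype=np.int32),
        offsets=np.asarray(offsets, dtype=np.int32),
        strands=np.asarray(strands, dtype=np.int8),
        mismatches=np.asarray(mism, dtype=np.int16),
    )
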