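"""SNP calling, mismatch scoring and the iterative genotype-matched
alignment workflow.

Genotypes are determined per gene/major allelic group from aligned variant
depths:

1. depth tables are thresholded into SNP tables (minimum depth 8 for the
   initial stage, 20 for the final stage; up to three variants per position
   whose depth is at least 0.25 of the maximum-depth variant);
2. homozygous SNPs are scored against every described allele (mismatch = 1),
   and alleles within a scoring buffer of the best (4 initial / 1 final) are
   carried into combination scoring;
3. all allele multisets of size equal to the gene's copy number (capped at
   3) are scored: per heterozygous position the mismatch contribution is the
   symmetric difference between called variants and the variants offered by
   the combination, and each component allele's homozygous score is added;
4. the minimum-score combinations are the determined genotype.  In the
   final stage only perfect (score 0) combinations are accepted; anything
   else is unresolved.

The iterative workflow aligns reads against a gene-content-matched reference
first, then twice against genotype-matched references (locking in perfect
unambiguous typings, injecting the diverse minimized allele set for any gene
whose typing mismatches its aligned SNPs, adding fully characterized
sequence for genes represented only by partial sequence, and applying
virtual-probe refinement rules), and finally performs a best-placement
alignment against the most congruent typings for a final exonic (5-digit)
genotype over all aligned reads.

Stage asymmetry: the initial stage compares against imputed and extended
sequences with uncharacterized positions counting as mismatches over all
allele-differentiating positions; the final stage compares against the
unimputed characterization with uncharacterized positions counting as
matches, over exonic positions only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_db import (
    STATE_NATIVE,
    STATE_UNCHARACTERIZED,
    AlleleDatabase,
    AlleleSequence,
    ReferenceSet,
)
from .align_core import (
    AlignmentResult,
    DepthTable,
    GroupFrame,
    ReadBatch,
    align,
    build_depth_table,
    classify_unique,
    group_frame,
)
from .probes import Probe, apply_refinement_rules, probe_hits

logger = logging.getLogger(__name__)

_VAR_BYTES = b"ACGT-+"


@dataclass(frozen=True)
class ScoringParams:
    """Stage-specific genotype determination parameters."""

    stage: str                       # "initial" | "final"
    min_depth: int
    het_ratio: float = 0.25
    hom_buffer: int = 4
    max_copy: int = 3
    max_variants: int = 3
    uncharacterized_matches: bool = False   # True: N counts as match
    exonic_only: bool = False
    native_only: bool = False               # True: unimputed characterization

    @classmethod
    def initial(cls, **kw) -> "ScoringParams":
        return cls(stage="initial", min_depth=8, hom_buffer=4,
                   uncharacterized_matches=False, exonic_only=False,
                   native_only=False, **kw)

    @classmethod
    def final(cls, **kw) -> "ScoringParams":
        return cls(stage="final", min_depth=20, hom_buffer=1,
                   uncharacterized_matches=True, exonic_only=True,
                   native_only=True, **kw)


@dataclass
class SNPTable:
    """Called variants per frame position passing the stage depth floor."""

    group: str
    positions: np.ndarray            # frame columns, ascending
    variants: list[bytes]            # called symbols per position (depth order)
    depths: list[tuple[int, ...]]    # depth of each called symbol

    def __len__(self) -> int:
        return len(self.positions)

    def zygosity(self) -> np.ndarray:
        return np.asarray([len(v) for v in self.variants], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Positions are reported relative to the gene body start (signed,
        1-based for characterized bases as in reports)."""
        return pd.DataFrame({
            "position": self.positions,
            "variants": [v.decode() for v in self.variants],
            "depths": [",".join(map(str, d)) for d in self.depths],
            "zygosity": self.zygosity(),
        })


def call_snps(depth: DepthTable, params: ScoringParams) -> SNPTable:
    """Threshold a depth table into a SNP table.

    Positions with total depth below ``min_depth`` are dropped; at each
    retained position the depth of every variant is divided by the highest
    depth variant and up to ``max_variants`` variants passing ``het_ratio``
    are recorded, ordered by depth.
    """
    total = depth.total_depth()
    keep = np.flatnonzero(total >= params.min_depth)
    positions = []
    variants: list[bytes] = []
    depths: list[tuple[int, ...]] = []
    counts = depth.counts
    for col in keep:
        d = counts[:, col]
        top = d.max()
        if top == 0:
            continue
        order = np.argsort(-d, kind="stable")
        called = [
            i for i in order
            if d[i] > 0 and d[i] / top >= params.het_ratio
        ][: params.max_variants]
        positions.append(int(col))
        variants.append(bytes(_VAR_BYTES[i] for i in called))
        depths.append(tuple(int(d[i]) for i in called))
    return SNPTable(
        group=depth.group,
        positions=np.asarray(positions, dtype=int),
        variants=variants,
        depths=depths,
    )


# ---------------------------------------------------------------------------
# Per-group scoring context
# ---------------------------------------------------------------------------

@dataclass
class GroupContext:
    """Precomputed comparison matrices for one gene/major group."""

    group: str
    frame: GroupFrame
    allele_names: list[str]
    symbols: np.ndarray          # (n_alleles, n_cols) uint8 over ACGTN-
    char_full: np.ndarray        # characterized incl. imputed/extended
    char_native: np.ndarray      # natively characterized only
    exonic_cols: np.ndarray      # bool per column
    fully_characterized: np.ndarray

    def characterized(self, params: ScoringParams) -> np.ndarray:
        return self.char_native if params.native_only else self.char_full

    def differentiating(self, params: ScoringParams) -> np.ndarray:
        """Columns able to distinguish alleles under the stage's policy."""
        char = self.characterized(params)
        sym = np.where(char, self.symbols, 0)
        lo = np.where(char, self.symbols, 255).min(axis=0)
        hi = sym.max(axis=0)
        some_char = char.any(axis=0)
        mixed = some_char & (~char).any(axis=0)
        differs = some_char & (lo != hi)
        out = differs | mixed
        if params.exonic_only:
            out = out & self.exonic_cols
        return out


def build_group_context(db: AlleleDatabase, group: str) -> GroupContext:
    frame = group_frame(db, group)
    names = sorted(frame.symbols)
    sym = np.vstack([frame.symbols[n] for n in names])
    states = np.vstack([frame.states[n] for n in names])
    char_full = states != STATE_UNCHARACTERIZED
    char_native = states == STATE_NATIVE
    # gaps are a characterized symbol; N is not
    n_mask = sym == ord("N")
    char_full &= ~n_mask
    char_native &= ~n_mask
    exonic = np.zeros(frame.n_cols, dtype=bool)
    for n in names:
        a = db.alleles[n]
        colmap = frame.colmaps[n]
        for f in a.features:
            if f.is_exon:
                exonic[colmap[f.start:f.end]] = True
    fully = np.asarray([db.alleles[n].is_fully_characterized for n in names])
    return GroupContext(
        group=group, frame=frame, allele_names=names, symbols=sym,
        char_full=char_full, char_native=char_native, exonic_cols=exonic,
        fully_characterized=fully,
    )


# ---------------------------------------------------------------------------
# Mismatch scoring
# ---------------------------------------------------------------------------

def score_homozygous(
    ctx: GroupContext, snps: SNPTable, params: ScoringParams
) -> tuple[np.ndarray, np.ndarray]:
    """Score every allele against homozygous SNPs (mismatch = 1, match = 0).

    Returns (scores, retained) over ``ctx.allele_names``; retained alleles
    score within ``hom_buffer`` of the minimum.
    """
    scope = ctx.differentiating(params)
    zyg = snps.zygosity()
    hom_idx = [
        i for i in range(len(snps))
        if zyg[i] == 1 and scope[snps.positions[i]]
    ]
    n = len(ctx.allele_names)
    if not hom_idx:
        return np.zeros(n, dtype=int), np.ones(n, dtype=bool)
    cols = snps.positions[hom_idx]
    called = np.asarray([snps.variants[i][0] for i in hom_idx], dtype=np.uint8)
    char = ctx.characterized(params)[:, cols]
    sym = ctx.symbols[:, cols]
    mismatch = (sym != called[None, :]) & char
    if not params.uncharacterized_matches:
        mismatch = mismatch | ~char
    scores = mismatch.sum(axis=1).astype(int)
    retained = scores <= scores.min() + params.hom_buffer
    return scores, retained


def _position_score(called: bytes, offered: list[int | None]) -> int:
    """Symmetric-difference mismatch count at one heterozygous position.

    ``offered`` holds each component allele's symbol (byte) or None when the
    allele is uncharacterized there under the stage policy: an
    uncharacterized component never adds a spurious variant, and under the
    match policy it absorbs one otherwise-missing called variant.
    """
    cset = set(called)
    known = {s for s in offered if s is not None}
    n_wild = sum(1 for s in offered if s is None)
    missing = len(cset - known)
    extra = len(known - cset)
    return max(0, missing - n_wild) + extra


def score_combinations(
    ctx: GroupContext,
    snps: SNPTable,
    retained: Sequence[int],
    copy: int,
    params: ScoringParams,
    hom_scores: np.ndarray,
) -> list[tuple[tuple[int, ...], int]]:
    """Score every allele multiset of size ``copy`` over the retained set.

    Per heterozygous position, the combination's variants are compared to
    the called variants (symmetric-difference counting); each component
    allele's homozygous score is added.  Returns the minimum-score
    combinations sorted by component names.
    """
    if copy < 1:
        return []
    copy = min(copy, params.max_copy)
    scope = ctx.differentiating(params)
    zyg = snps.zygosity()
    het_idx = [
        i for i in range(len(snps))
        if zyg[i] >= 2 and scope[snps.positions[i]]
    ]
    char = ctx.characterized(params)
    uncharacterized_none = params.uncharacterized_matches

    # per retained allele, per het position: symbol or None
    offer: dict[int, list[int | None]] = {}
    for a in retained:
        row: list[int | None] = []
        for i in het_idx:
            col = snps.positions[i]
            if char[a, col]:
                row.append(int(ctx.symbols[a, col]))
            elif uncharacterized_none:
                row.append(None)
            else:
                row.append(-1)  # sentinel: never matches any called variant
        offer[a] = row

    best: int | None = None
    best_combos: list[tuple[int, ...]] = []
    for combo in itertools.combinations_with_replacement(sorted(retained), copy):
        total = int(sum(hom_scores[a] for a in combo))
        if best is not None and total > best:
            continue
        for i, hi in enumerate(het_idx):
            total += _position_score(snps.variants[hi], [offer[a][i] for a in combo])
            if best is not None and total > best:
                break
        if best is None or total < best:
            best = total
            best_combos = [combo]
        elif total == best:
            best_combos.append(combo)
    return [(c, best) for c in best_combos]


# ---------------------------------------------------------------------------
# Genotype calls
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCall:
    """Candidate allele combinations for one group, with status."""

    group: str
    copy: int
    candidates: list[tuple[tuple[str, ...], int]] = field(default_factory=list)
    locked: bool = False
    status: str = "unresolved"      # resolved | ambiguous | unresolved | null | no_reads
    resolution: int | None = None
    best_score: int | None = None
    note: str = ""

    @property
    def is_perfect_unambiguous(self) -> bool:
        return (
            self.best_score == 0
            and len({c for c, _ in self.candidates}) == 1
        )

    def combo_names(self) -> list[tuple[str, ...]]:
        return [c for c, _ in self.candidates]

    def allele_union(self) -> list[str]:
        return sorted({n for combo, _ in self.candidates for n in combo})

    def names_at(self, resolution: int, db: AlleleDatabase) -> list[tuple[str, ...]]:
        out = {
            tuple(sorted(db.alleles[n].name_at(resolution) for n in combo))
            for combo, _ in self.candidates
        }
        return sorted(out)


def determine_genotype(
    ctx: GroupContext,
    snps: SNPTable,
    copy: int,
    params: ScoringParams,
    db: AlleleDatabase,
) -> GenotypeCall:
    """Full genotype determination for one group at its copy number."""
    if copy == 0:
        return GenotypeCall(group=ctx.group, copy=0, status="null", best_score=None)
    if copy > params.max_copy:
        note = f"copy {copy} scored at cap {params.max_copy}"
        logger.warning("%s: %s", ctx.group, note)
    else:
        note = ""
    hom_scores, retained_mask = score_homozygous(ctx, snps, params)
    retained = list(np.flatnonzero(retained_mask))
    combos = score_combinations(ctx, snps, retained, copy, params, hom_scores)
    if not combos:
        return GenotypeCall(
            group=ctx.group, copy=copy, status="unresolved",
            note=note or "no scorable combination",
        )
    best = combos[0][1]
    named = sorted(
        {tuple(sorted(ctx.allele_names[a] for a in c)) for c, _ in combos}
    )
    call = GenotypeCall(
        group=ctx.group, copy=copy,
        candidates=[(c, best) for c in named],
        best_score=best, note=note,
    )
    if params.stage == "final" and best > 0:
        call.status = "unresolved"
        return call
    # resolution: unique at 7 digits, else collapse to 5
    if len(named) == 1:
        call.status = "resolved"
        call.resolution = 7 if params.stage == "initial" else 5
    else:
        five = call.names_at(5, db)
        if len(five) == 1:
            call.status = "resolved"
            call.resolution = 5
        else:
            call.status = "ambiguous"
    return call


# ---------------------------------------------------------------------------
# Iterative genotype-matched workflow
# ---------------------------------------------------------------------------

@dataclass
class GenotypingContext:
    """Cohort-level invariants: database, frames, minimized set, probes."""

    db: AlleleDatabase
    minimized: ReferenceSet
    probes: Sequence[Probe] = ()
    params_initial: ScoringParams = field(default_factory=ScoringParams.initial)
    params_final: ScoringParams = field(default_factory=ScoringParams.final)
    contexts: dict[str, GroupContext] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contexts:
            self.contexts = {
                g: build_group_context(self.db, g) for g in self.db.group_names
            }
        self._min_by_group: dict[str, list[AlleleSequence]] = {}
        for a in self.minimized.alleles:
            self._min_by_group.setdefault(a.major_group, []).append(a)

    def minimized_of(self, group: str) -> list[AlleleSequence]:
        return self._min_by_group.get(group, [])

    @property
    def framework_groups(self) -> list[str]:
        return self.db.groups[self.db.framework_gene]


@dataclass
class RoundLog:
    round: str
    reference: list[str]
    best_scores: dict[str, int | None]
    locked: list[str]
    unique_counts: dict[str, int]


@dataclass
class WorkflowResult:
    sample_id: str
    copies: dict[str, int]
    calls: dict[str, GenotypeCall]           # final calls per group
    initial_calls: dict[str, GenotypeCall]
    rounds: list[RoundLog]
    final_alignment: AlignmentResult | None = None

    def audit_table(self) -> pd.DataFrame:
        """Per-round log of references used, scores and lock events."""
        rows = []
        for log in self.rounds:
            for g, score in sorted(log.best_scores.items()):
                rows.append({
                    "sample": self.sample_id, "round": log.round, "group": g,
                    "best_score": score, "locked": g in log.locked,
                    "unique_reads": log.unique_counts.get(g, 0),
                    "n_reference_alleles": len(log.reference),
                })
        return pd.DataFrame(rows)


def _call_group_from_alignment(
    gctx: GenotypingContext,
    result: AlignmentResult,
    group: str,
    copy: int,
    params: ScoringParams,
    read_rows: np.ndarray | None,
) -> GenotypeCall:
    ctx = gctx.contexts[group]
    depth = build_depth_table(result, ctx.frame, read_rows=read_rows)
    if depth.n_reads == 0:
        return GenotypeCall(
            group=group, copy=copy, status="no_reads",
            note="no aligned reads for group",
        )
    snps = call_snps(depth, params)
    return determine_genotype(ctx, snps, copy, params, gctx.db)


def _reference_for_round(
    gctx: GenotypingContext,
    present: Sequence[str],
    calls: Mapping[str, GenotypeCall],
    hits: Mapping[str, bool],
) -> ReferenceSet:
    """Genotype-matched reference: current typings plus countermeasures."""
    db = gctx.db
    names: set[str] = set()
    for g in present:
        call = calls.get(g)
        cand = call.allele_union() if call else []
        names.update(cand)
        stuck = call is None or call.status in ("no_reads",) or (
            call.best_score is None or call.best_score > 0
        )
        if stuck:
            # anti-stuck: inject the diverse minimized set for this group
            names.update(a.allele_name for a in gctx.minimized_of(g))
        if cand and all(not db.alleles[n].is_fully_characterized for n in cand):
            names.update(
                a.allele_name for a in gctx.minimized_of(g)
                if a.is_fully_characterized
            )
    for g in gctx.framework_groups:
        names.update(a.allele_name for a in gctx.minimized_of(g))
    alleles = tuple(sorted((db.alleles[n] for n in names), key=lambda a: a.allele_name))
    ref = ReferenceSet(name="genotype_matched", alleles=alleles)
    refined = apply_refinement_rules(hits, ref, gctx.probes, db)
    return refined.reference


def run_genotyping_workflow(
    reads: ReadBatch,
    copies: Mapping[str, int],
    gctx: GenotypingContext,
    *,
    sample_id: str = "sample",
    initial_alignment: AlignmentResult | None = None,
    n_intermediate: int = 2,
    keep_final_alignment: bool = False,
) -> WorkflowResult:
    """Run the full iterative genotyping workflow for one sample.

    ``initial_alignment`` may supply a precomputed exhaustive alignment
    against (a superset of) the minimized reference; exhaustive placements
    restricted to the gene-content-matched subset are identical to a fresh
    alignment against that subset.
    """
    db = gctx.db
    present = [
        g for g in db.group_names
        if copies.get(g, 0) >= 1 or g in gctx.framework_groups
    ]
    rounds: list[RoundLog] = []

    # ---- stage 1: gene-content matched exhaustive alignment -------------
    content_names = [
        a.allele_name for g in present for a in gctx.minimized_of(g)
    ]
    if initial_alignment is not None:
        res = initial_alignment.restrict_to_alleles(content_names)
    else:
        refs = ReferenceSet(
            "content_matched",
            tuple(db.alleles[n] for n in sorted(content_names)),
        )
        res = align(reads, refs, mode="exhaustive")
    uniq = classify_unique(res)
    calls: dict[str, GenotypeCall] = {}
    for g in present:
        calls[g] = _call_group_from_alignment(
            gctx, res, g, copies.get(g, 0), gctx.params_initial,
            uniq.unique_rows.get(g, np.empty(0, dtype=np.int64)),
        )
    initial_calls = dict(calls)
    locked: dict[str, GenotypeCall] = {
        g: c for g, c in calls.items()
        if c.is_perfect_unambiguous and c.copy >= 1
    }
    for c in locked.values():
        c.locked = True
    history: dict[str, list[tuple[str, GenotypeCall]]] = {
        g: [("round0", calls[g])] for g in present
    }
    rounds.append(RoundLog(
        round="round0", reference=sorted(content_names),
        best_scores={g: calls[g].best_score for g in present},
        locked=sorted(locked), unique_counts=dict(uniq.counts),
    ))

    # probe hits over the raw read sequences (both mates, once per sample)
    read_seqs = [reads.sequence(i) for i in range(len(reads))]
    hits = probe_hits(read_seqs, gctx.probes) if gctx.probes else {}

    # ---- stage 2: genotype-matched intermediate rounds -------------------
    for r in range(1, n_intermediate + 1):
        ref = _reference_for_round(gctx, present, calls, hits)
        res = align(reads, ref, mode="exhaustive")
        uniq = classify_unique(res)
        for g in present:
            if g in locked:
                continue
            call = _call_group_from_alignment(
                gctx, res, g, copies.get(g, 0), gctx.params_initial,
                uniq.unique_rows.get(g, np.empty(0, dtype=np.int64)),
            )
            calls[g] = call
            history[g].append((f"round{r}", call))
            if call.is_perfect_unambiguous and call.copy >= 1:
                call.locked = True
                locked[g] = call
        rounds.append(RoundLog(
            round=f"round{r}", reference=ref.names(),
            best_scores={g: calls[g].best_score for g in present},
            locked=sorted(locked), unique_counts=dict(uniq.counts),
        ))

    # ---- stage 3: final non-exhaustive round -----------------------------
    congruent: dict[str, GenotypeCall] = {}
    for g in present:
        if g in locked:
            congruent[g] = locked[g]
            continue
        # most congruent typing across rounds: least SNP mismatches,
        # later rounds win ties
        scored = [
            (c.best_score, -i, c) for i, (_, c) in enumerate(history[g])
            if c.best_score is not None
        ]
        congruent[g] = min(scored)[2] if scored else calls[g]
    final_names: set[str] = set()
    for g in present:
        final_names.update(congruent[g].allele_union())
        if not congruent[g].allele_union():
            final_names.update(a.allele_name for a in gctx.minimized_of(g))
    ref = ReferenceSet(
        "final", tuple(sorted((db.alleles[n] for n in final_names),
                              key=lambda a: a.allele_name)),
    )
    ref = apply_refinement_rules(hits, ref, gctx.probes, db).reference
    res_final = align(reads, ref, mode="best")
    final_calls: dict[str, GenotypeCall] = {}
    for g in db.group_names:
        cp = copies.get(g, 0)
        if cp == 0:
            final_calls[g] = GenotypeCall(group=g, copy=0, status="null")
            continue
        final_calls[g] = _call_group_from_alignment(
            gctx, res_final, g, cp, gctx.params_final, read_rows=None
        )
        final_calls[g].locked = g in locked
    return WorkflowResult(
        sample_id=sample_id, copies=dict(copies), calls=final_calls,
        initial_calls=initial_calls, rounds=rounds,
        final_alignment=res_final if keep_final_alignment else None,
    )


# ---------------------------------------------------------------------------
# Genotype formatting
# ---------------------------------------------------------------------------

NULL_ALLELE = "null"
DEFAULT_MERGES: tuple[tuple[str, str, str], ...] = ()


def format_genotypes(
    results: Mapping[str, GenotypeCall] | WorkflowResult,
    db: AlleleDatabase,
    *,
    resolution: int = 5,
    merges: Sequence[tuple[str, str, str]] = DEFAULT_MERGES,
) -> dict[str, str]:
    """Render final calls as genotype strings.

    Copy-0/1 genes are padded with ``null`` tokens to two components; merged
    allelic-group pairs emit a single combined column; ambiguity is rendered
    as a sorted ``|``-separated list of alternatives.
    """
    calls = results.calls if isinstance(results, WorkflowResult) else dict(results)

    def components(call: GenotypeCall) -> list[list[str]]:
        """Alternative component lists (one per candidate combo)."""
        if call.status in ("null",):
            return [[NULL_ALLELE, NULL_ALLELE]]
        if call.status in ("unresolved", "no_reads") or not call.candidates:
            return [["unresolved"] * max(call.copy, 1)]
        alts = []
        for combo in call.names_at(resolution, db):
            comp = list(combo)
            while len(comp) < 2 and call.copy < 2:
                comp.append(NULL_ALLELE)
            alts.append(comp)
        return sorted(alts)

    merged_groups = {g for a, b, _ in merges for g in (a, b)}
    out: dict[str, str] = {}
    for g in sorted(calls):
        if g in merged_groups:
            continue
        alts = components(calls[g])
        out[g] = "|".join("+".join(c) for c in alts)
    for a, b, name in merges:
        if a not in calls and b not in calls:
            continue
        parts: list[list[str]] = []
        for g in (a, b):
            if g not in calls:
                continue
            call = calls[g]
            if call.status == "null":
                # the merged locus carries the pair total; nulls from one
                # member are implied by the other's copies
                continue
            if call.status in ("unresolved", "no_reads") or not call.candidates:
                parts.append(["unresolved"] * max(call.copy, 1))
            else:
                # no per-member null padding: the pair total is shared
                parts.append(list(call.names_at(resolution, db)[0]))
        flat = [tok for p in parts for tok in p]
        if not flat:
            flat = [NULL_ALLELE, NULL_ALLELE]
        out[name] = "+".join(sorted(flat))
    return out


def genotype_table(
    results: Iterable[WorkflowResult],
    db: AlleleDatabase,
    *,
    resolution: int = 5,
    merges: Sequence[tuple[str, str, str]] = DEFAULT_MERGES,
) -> pd.DataFrame:
    """One row per sample and output column (merged pairs emit one row)."""
    member_of = {g: name for a, b, name in merges for g in (a, b)}
    rows = []
    for wr in results:
        formatted = format_genotypes(wr, db, resolution=resolution, merges=merges)
        emitted: set[str] = set()
        for g, call in sorted(wr.calls.items()):
            name = member_of.get(g, g)
            if name in emitted:
                continue
            emitted.add(name)
            if name == g:
                members = [call]
            else:
                members = [wr.calls[m] for m in wr.calls
                           if member_of.get(m) == name]
            statuses = [m.status for m in members]
            if any(s in ("unresolved", "no_reads") for s in statuses):
                status = "unresolved"
            elif any(s == "ambiguous" for s in statuses):
                status = "ambiguous"
            elif all(s == "null" for s in statuses):
                status = "null"
            else:
                status = "resolved"
            scores = [m.best_score for m in members if m.best_score is not None]
            rows.append({
                "sample": wr.sample_id, "group": name,
                "copy": sum(m.copy for m in members),
                "status": status,
                "score": sum(scores) if scores else None,
                "locked": (
                    any(m.copy for m in members)
                    and all(m.locked for m in members if m.copy)
                ),
                "genotype": formatted.get(name, ""),
            })
    return pd.DataFrame(rows).astype({"score": "Int64"})
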