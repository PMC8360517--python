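"""End-to-end cohort orchestration: simulate -> extract -> copy -> genotype.

This module wires the stage modules together for batch processing, caching
the expensive cohort-level artifacts (prepared database, reference indexes,
per-sample exhaustive alignments) so that copy-number thresholding -- which
needs the whole batch -- can precede per-sample genotyping without
re-aligning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align_core import AlignmentResult, ReadBatch, ReferenceIndex, align, classify_unique
from .allele_db import (
    AlleleDatabase,
    ReferenceSet,
    extend_utrs,
    impute_database,
    select_minimized_reference,
)
from .copy_number import (
    CopyRatioMatrix,
    CopyThresholds,
    batch_thresholds,
    call_copies,
    ratio_matrix,
)
from .extractor import extract_reads, haplotype_references
from .genotype import GenotypingContext, WorkflowResult, run_genotyping_workflow
from .simulate import (
    SyntheticFamily,
    TruthRecord,
    build_family,
    parse_read_name,
    sample_genotype,
    simulate_reads,
)
from .tracing import FlowTable, trace_flows

logger = logging.getLogger(__name__)


@dataclass
class PreparedFamily:
    """Cohort-invariant artifacts derived from a synthetic family."""

    family: SyntheticFamily
    db: AlleleDatabase                  # imputed + UTR-extended
    minimized: ReferenceSet
    comprehensive: ReferenceSet
    single_ref: ReferenceSet
    gctx: GenotypingContext
    hap_index: ReferenceIndex
    min_index: ReferenceIndex
    comp_index: ReferenceIndex | None = None
    single_index: ReferenceIndex | None = None


def prepare_family(
    family: SyntheticFamily | None = None,
    *,
    per_group: int = 5,
    with_comprehensive: bool = True,
    with_single: bool = True,
) -> PreparedFamily:
    """Impute, extend and index a family for cohort processing.

    The minimized reference force-includes the configured sequestration
    allele (a gene-conversion carrier prone to off-gene read capture).
    """
    family = family or build_family()
    db = extend_utrs(impute_database(family.database))
    conv_group, _, _ = family.config.conversion_allele
    seq_allele = f"{conv_group}*{family.config.n_exonic_classes:03d}0101"
    minimized = select_minimized_reference(
        db, per_group=per_group, force_include=[seq_allele]
    )
    comprehensive = ReferenceSet(
        "comprehensive",
        tuple(sorted(db.alleles.values(), key=lambda a: a.allele_name)),
    )
    single = ReferenceSet(
        "single_sequence",
        tuple(
            db.alleles[f"{g}*0010101"] for g in db.group_names
            if f"{g}*0010101" in db.alleles
        ),
    )
    gctx = GenotypingContext(db=db, minimized=minimized, probes=family.probes)
    prepared = PreparedFamily(
        family=family, db=db, minimized=minimized, comprehensive=comprehensive,
        single_ref=single, gctx=gctx,
        hap_index=ReferenceIndex(
            haplotype_references(family.haplotype_seqs),
        ),
        min_index=ReferenceIndex(minimized),
    )
    if with_comprehensive:
        prepared.comp_index = ReferenceIndex(comprehensive)
    if with_single:
        prepared.single_index = ReferenceIndex(single)
    return prepared


@dataclass
class SampleRun:
    truth: TruthRecord
    reads: ReadBatch | None                 # extracted reads (cached for pass 2)
    alignment: AlignmentResult | None       # exhaustive vs minimized reference
    retention: float
    unique_min: dict[str, int]
    unique_comp: dict[str, int] = field(default_factory=dict)
    unique_single: dict[str, int] = field(default_factory=dict)
    off_target_unique_comp: int = 0
    off_target_unique_single: int = 0
    workflow: WorkflowResult | None = None


@dataclass
class CohortResult:
    samples: list[SampleRun]
    ratios_min: CopyRatioMatrix
    thresholds: dict[str, CopyThresholds]
    copies_min: pd.DataFrame
    ratios_comp: CopyRatioMatrix | None = None
    thresholds_comp: dict[str, CopyThresholds] | None = None
    copies_comp: pd.DataFrame | None = None
    flows: FlowTable | None = None

    @property
    def copies(self) -> pd.DataFrame:
        """Copy calls used for genotyping (comprehensive reference when
        available, minimized otherwise)."""
        return self.copies_comp if self.copies_comp is not None else self.copies_min

    def truth_copies(self) -> pd.DataFrame:
        rows = {
            s.truth.sample_id: dict(s.truth.copies) for s in self.samples
        }
        return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


def _off_target_unique(uniq, reads: ReadBatch) -> int:
    n = 0
    for g, rows in uniq.unique_rows.items():
        for row in rows:
            try:
                _, allele, _ = parse_read_name(reads.names[row])
            except ValueError:
                continue
            if allele.split("*")[0] != g:
                n += 1
    return n


def run_cohort(
    prepared: PreparedFamily,
    n_samples: int = 50,
    seed: int = 1,
    *,
    coverage: float = 50.0,
    read_len: int = 150,
    frag_median: int = 200,
    do_genotype: bool = True,
    do_trace: bool = False,
    log_every: int = 0,
) -> CohortResult:
    """Simulate and process a cohort end to end.

    Pass 1 per sample: draw a genotype, simulate reads, extract, align
    exhaustively against the minimized reference (plus optionally the
    comprehensive and single-sequence references) and record unique-read
    counts.  Batch step: ratio normalization against the framework gene and
    automatic thresholding.  Pass 2 per sample: the iterative genotyping
    workflow, reusing the cached minimized-reference alignment.
    """
    rng = np.random.default_rng(seed)
    fw_group = prepared.db.groups[prepared.db.framework_gene][0]
    samples: list[SampleRun] = []
    for i in range(n_samples):
        sid = f"S{i + 1:03d}"
        truth = sample_genotype(prepared.db, prepared.family.templates, rng, sid)
        batch = simulate_reads(
            truth, read_len=read_len, coverage=coverage,
            frag_median=frag_median, rng=rng,
        )
        extraction = extract_reads(batch, prepared.hap_index)
        reads = ReadBatch.from_pairs(
            extraction.batch.names, extraction.batch.r1, extraction.batch.r2
        )
        res_min = align(reads, prepared.min_index, mode="exhaustive")
        uniq_min = classify_unique(res_min)
        run = SampleRun(
            truth=truth, reads=reads, alignment=res_min,
            retention=extraction.retention, unique_min=dict(uniq_min.counts),
        )
        if prepared.comp_index is not None:
            res_c = align(reads, prepared.comp_index, mode="exhaustive")
            uniq_c = classify_unique(res_c)
            run.unique_comp = dict(uniq_c.counts)
            run.off_target_unique_comp = _off_target_unique(uniq_c, reads)
        if prepared.single_index is not None:
            res_s = align(reads, prepared.single_index, mode="exhaustive")
            uniq_s = classify_unique(res_s)
            run.unique_single = dict(uniq_s.counts)
            run.off_target_unique_single = _off_target_unique(uniq_s, reads)
        samples.append(run)
        if log_every and (i + 1) % log_every == 0:
            logger.info("pass1 %d/%d samples", i + 1, n_samples)

    counts_min = pd.DataFrame(
        {s.truth.sample_id: s.unique_min for s in samples}
    ).T.fillna(0)
    ratios_min = ratio_matrix(counts_min, fw_group)
    thresholds = batch_thresholds(ratios_min)
    copies_min = call_copies(ratios_min, thresholds)

    ratios_comp = thresholds_comp = copies_comp = None
    if prepared.comp_index is not None:
        counts_comp = pd.DataFrame(
            {s.truth.sample_id: s.unique_comp for s in samples}
        ).T.fillna(0)
        ratios_comp = ratio_matrix(counts_comp, fw_group)
        thresholds_comp = batch_thresholds(ratios_comp)
        copies_comp = call_copies(ratios_comp, thresholds_comp)

    # genotype against the most reliable copy calls available (the
    # comprehensive reference resolves high-homology groups that the
    # minimized reference cannot)
    copies_for_genotyping = copies_comp if copies_comp is not None else copies_min
    flows = None
    if do_genotype:
        flow_frames: list[FlowTable] = []
        for i, run in enumerate(samples):
            sid = run.truth.sample_id
            copies = copies_for_genotyping.loc[sid].to_dict()
            run.workflow = run_genotyping_workflow(
                run.reads, copies, prepared.gctx, sample_id=sid,
                initial_alignment=run.alignment,
                keep_final_alignment=do_trace,
            )
            if do_trace and run.workflow.final_alignment is not None:
                flow_frames.append(trace_flows(run.workflow.final_alignment))
                run.workflow.final_alignment = None
            run.reads = None       # release per-sample memory
            run.alignment = None
            if log_every and (i + 1) % log_every == 0:
                logger.info("pass2 %d/%d samples", i + 1, n_samples)
        if flow_frames:
            merged: dict[tuple[str, str], int] = {}
            on_target: dict[str, int] = {}
            for ft in flow_frames:
                for r in ft.flows.itertuples(index=False):
                    key = (r.source_gene, r.aligned_gene)
                    merged[key] = merged.get(key, 0) + r.count
                for g, c in ft.on_target.items():
                    on_target[g] = on_target.get(g, 0) + c
            flows = FlowTable(
                flows=pd.DataFrame(
                    [
                        {"source_gene": s, "aligned_gene": g, "count": c}
                        for (s, g), c in sorted(merged.items())
                    ],
                    columns=["source_gene", "aligned_gene", "count"],
                ),
                on_target=on_target,
            )
    return CohortResult(
        samples=samples, ratios_min=ratios_min, thresholds=thresholds,
        copies_min=copies_min, ratios_comp=ratios_comp,
        thresholds_comp=thresholds_comp, copies_comp=copies_comp, flows=flows,
    )


# ---------------------------------------------------------------------------
# Concordance evaluation
# ---------------------------------------------------------------------------

def copy_concordance(
    cohort: CohortResult, group: str, *, which: str = "minimized"
) -> float:
    """Fraction of samples whose called copy matches simulated truth."""
    called = cohort.copies_min if which == "minimized" else cohort.copies_comp
    if called is None:
        raise ValueError(f"no {which} copy calls in this cohort")
    truth = cohort.truth_copies()
    truth = truth.loc[called.index]
    return float((called[group] == truth[group]).mean())


def genotype_concordance(
    cohort: CohortResult, group: str, *, resolution: int = 5
) -> dict[str, float | int]:
    """Component-allele concordance for one group (match / mismatch /
    unresolved fractions over truth components, plus resolved-only
    concordance)."""
    n = matched = mismatched = unresolved = 0
    resolved_n = resolved_matched = 0
    for s in cohort.samples:
        wr = s.workflow
        if wr is None:
            continue
        truth_names = sorted(
            _name_at(a, resolution) for a in s.truth.allele_multiset(group)
        )
        if not truth_names:
            continue
        call = wr.calls.get(group)
        n += len(truth_names)
        if call is None or call.status in ("unresolved", "no_reads", "null"):
            unresolved += len(truth_names)
            continue
        if call.status == "ambiguous":
            unresolved += len(truth_names)
            continue
        called = sorted(
            _name_at(a, resolution)
            for combo, _ in call.candidates[:1] for a in combo
        )
        m = _multiset_overlap(truth_names, called)
        matched += m
        mismatched += len(truth_names) - m
        resolved_n += len(truth_names)
        resolved_matched += m
    return {
        "n": n,
        "match": matched / n if n else float("nan"),
        "mismatch": mismatched / n if n else float("nan"),
        "unresolved": unresolved / n if n else float("nan"),
        "resolved_n": resolved_n,
        "resolved_match": resolved_matched / resolved_n if resolved_n else float("nan"),
    }


def _name_at(allele_name: str, resolution: int) -> str:
    group, digits = allele_name.split("*")
    return f"{group}*{digits[:resolution]}"


def _multiset_overlap(a: Sequence[str], b: Sequence[str]) -> int:
    from collections import Counter

    ca, cb = Counter(a), Counter(b)
    return sum((ca & cb).values())
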