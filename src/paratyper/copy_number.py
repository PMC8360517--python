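"""Batch copy-number determination from unique-read depth ratios.

Per sample, the number of reads aligning uniquely to each gene/major allelic
group is normalized by the unique-read count of the framework gene (assumed
present at two copies in every individual).  Across a batch, these ratios
cluster by copy number; thresholds between clusters yield integer copy
calls.  Thresholding is automated by 1-D cluster detection over the sorted
ratios, with a separability score so that poorly separated genes can be
flagged for manual thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MAX_COPY_DEFAULT = 4
BATCH_FLOOR = 10


@dataclass
class CopyRatioMatrix:
    """Samples x groups matrix of unique-read ratios vs the framework gene."""

    ratios: pd.DataFrame
    framework: str
    excluded: list[str] = field(default_factory=list)  # zero framework count


def ratio_matrix(
    unique_counts: pd.DataFrame | Mapping[str, Mapping[str, int]],
    framework: str,
) -> CopyRatioMatrix:
    """``ratio[s, g] = unique[s, g] / unique[s, framework]``.

    Samples with a zero framework count cannot be normalized; they are
    excluded and reported.
    """
    df = (
        unique_counts.copy() if isinstance(unique_counts, pd.DataFrame)
        else pd.DataFrame.from_dict(unique_counts, orient="index").fillna(0)
    )
    if framework not in df.columns:
        raise ValueError(f"framework gene {framework!r} missing from counts")
    fw = df[framework].astype(float)
    bad = fw <= 0
    excluded = list(df.index[bad])
    good = df.loc[~bad]
    ratios = good.div(good[framework].astype(float), axis=0)
    return CopyRatioMatrix(ratios=ratios, framework=framework, excluded=excluded)


@dataclass
class CopyThresholds:
    """Ordered cut points between copy groups for one gene.

    ``copies[i]`` is the copy number of ratios in
    ``(cuts[i-1], cuts[i]]``-style interval i (a value equal to a cut is
    assigned to the higher interval).
    """

    gene: str
    cuts: tuple[float, ...]
    copies: tuple[int, ...]
    provenance: str = "auto"
    separability: float | None = None
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError(f"{self.gene}: cuts must be strictly increasing")
        if len(self.copies) != len(self.cuts) + 1:
            raise ValueError(f"{self.gene}: need one copy label per interval")


def auto_thresholds(
    ratios: Sequence[float] | pd.Series,
    gene: str = "",
    *,
    max_copy: int = MAX_COPY_DEFAULT,
    batch_floor: int = BATCH_FLOOR,
    min_gap: float = 0.015,
    copy_spacing: float = 0.5,
) -> CopyThresholds:
    """Derive copy thresholds by 1-D cluster detection on sorted ratios.

    Gaps between consecutive sorted ratios that exceed
    ``max(min_gap, 0.1 * largest_gap, min(5 * median_gap, copy_spacing / 2))``
    split the batch into clusters (at most ``max_copy + 1``).  Copy labels are anchored at
    ratio ~ 0 for copy 0; the remaining clusters are assigned by the spacing
    of cluster centers, defaulting to the framework-relative expectation of
    ``copy_spacing`` per copy when only a single cluster is present (which is
    flagged for manual review, as are low-separability genes).
    """
    r = np.sort(np.asarray(ratios, dtype=float))
    n = len(r)
    if n < batch_floor:
        raise ValueError(f"{gene or 'gene'}: batch of {n} below floor {batch_floor}")
    gaps = np.diff(r)
    med = float(np.median(gaps)) if len(gaps) else 0.0
    biggest = float(gaps.max()) if len(gaps) else 0.0
    threshold = max(
        min_gap, 0.1 * biggest, min(5.0 * med, copy_spacing / 2.0)
    )
    split_idx = np.flatnonzero(gaps >= threshold)
    if len(split_idx) > max_copy:  # keep the largest gaps only
        order = np.argsort(gaps[split_idx])[::-1][:max_copy]
        split_idx = np.sort(split_idx[order])

    bounds = np.concatenate([[0], split_idx + 1, [n]])
    centers = np.array([r[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    cuts = tuple(
        float((r[i] + r[i + 1]) / 2.0) for i in split_idx
    )
    flagged = False
    note = ""
    sep = None
    if len(split_idx):
        sep = float(gaps[split_idx].min() / threshold)
        if sep < 2.0:
            flagged = True
            note = "low separability"

    # copy labels per cluster
    if len(centers) == 1:
        c = centers[0]
        copy = 0 if c < min(0.02, copy_spacing / 10) else max(1, round(c / copy_spacing))
        copies = (int(copy),)
        flagged = True
        note = (note + "; " if note else "") + "single cluster"
    else:
        zero = centers[0] < max(0.02, 0.25 * centers[1])
        positive = centers[1:] if zero else centers
        unit = float(positive[0])
        m = max(1, round(unit / copy_spacing)) if unit > 0.7 * copy_spacing * 2 else 1
        unit /= m
        labels = [int(max(m, round(c / unit))) for c in positive]
        if zero:
            labels = [0] + labels
        if labels != sorted(set(labels)):
            # fall back to framework-relative spacing
            labels = [int(round(c / copy_spacing)) for c in centers]
            flagged = True
            note = (note + "; " if note else "") + "cluster spacing irregular"
        copies = tuple(labels)
    if max(copies) > max_copy:
        flagged = True
        note = (note + "; " if note else "") + f"copy above cap {max_copy}"
    return CopyThresholds(
        gene=gene, cuts=cuts, copies=copies, provenance="auto",
        separability=sep, flagged=flagged, note=note,
    )


def call_copies(
    matrix: CopyRatioMatrix, thresholds: Mapping[str, CopyThresholds]
) -> pd.DataFrame:
    """Assign each ratio to its threshold interval (ties go upward)."""
    out = pd.DataFrame(index=matrix.ratios.index, columns=matrix.ratios.columns,
                       dtype=int)
    for gene in matrix.ratios.columns:
        th = thresholds[gene]
        idx = np.searchsorted(np.asarray(th.cuts), matrix.ratios[gene].values,
                              side="right")
        out[gene] = np.asarray(th.copies)[idx]
    return out


def batch_thresholds(
    matrix: CopyRatioMatrix,
    *,
    max_copy: int = MAX_COPY_DEFAULT,
    overrides: Mapping[str, CopyThresholds] | None = None,
) -> dict[str, CopyThresholds]:
    """Auto thresholds for every gene of a batch, honoring manual overrides.

    The framework gene is fixed at copy 2 by assumption (it normalizes the
    ratios, so its own ratio is identically 1).
    """
    out: dict[str, CopyThresholds] = {}
    for gene in matrix.ratios.columns:
        if overrides and gene in overrides:
            th = overrides[gene]
            out[gene] = CopyThresholds(
                gene=gene, cuts=th.cuts, copies=th.copies, provenance="manual",
                separability=th.separability, flagged=False, note="manual override",
            )
        elif gene == matrix.framework:
            out[gene] = CopyThresholds(
                gene=gene, cuts=(), copies=(2,), provenance="auto",
                note="framework gene assumed copy 2",
            )
        else:
            out[gene] = auto_thresholds(
                matrix.ratios[gene], gene, max_copy=max_copy
            )
    return out


def paired_gene_fallback(
    copies: pd.DataFrame, gene_a: str, gene_b: str, total: int = 2
) -> pd.DataFrame:
    """Set ``copy[gene_a] = total - copy[gene_b]`` for a complementary pair.

    Used when one member of a paired allelic-group locus separates cleanly
    while the other does not: the locus carries ``total`` copies split
    between the two groups, so the well-determined member fixes the other.
    """
    if gene_b not in copies.columns:
        raise KeyError(gene_b)
    if (copies[gene_b] > total).any():
        bad = copies.index[copies[gene_b] > total].tolist()
        raise ValueError(
            f"{gene_b} copy exceeds pair total {total} for samples {bad}"
        )
    out = copies.copy()
    out[gene_a] = total - copies[gene_b]
    return out


def write_threshold_manifest(
    thresholds: Mapping[str, CopyThresholds], path: str | Path
) -> None:
    rows = []
    for gene, th in sorted(thresholds.items()):
        rows.append({
            "gene": gene,
            "cuts": ",".join(f"{c:.4f}" for c in th.cuts),
            "copies": ",".join(str(c) for c in th.copies),
            "provenance": th.provenance,
            "separability": "" if th.separability is None else f"{th.separability:.3f}",
            "flagged": th.flagged,
            "note": th.note,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
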