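"""Virtual exact-substring probes for presence calls and reference refinement.

A virtual probe is a short (20-50 nt) sequence unique to a target allele or
allelic group.  Scanning raw reads for exact containment of the probe (on
either strand) gives a cheap, alignment-free presence signal for alleles that
are systematically misidentified by read alignment.  Probe hits can trigger
reference refinement rules that force specific allele sequences into the
alignment reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .allele_db import AlleleDatabase, ReferenceSet

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Probe:
    """One virtual probe.

    ``action`` is ``presence_flag`` (report only) or ``add_reference_allele``
    (on a hit, add ``action_arg`` to the alignment reference).  Probes sharing
    a ``precedence_group`` are mutually exclusive refinements: when several
    fire, the single allele named by the group's ``precedence_arg`` is added
    instead of the individual ones.
    """

    name: str
    target: str
    sequence: str
    threshold: int = 10
    action: str = "presence_flag"
    action_arg: str = ""
    precedence_group: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"probe {self.name}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"probe {self.name}: sequence must be over ACGT")
        if self.threshold < 1:
            raise ValueError(f"probe {self.name}: threshold must be >= 1")


def count_probe(reads: Iterable[str], probe: Probe) -> int:
    """Number of *distinct* read sequences containing the probe exactly.

    Both the probe and its reverse complement are searched, since raw reads
    come from either strand.  Duplicate read sequences count once.
    """
    fwd, rev = probe.sequence, revcomp(probe.sequence)
    seen: set[str] = set()
    for seq in reads:
        if seq in seen:
            continue
        if fwd in seq or rev in seq:
            seen.add(seq)
    return len(seen)


def probe_hits(
    reads: Sequence[str], probes: Iterable[Probe]
) -> dict[str, bool]:
    """Evaluate every probe against the read set (hit iff count >= threshold)."""
    return {p.name: count_probe(reads, p) >= p.threshold for p in probes}


def verify_probe_uniqueness(
    probe: Probe, db: AlleleDatabase, declared_targets: Sequence[str] | None = None
) -> pd.DataFrame:
    """Scan every allele for probe containment (exact substring, both strands).

    Returns a table of containing alleles with a ``declared`` column; the
    probe passes iff every containing allele is in the declared target set
    (by default: alleles whose name starts with ``probe.target``).
    """
    fwd, rev = probe.sequence, revcomp(probe.sequence)
    if declared_targets is None:
        declared = lambda name: name.startswith(probe.target)
    else:
        dset = set(declared_targets)
        declared = lambda name: name in dset
    rows = []
    for name, a in sorted(db.alleles.items()):
        if fwd in a.seq or rev in a.seq:
            rows.append({"allele": name, "group": a.major_group,
                         "declared": bool(declared(name))})
    df = pd.DataFrame(rows, columns=["allele", "group", "declared"])
    df.attrs["unique_to_target"] = bool(df["declared"].all()) if len(df) else False
    return df


@dataclass
class RefinementOutcome:
    reference: ReferenceSet
    added: list[str] = field(default_factory=list)
    flags: dict[str, bool] = field(default_factory=dict)


def apply_refinement_rules(
    hits: Mapping[str, bool],
    reference: ReferenceSet,
    probes: Sequence[Probe],
    db: AlleleDatabase,
    *,
    precedence_args: Mapping[str, str] | None = None,
) -> RefinementOutcome:
    """Add probe-designated alleles to the reference for every firing rule.

    Within a precedence group, if exactly one probe fires its own allele is
    added; if several fire, only the group's precedence allele is added (for
    the canonical rule set that is the first group member's allele).
    ``precedence_args`` maps precedence_group -> allele name and defaults to
    the ``action_arg`` of the lexicographically first probe of the group.
    """
    precedence_args = dict(precedence_args or {})
    by_group: dict[str, list[Probe]] = {}
    singles: list[Probe] = []
    flags: dict[str, bool] = {}
    for p in probes:
        flags[p.name] = bool(hits.get(p.name, False))
        if p.action != "add_reference_allele":
            continue
        if p.precedence_group:
            by_group.setdefault(p.precedence_group, []).append(p)
        else:
            singles.append(p)

    to_add: list[str] = []
    for p in singles:
        if flags[p.name]:
            to_add.append(p.action_arg)
    for group, members in sorted(by_group.items()):
        members = sorted(members, key=lambda p: p.name)
        firing = [p for p in members if flags[p.name]]
        if not firing:
            continue
        if len(firing) == 1:
            to_add.append(firing[0].action_arg)
        else:
            to_add.append(precedence_args.get(group, members[0].action_arg))

    existing = set(reference.names())
    added: list[str] = []
    alleles = list(reference.alleles)
    for name in to_add:
        if name not in db.alleles:
            raise KeyError(f"refinement rule names unknown allele {name!r}")
        if name not in existing:
            alleles.append(db.alleles[name])
            existing.add(name)
            added.append(name)
    alleles.sort(key=lambda a: a.allele_name)
    return RefinementOutcome(
        reference=ReferenceSet(name=reference.name, alleles=tuple(alleles)),
        added=added, flags=flags,
    )


# -- probe table I/O --------------------------------------------------------

_COLUMNS = ["name", "target", "sequence", "threshold", "action", "action_arg",
            "precedence_group"]


def read_probe_table(path: str | Path) -> list[Probe]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table {path} missing columns {sorted(missing)}")
    return [
        Probe(
            name=r.name, target=r.target, sequence=r.sequence,
            threshold=int(r.threshold), action=r.action,
            action_arg=r.action_arg, precedence_group=r.precedence_group,
        )
        for r in df.itertuples(index=False)
    ]


def write_probe_table(probes: Sequence[Probe], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(p, c) for c in _COLUMNS} for p in probes]
    ).to_csv(path, sep="\t", index=False)
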