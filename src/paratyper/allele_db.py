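"""Allele database ingestion, imputation, UTR extension and reference design.

The allele database models a curated collection of named allele sequences for a
family of highly homologous genes (the KIR complex being the canonical
instance).  Many curated alleles are only partially characterized -- typically
exons only -- with uncharacterized stretches recorded as ``N``.  This module

* parses per-gene FASTA + multiple sequence alignments + a feature table into
  an :class:`AlleleDatabase`;
* imputes uncharacterized positions from alignment-invariant columns;
* extends 5'/3' untranslated regions to a fixed length using per-group donor
  sequences, so that alignment depth is available across the first exon;
* derives a small, diverse "minimized" reference allele set per gene/group.

Coordinates are 0-based half-open internally; file interfaces (feature table,
reports) are 1-based closed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

# Characterization states, per position.
STATE_UNCHARACTERIZED = 0  # unknown sequence ('N')
STATE_NATIVE = 1           # characterized in the source database
STATE_IMPUTED = 2          # filled from an alignment-invariant column
STATE_EXTENDED = 3         # filled from a UTR donor sequence

GAP = "-"
_NAME_RE = re.compile(r"^(?P<group>[A-Za-z0-9]+)\*(?P<digits>\d{3,7})$")


class DatabaseError(ValueError):
    """Raised for malformed or internally inconsistent database inputs."""


@dataclass(frozen=True)
class Feature:
    """A typed interval on an (ungapped) allele sequence.

    ``kind`` is one of ``5UTR``, ``exon_<k>``, ``intron_<k>``, ``3UTR``.
    ``start``/``end`` are 0-based half-open.
    """

    kind: str
    start: int
    end: int

    @property
    def is_exon(self) -> bool:
        return self.kind.startswith("exon")


@dataclass
class AlleleSequence:
    """One named allele of one gene.

    ``seq`` is the full-length sequence over ``{A,C,G,T,N}`` with ``N`` at
    uncharacterized positions.  ``states`` records, per position, whether the
    base is natively characterized, imputed, donor-extended or unknown.
    ``features`` tile ``[0, len(seq))`` without gaps or overlaps.

    Allele names follow the ``GROUP*digits`` grammar where the digit string
    carries resolution semantics: the first 3 digits identify the protein,
    the first 5 the coding sequence (synonymous level), and all 7 the full
    (non-coding) sequence.
    """

    gene: str
    major_group: str
    allele_name: str
    seq: str
    states: np.ndarray
    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if len(self.states) != len(self.seq):
            raise DatabaseError(
                f"{self.allele_name}: states length {len(self.states)} != "
                f"sequence length {len(self.seq)}"
            )
        uncharacterized = self.states == STATE_UNCHARACTERIZED
        seq_n = np.frombuffer(self.seq.encode(), dtype=np.uint8) == ord("N")
        if not np.array_equal(uncharacterized, seq_n):
            raise DatabaseError(
                f"{self.allele_name}: 'N' positions disagree with "
                "characterization states"
            )
        _check_features(self.features, len(self.seq), self.allele_name)

    # -- name resolution helpers ------------------------------------------
    @property
    def digits(self) -> str:
        m = _NAME_RE.match(self.allele_name)
        if not m:
            raise DatabaseError(f"bad allele name: {self.allele_name!r}")
        return m.group("digits")

    def name_at(self, resolution: int) -> str:
        """Allele name truncated to 3/5/7-digit resolution."""
        return f"{self.major_group}*{self.digits[:resolution]}"

    # -- characterization helpers -----------------------------------------
    @property
    def mask(self) -> np.ndarray:
        """Boolean characterized mask (native, imputed or extended)."""
        return self.states != STATE_UNCHARACTERIZED

    def characterized_fraction(self, *, native_only: bool = False) -> float:
        if native_only:
            return float(np.mean(self.states == STATE_NATIVE))
        return float(np.mean(self.mask))

    @property
    def is_fully_characterized(self) -> bool:
        return bool(self.mask.all())

    def feature_of_kind(self, kind: str) -> Feature:
        for f in self.features:
            if f.kind == kind:
                return f
        raise KeyError(f"{self.allele_name}: no feature {kind!r}")

    def exonic_mask(self) -> np.ndarray:
        m = np.zeros(len(self.seq), dtype=bool)
        for f in self.features:
            if f.is_exon:
                m[f.start:f.end] = True
        return m


def _check_features(features: Sequence[Feature], length: int, name: str) -> None:
    if not features:
        raise DatabaseError(f"{name}: no features")
    pos = 0
    for f in features:
        if f.start != pos or f.end <= f.start:
            raise DatabaseError(
                f"{name}: features must tile [0,{length}) in order; "
                f"got {f.kind} [{f.start},{f.end}) at offset {pos}"
            )
        pos = f.end
    if pos != length:
        raise DatabaseError(f"{name}: features end at {pos}, sequence length {length}")


@dataclass
class GeneMSA:
    """Per-gene multiple sequence alignment (gapped rows over ACGTN-)."""

    gene: str
    rows: dict[str, str]
    row_states: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lens = {len(r) for r in self.rows.values()}
        if len(lens) > 1:
            raise DatabaseError(f"{self.gene}: ragged MSA rows {sorted(lens)}")
        if not self.rows:
            raise DatabaseError(f"{self.gene}: empty MSA")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    def column_map(self, allele_name: str) -> np.ndarray:
        """Map ungapped position -> MSA column for one row."""
        row = np.frombuffer(self.rows[allele_name].encode(), dtype=np.uint8)
        return np.flatnonzero(row != ord(GAP))

    def matrix(self) -> tuple[list[str], np.ndarray]:
        names = sorted(self.rows)
        arr = np.vstack(
            [np.frombuffer(self.rows[n].encode(), dtype=np.uint8) for n in names]
        )
        return names, arr


@dataclass
class ReferenceSet:
    """A named collection of alleles used as an alignment reference."""

    name: str
    alleles: tuple[AlleleSequence, ...]

    def names(self) -> list[str]:
        return [a.allele_name for a in self.alleles]

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass
class AlleleDatabase:
    """All alleles of a gene family plus per-gene MSAs and UTR donors.

    ``groups`` maps each gene to its major allelic groups (most genes have a
    single group equal to the gene name; split loci list several).  The
    framework gene is assumed present at two copies in every individual and
    anchors copy-number normalization.
    """

    alleles: dict[str, AlleleSequence]
    msas: dict[str, GeneMSA]
    donors: dict[tuple[str, str], tuple[str, str]]
    groups: dict[str, list[str]]
    framework_gene: str

    def __post_init__(self) -> None:
        for a in self.alleles.values():
            if a.gene not in self.groups:
                raise DatabaseError(f"{a.allele_name}: gene {a.gene} not in groups")
            if a.major_group not in self.groups[a.gene]:
                raise DatabaseError(
                    f"{a.allele_name}: group {a.major_group} not a group of {a.gene}"
                )

    @property
    def group_names(self) -> list[str]:
        out: list[str] = []
        for g in sorted(self.groups):
            out.extend(self.groups[g])
        return out

    def alleles_of_group(self, group: str) -> list[AlleleSequence]:
        return sorted(
            (a for a in self.alleles.values() if a.major_group == group),
            key=lambda a: a.allele_name,
        )

    def gene_of_group(self, group: str) -> str:
        for gene, gs in self.groups.items():
            if group in gs:
                return gene
        raise KeyError(group)

    def group_of_allele(self, allele_name: str) -> str:
        return self.alleles[allele_name].major_group


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_allele_header(header: str) -> tuple[str, str, str]:
    """Parse ``GROUP*digits [gene=GENE]`` FASTA headers.

    Returns (allele_name, group, gene).  The gene defaults to the group
    label; split loci override it with an explicit ``gene=`` token.
    """
    parts = header.split()
    name = parts[0]
    m = _NAME_RE.match(name)
    if not m:
        raise DatabaseError(f"FASTA header {header!r} does not match GROUP*digits")
    group = m.group("group")
    gene = group
    for tok in parts[1:]:
        if tok.startswith("gene="):
            gene = tok[5:]
    return name, group, gene


def _read_feature_table(path: Path) -> dict[str, tuple[Feature, ...]]:
    df = pd.read_csv(path, sep="\t", dtype={"allele": str, "feature": str})
    required = {"allele", "feature", "start", "end"}
    if not required.issubset(df.columns):
        raise DatabaseError(f"feature table {path} missing columns {required - set(df.columns)}")
    out: dict[str, list[Feature]] = {}
    for row in df.itertuples(index=False):
        # file coordinates are 1-based closed
        out.setdefault(row.allele, []).append(
            Feature(row.feature, int(row.start) - 1, int(row.end))
        )
    return {k: tuple(sorted(v, key=lambda f: f.start)) for k, v in out.items()}


def _states_from_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.where(arr == ord("N"), STATE_UNCHARACTERIZED, STATE_NATIVE).astype(np.uint8)


def parse_database(
    allele_fasta: str | Path,
    msa_files: Iterable[str | Path],
    feature_table: str | Path,
    *,
    donor_fasta: str | Path | None = None,
    framework_gene: str,
    gene_of_group: Mapping[str, str] | None = None,
) -> AlleleDatabase:
    """Load an allele database from FASTA + MSA + feature-table files.

    ``msa_files`` are aligned FASTA (``.afa``/``.fasta``) or MSF files, one
    per gene, whose rows name alleles present in ``allele_fasta``.  An
    optional ``donor_fasta`` supplies UTR donors with headers
    ``GENE|GROUP|5UTR`` / ``GENE|GROUP|3UTR``; when absent, donors default to
    the longest fully characterized allele of each group at extension time.
    """
    allele_fasta = Path(allele_fasta)
    features = _read_feature_table(Path(feature_table))

    alleles: dict[str, AlleleSequence] = {}
    groups: dict[str, list[str]] = {}
    for i, rec in enumerate(SeqIO.parse(str(allele_fasta), "fasta")):
        try:
            name, group, gene = parse_allele_header(rec.description)
        except DatabaseError as e:
            raise DatabaseError(f"{allele_fasta} record {i + 1}: {e}") from e
        if gene_of_group and group in gene_of_group:
            gene = gene_of_group[group]
        seq = str(rec.seq).upper()
        if name not in features:
            raise DatabaseError(f"{name}: missing from feature table")
        alleles[name] = AlleleSequence(
            gene=gene,
            major_group=group,
            allele_name=name,
            seq=seq,
            states=_states_from_seq(seq),
            features=features[name],
        )
        groups.setdefault(gene, [])
        if group not in groups[gene]:
            groups[gene].append(group)

    msas: dict[str, GeneMSA] = {}
    for path in sorted(Path(p) for p in msa_files):
        fmt = "msf" if path.suffix.lower() == ".msf" else "fasta"
        try:
            aln = AlignIO.read(str(path), fmt)
        except ValueError as e:
            raise DatabaseError(f"{path}: unreadable or empty MSA ({e})") from e
        if len(aln) == 0:
            raise DatabaseError(f"{path}: empty MSA")
        rows: dict[str, str] = {}
        gene = None
        for rec in aln:
            rname = rec.id
            if rname not in alleles:
                raise DatabaseError(f"{path}: MSA row {rname!r} names unknown allele")
            rows[rname] = str(rec.seq).upper()
            gene = alleles[rname].gene
        msa = GeneMSA(gene=gene, rows=rows)
        for rname, row in rows.items():
            ungapped = row.replace(GAP, "")
            if ungapped != alleles[rname].seq:
                raise DatabaseError(
                    f"{path}: ungapped MSA row for {rname} disagrees with FASTA sequence"
                )
            msa.row_states[rname] = _project_states_to_row(
                alleles[rname].states, row
            )
        msas[gene] = msa

    donors: dict[tuple[str, str], tuple[str, str]] = {}
    if donor_fasta is not None:
        raw: dict[tuple[str, str, str], str] = {}
        for rec in SeqIO.parse(str(donor_fasta), "fasta"):
            try:
                gene, group, kind = rec.id.split("|")
            except ValueError as e:
                raise DatabaseError(f"donor header {rec.id!r} not GENE|GROUP|KIND") from e
            raw[(gene, group, kind)] = str(rec.seq).upper()
        for (gene, group, kind) in list(raw):
            if kind == "5UTR":
                key3 = (gene, group, "3UTR")
                if key3 not in raw:
                    raise DatabaseError(f"missing 3UTR donor for {gene}/{group}")
                donors[(gene, group)] = (raw[(gene, group, kind)], raw[key3])

    if framework_gene not in groups:
        raise DatabaseError(f"framework gene {framework_gene!r} absent from database")
    return AlleleDatabase(
        alleles=alleles, msas=msas, donors=donors, groups=groups,
        framework_gene=framework_gene,
    )


def _project_states_to_row(states: np.ndarray, row: str) -> np.ndarray:
    """Spread ungapped per-position states onto a gapped MSA row."""
    arr = np.frombuffer(row.encode(), dtype=np.uint8)
    out = np.full(len(row), STATE_NATIVE, dtype=np.uint8)  # gaps count as characterized
    nongap = arr != ord(GAP)
    out[nongap] = states
    return out


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    msa: GeneMSA
    alleles: list[AlleleSequence]
    zero_characterized_columns: np.ndarray  # column indices no row characterizes
    imputed_positions: dict[str, int]       # per allele, count of filled positions


def impute_msa(
    msa: GeneMSA, templates: Mapping[str, AlleleSequence] | None = None
) -> ImputationResult:
    """Fill uncharacterized positions from alignment-invariant columns.

    For every allele and every uncharacterized column: if all rows that are
    characterized at that column carry the same symbol (a base or a gap), the
    allele receives that symbol, flagged as characterized-by-imputation;
    otherwise the position stays ``N``.  Columns with zero characterized rows
    stay ``N`` and are reported.  Natively characterized positions are never
    altered.
    """
    names, arr = msa.matrix()
    n_code = ord("N")
    unchar = arr == n_code
    has_char = (~unchar).any(axis=0)
    lo = np.where(unchar, 255, arr).min(axis=0)
    hi = np.where(unchar, 0, arr).max(axis=0)
    invariant = has_char & (lo == hi)
    fill = lo  # valid where invariant

    new_rows: dict[str, str] = {}
    new_states: dict[str, np.ndarray] = {}
    imputed_counts: dict[str, int] = {}
    for i, name in enumerate(names):
        row = arr[i].copy()
        states = (
            msa.row_states[name].copy()
            if name in msa.row_states
            else np.where(row == n_code, STATE_UNCHARACTERIZED, STATE_NATIVE).astype(np.uint8)
        )
        fillable = (row == n_code) & invariant
        row[fillable] = fill[fillable]
        states[fillable] = STATE_IMPUTED
        imputed_counts[name] = int(fillable.sum())
        new_rows[name] = row.tobytes().decode()
        new_states[name] = states

    new_msa = GeneMSA(gene=msa.gene, rows=new_rows, row_states=new_states)
    alleles = []
    for name in names:
        tmpl = templates.get(name) if templates else None
        alleles.append(_allele_from_row(new_msa, name, tmpl))
    return ImputationResult(
        msa=new_msa,
        alleles=alleles,
        zero_characterized_columns=np.flatnonzero(~has_char),
        imputed_positions=imputed_counts,
    )


def _allele_from_row(
    msa: GeneMSA, name: str, template: AlleleSequence | None
) -> AlleleSequence:
    row = np.frombuffer(msa.rows[name].encode(), dtype=np.uint8)
    nongap = row != ord(GAP)
    seq = row[nongap].tobytes().decode()
    states = msa.row_states[name][nongap]
    if template is not None:
        feats = template.features
        gene, group = template.gene, template.major_group
        if sum(f.end - f.start for f in feats) != len(seq):
            # imputation can turn N rows into gapped rows of different ungapped
            # length only if gaps were imputed; rebuild a single span then
            feats = (Feature("gene", 0, len(seq)),)
    else:
        m = _NAME_RE.match(name)
        gene = group = m.group("group") if m else msa.gene
        feats = (Feature("gene", 0, len(seq)),)
    return AlleleSequence(
        gene=gene, major_group=group, allele_name=name,
        seq=seq, states=states, features=feats,
    )


def impute_database(db: AlleleDatabase) -> AlleleDatabase:
    """Apply :func:`impute_msa` to every gene of the database."""
    new_alleles: dict[str, AlleleSequence] = {}
    new_msas: dict[str, GeneMSA] = {}
    for gene, msa in db.msas.items():
        res = impute_msa(msa, templates=db.alleles)
        new_msas[gene] = res.msa
        for a in res.alleles:
            new_alleles[a.allele_name] = a
    for name, a in db.alleles.items():
        if name not in new_alleles:  # allele without an MSA row stays as-is
            new_alleles[name] = a
    return AlleleDatabase(
        alleles=new_alleles, msas=new_msas, donors=dict(db.donors),
        groups={g: list(v) for g, v in db.groups.items()},
        framework_gene=db.framework_gene,
    )


# ---------------------------------------------------------------------------
# UTR extension
# ---------------------------------------------------------------------------

def default_donors(db: AlleleDatabase, target_len: int) -> dict[tuple[str, str], tuple[str, str]]:
    """Derive UTR donors from the longest fully characterized allele per group.

    Used when no explicit donor FASTA was supplied.  The donor's own UTRs must
    already span ``target_len`` for the result to be usable.
    """
    donors: dict[tuple[str, str], tuple[str, str]] = {}
    for gene, gs in db.groups.items():
        for group in gs:
            cands = [a for a in db.alleles_of_group(group) if a.is_fully_characterized]
            if not cands:
                continue
            best = max(cands, key=lambda a: (len(a.seq), a.allele_name))
            try:
                f5 = best.feature_of_kind("5UTR")
                f3 = best.feature_of_kind("3UTR")
            except KeyError:
                continue
            donors[(gene, group)] = (best.seq[f5.start:f5.end], best.seq[f3.start:f3.end])
    return donors


def extend_utrs(db: AlleleDatabase, target_len: int = 1000) -> AlleleDatabase:
    """Pad every allele's 5' and 3' UTR to ``target_len`` using group donors.

    The appended sequence is the donor's terminal (outermost) portion: for a
    5'UTR of current length L the donor's first ``target_len - L`` bases are
    prepended; symmetrically for the 3'UTR.  Exon/intron sequence is untouched
    and feature intervals are re-indexed.  Alleles of one gene must share UTR
    feature lengths so that the gene MSA stays rectangular.
    """
    donors = dict(db.donors) or default_donors(db, target_len)

    new_alleles: dict[str, AlleleSequence] = {}
    new_msas: dict[str, GeneMSA] = {}
    for gene, msa in db.msas.items():
        row_alleles = [db.alleles[n] for n in msa.rows]
        len5 = {a.feature_of_kind("5UTR").end - a.feature_of_kind("5UTR").start
                for a in row_alleles}
        len3 = {a.feature_of_kind("3UTR").end - a.feature_of_kind("3UTR").start
                for a in row_alleles}
        if len(len5) > 1 or len(len3) > 1:
            raise DatabaseError(f"{gene}: alleles disagree on native UTR lengths")
        l5, l3 = len5.pop(), len3.pop()
        pad5, pad3 = target_len - l5, target_len - l3
        if pad5 < 0 or pad3 < 0:
            raise DatabaseError(f"{gene}: native UTRs exceed target {target_len}")

        new_rows: dict[str, str] = {}
        new_states: dict[str, np.ndarray] = {}
        for a in row_alleles:
            group_key = (gene, a.major_group)
            if group_key not in donors:
                raise DatabaseError(
                    f"no UTR donor for gene {gene} group {a.major_group}"
                )
            d5, d3 = donors[group_key]
            if len(d5) < target_len or len(d3) < target_len:
                raise DatabaseError(
                    f"donor for {gene}/{a.major_group} shorter than required "
                    f"{target_len}bp UTR"
                )
            head, tail = d5[:pad5], d3[target_len - pad3:] if pad3 else ""
            seq = head + a.seq + tail
            states = np.concatenate([
                np.full(pad5, STATE_EXTENDED, dtype=np.uint8),
                a.states,
                np.full(pad3, STATE_EXTENDED, dtype=np.uint8),
            ])
            feats = [Feature("5UTR", 0, target_len)]
            for f in a.features:
                if f.kind in ("5UTR", "3UTR"):
                    continue
                feats.append(Feature(f.kind, f.start + pad5, f.end + pad5))
            feats.append(Feature("3UTR", len(seq) - target_len, len(seq)))
            new_alleles[a.allele_name] = replace(
                a, seq=seq, states=states, features=tuple(feats)
            )
            new_rows[a.allele_name] = head + msa.rows[a.allele_name] + tail
            new_states[a.allele_name] = np.concatenate([
                np.full(pad5, STATE_EXTENDED, dtype=np.uint8),
                msa.row_states.get(
                    a.allele_name, _project_states_to_row(a.states, msa.rows[a.allele_name])
                ),
                np.full(pad3, STATE_EXTENDED, dtype=np.uint8),
            ])
        new_msas[gene] = GeneMSA(gene=gene, rows=new_rows, row_states=new_states)

    for name, a in db.alleles.items():
        new_alleles.setdefault(name, a)
    return AlleleDatabase(
        alleles=new_alleles, msas=new_msas, donors=donors,
        groups={g: list(v) for g, v in db.groups.items()},
        framework_gene=db.framework_gene,
    )


# ---------------------------------------------------------------------------
# Completeness report
# ---------------------------------------------------------------------------

def completeness_report(db: AlleleDatabase, *, native_only: bool = False) -> pd.DataFrame:
    """Characterized length of each allele / longest allele of its group.

    With ``native_only`` the imputed and donor-extended positions are not
    counted, giving the pre-imputation picture.
    """
    rows = []
    for group in db.group_names:
        members = db.alleles_of_group(group)
        if not members:
            continue
        longest = max(len(a.seq) for a in members)
        for a in members:
            if native_only:
                char = int(np.sum(a.states == STATE_NATIVE))
            else:
                char = int(np.sum(a.mask))
            rows.append({
                "allele": a.allele_name, "gene": a.gene, "group": group,
                "length": len(a.seq), "characterized": char,
                "fraction": char / longest,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minimized reference design
# ---------------------------------------------------------------------------

def _pairwise_distance(msa: GeneMSA, a: str, b: str) -> int:
    ra = np.frombuffer(msa.rows[a].encode(), dtype=np.uint8)
    rb = np.frombuffer(msa.rows[b].encode(), dtype=np.uint8)
    known = (ra != ord("N")) & (rb != ord("N"))
    return int(np.sum((ra != rb) & known))


def select_minimized_reference(
    db: AlleleDatabase,
    per_group: int = 5,
    *,
    force_include: Sequence[str] = (),
    completeness_floor: float = 0.95,
) -> ReferenceSet:
    """Select a small, diverse allele reference set (default 5 per group).

    Selection per gene/major group: candidates are restricted to (nearly)
    fully characterized alleles (characterized fraction >= ``completeness_floor``
    of the group's best, relaxed when too few qualify); the most complete
    allele seeds the set and the remainder are added greedily maximizing the
    minimum pairwise Hamming distance over MSA columns.  Ties break on
    lexicographic allele name, so the result is deterministic.  Alleles listed
    in ``force_include`` (e.g. cross-mapping "sequestration" pairs) are always
    added.
    """
    chosen: list[AlleleSequence] = []
    for group in db.group_names:
        members = db.alleles_of_group(group)
        if not members:
            continue
        if len(members) <= per_group:
            chosen.extend(members)
            continue
        gene = members[0].gene
        msa = db.msas.get(gene)
        fracs = {a.allele_name: a.characterized_fraction() for a in members}
        best_frac = max(fracs.values())
        cands = [a for a in members if fracs[a.allele_name] >= completeness_floor * best_frac]
        if len(cands) < per_group:
            cands = members
        # seed: most complete, name-lexicographic tie-break
        seed = max(cands, key=lambda a: (fracs[a.allele_name], _neg_name(a.allele_name)))
        picked = [seed]
        remaining = [a for a in cands if a.allele_name != seed.allele_name]
        while remaining and len(picked) < per_group:
            def min_dist(a: AlleleSequence) -> int:
                if msa is None:
                    return 0
                return min(_pairwise_distance(msa, a.allele_name, p.allele_name)
                           for p in picked)
            remaining.sort(key=lambda a: (-min_dist(a), a.allele_name))
            picked.append(remaining.pop(0))
        chosen.extend(sorted(picked, key=lambda a: a.allele_name))

    names_present = {a.allele_name for a in chosen}
    for name in force_include:
        if name not in db.alleles:
            raise DatabaseError(f"force_include allele {name!r} not in database")
        if name not in names_present:
            chosen.append(db.alleles[name])
            names_present.add(name)
    chosen.sort(key=lambda a: a.allele_name)
    return ReferenceSet(name=f"minimized_{per_group}", alleles=tuple(chosen))


class _neg_name(str):
    """Key wrapper inverting lexicographic order inside a max()."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# FASTA / manifest output
# ---------------------------------------------------------------------------

def write_allele_fasta(alleles: Iterable[AlleleSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in sorted(alleles, key=lambda x: x.allele_name):
            extra = f" gene={a.gene}" if a.gene != a.major_group else ""
            fh.write(f">{a.allele_name}{extra}\n")
            for i in range(0, len(a.seq), 80):
                fh.write(a.seq[i:i + 80] + "\n")


def write_reference_manifest(ref: ReferenceSet, path: str | Path) -> None:
    rows = [
        {
            "allele": a.allele_name, "gene": a.gene, "group": a.major_group,
            "length": len(a.seq),
            "characterized_fraction": a.characterized_fraction(),
        }
        for a in ref.alleles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
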