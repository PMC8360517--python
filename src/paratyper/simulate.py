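"""Truth-labeled synthetic gene families, genotypes and paired-end reads.

The simulator stands in for a curated allele database plus a sequenced
cohort.  It builds a family of highly homologous genes whose salient
structure mirrors the KIR complex:

* ~10 genes / major allelic groups with pairwise identity "hotspots"
  (clusters at 92-97% identity plus a pseudogene-analog sharing most of its
  read-length k-mers with a neighbor);
* per-gene allelic polymorphism (exonic "class" variants that define 5-digit
  resolution, non-coding variants that define 7-digit resolution, and a few
  private substitutions per allele);
* partially characterized alleles (exons-only masking) in a configurable
  fraction of the database;
* gene-content variable haplotype templates (gene absence and duplication),
  with a framework gene present on every haplotype;
* 150 bp paired-end reads at 50x coverage with a median fragment length of
  200 bp and a position-dependent substitution error rate, read names
  encoding the source sample/allele so every read can be traced back to
  truth.

Everything is deterministic under a seed: the family layout under the
family seed, cohort genotypes and reads under the cohort seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .allele_db import (
    STATE_NATIVE,
    STATE_UNCHARACTERIZED,
    AlleleDatabase,
    AlleleSequence,
    Feature,
    GeneMSA,
    write_allele_fasta,
)
from .probes import Probe, write_probe_table

FAMILY_SEED = 20210
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: exon/intron layout of the gene body (kind, length); UTRs are handled
#: separately (native 250 bp 5' / 500 bp 3', donors span 1000 bp each).
DEFAULT_BODY_LAYOUT: tuple[tuple[str, int], ...] = (
    ("exon_1", 140), ("intron_1", 220), ("exon_2", 300), ("intron_2", 260),
    ("exon_3", 280), ("intron_3", 230), ("exon_4", 170),
)


@dataclass(frozen=True)
class HaplotypeTemplate:
    """Gene content of one haplotype (group -> copies on the haplotype)."""

    name: str
    gene_content: Mapping[str, int]

    def copies(self, group: str) -> int:
        return int(self.gene_content.get(group, 0))


#: Haplotype templates capturing gene-content variation: absence (CNV1, GXA,
#: GXB, HSA/HSB, PSG), duplication (CNV1 on t04, GXB on t10), a large
#: deletion haplotype (t05), and the paired allelic groups DLA/DLB of the
#: split locus DLX, exactly one of which is present per haplotype.  The
#: framework gene FRW1 is on every template.
DEFAULT_TEMPLATES: tuple[HaplotypeTemplate, ...] = tuple(
    HaplotypeTemplate(name, content) for name, content in [
        ("t01", {"FRW1": 1, "CNV1": 1, "DST1": 1, "DLA": 1, "HSA": 1, "PSG": 1, "GXA": 1, "GXB": 1}),
        ("t02", {"FRW1": 1, "CNV1": 1, "DST1": 1, "DLB": 1, "HSB": 1, "PSG": 1, "GXA": 1, "GXB": 1}),
        ("t03", {"FRW1": 1, "DST1": 1, "DLA": 1, "HSB": 1, "PSG": 1, "GXA": 1, "GXB": 1}),
        ("t04", {"FRW1": 1, "CNV1": 2, "DST1": 1, "DLB": 1, "HSA": 1, "PSG": 1, "GXA": 1, "GXB": 1}),
        ("t05", {"FRW1": 1, "DST1": 1, "DLA": 1, "PSG": 1, "GXB": 1}),
        ("t06", {"FRW1": 1, "CNV1": 1, "DST1": 1, "DLB": 1, "HSA": 1, "HSB": 1, "PSG": 1, "GXA": 1, "GXB": 1}),
        ("t07", {"FRW1": 1, "DST1": 1, "DLB": 1, "HSB": 1, "PSG": 1, "GXA": 1}),
        ("t08", {"FRW1": 1, "CNV1": 1, "DST1": 1, "DLA": 1, "HSA": 1, "PSG": 1, "GXB": 1}),
        ("t09", {"FRW1": 1, "CNV1": 1, "DST1": 1, "DLA": 1, "HSB": 1, "GXA": 1, "GXB": 1}),
        ("t10", {"FRW1": 1, "CNV1": 1, "DST1": 1, "DLB": 1, "HSA": 1, "PSG": 1, "GXA": 1, "GXB": 2}),
        ("t11", {"FRW1": 1, "DST1": 1, "DLB": 1, "HSA": 1, "PSG": 1, "GXA": 1, "GXB": 1}),
    ]
)


@dataclass
class FamilyConfig:
    """Layout and polymorphism parameters of the synthetic family.

    ``clusters`` maps a cluster name to (member groups, pairwise identity):
    each member is derived from a shared ancestor so that realized pairwise
    identity approximates the configured level.  ``gene_of_group`` assigns
    groups of split loci to a common gene (DLA/DLB -> DLX).  The pseudogene
    analog ``PSG`` mirrors the allele set of ``HSA`` outside a short unique
    block, so that the bulk of its read-length k-mers are shared.
    """

    body_layout: tuple[tuple[str, int], ...] = DEFAULT_BODY_LAYOUT
    utr5_native: int = 250
    utr3_native: int = 500
    utr_target: int = 1000
    clusters: Mapping[str, tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: {
            "fw": (("FRW1",), 1.0),
            "dst": (("DST1",), 1.0),
            "cnv": (("CNV1",), 1.0),
            "dl": (("DLA", "DLB"), 0.97),
            "hs": (("HSA", "HSB"), 0.95),
            "gx": (("GXA", "GXB"), 0.92),
        }
    )
    gene_of_group: Mapping[str, str] = field(
        default_factory=lambda: {"DLA": "DLX", "DLB": "DLX"}
    )
    pseudogene: str = "PSG"
    pseudogene_source: str = "HSA"
    #: unique block of the pseudogene in extended coordinates (within exon_2)
    pseudogene_block: tuple[int, int] = (1450, 1650)
    n_exonic_classes: int = 6
    n_noncoding_variants: int = 2         # 7-digit sub-alleles of classes 1 and 2
    n_private_variants: int = 3
    masking_fraction: float = 0.375
    masking_overrides: Mapping[str, float] = field(
        default_factory=lambda: {"DST1": 0.0, "FRW1": 0.0}
    )
    #: allele carrying a gene-conversion tract from its cluster sibling;
    #: selected into the minimized reference to sequester cross-mapping reads
    conversion_allele: tuple[str, str, tuple[int, int]] = ("GXA", "GXB", (1850, 2250))
    framework_gene: str = "FRW1"
    templates: tuple[HaplotypeTemplate, ...] = DEFAULT_TEMPLATES
    family_seed: int = FAMILY_SEED

    @property
    def body_len(self) -> int:
        return sum(n for _, n in self.body_layout)

    @property
    def ext_len(self) -> int:
        return self.utr_target + self.body_len + self.utr_target

    @property
    def groups(self) -> list[str]:
        out = [g for _, (gs, _) in sorted(self.clusters.items()) for g in gs]
        out.append(self.pseudogene)
        return sorted(out)


# ---------------------------------------------------------------------------
# Family construction
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for p in hits:
        choices = _BASES[_BASES != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out


def _pick_positions(
    rng: np.random.Generator, pool: np.ndarray, n: int, spacing: int
) -> list[int]:
    """Draw n positions from pool with minimum pairwise spacing."""
    chosen: list[int] = []
    pool = pool.copy()
    rng.shuffle(pool)
    for p in pool:
        if all(abs(p - q) >= spacing for q in chosen):
            chosen.append(int(p))
            if len(chosen) == n:
                return chosen
    raise ValueError("cannot place variant positions with requested spacing")


@dataclass
class SyntheticFamily:
    """A built family: raw database + donors + templates + probe set."""

    config: FamilyConfig
    database: AlleleDatabase            # raw (native UTRs, masking applied)
    donors: dict[tuple[str, str], tuple[str, str]]
    templates: tuple[HaplotypeTemplate, ...]
    probes: list[Probe]
    haplotype_seqs: dict[str, str]      # template name -> reference sequence
    base_seqs: dict[str, str]           # group -> ancestral extended sequence

    def write_files(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA/MSA/feature/donor/template/probe files for the CLI."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["alleles"] = outdir / "alleles.fasta"
        write_allele_fasta(self.database.alleles.values(), paths["alleles"])

        msa_dir = outdir / "msa"
        msa_dir.mkdir(exist_ok=True)
        msa_paths = []
        for gene, msa in self.database.msas.items():
            p = msa_dir / f"{gene}.afa"
            with open(p, "w") as fh:
                for name in sorted(msa.rows):
                    fh.write(f">{name}\n{msa.rows[name]}\n")
            msa_paths.append(p)
        paths["msa_dir"] = msa_dir

        paths["features"] = outdir / "features.tsv"
        with open(paths["features"], "w") as fh:
            fh.write("allele\tfeature\tstart\tend\n")
            for name in sorted(self.database.alleles):
                for f in self.database.alleles[name].features:
                    fh.write(f"{name}\t{f.kind}\t{f.start + 1}\t{f.end}\n")

        paths["donors"] = outdir / "utr_donors.fasta"
        with open(paths["donors"], "w") as fh:
            for (gene, group), (d5, d3) in sorted(self.donors.items()):
                fh.write(f">{gene}|{group}|5UTR\n{d5}\n>{gene}|{group}|3UTR\n{d3}\n")

        paths["haplotypes"] = outdir / "haplotypes.fasta"
        with open(paths["haplotypes"], "w") as fh:
            for name, seq in sorted(self.haplotype_seqs.items()):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

        paths["templates"] = outdir / "templates.yaml"
        with open(paths["templates"], "w") as fh:
            yaml.safe_dump(
                {t.name: dict(t.gene_content) for t in self.templates}, fh
            )

        paths["probes"] = outdir / "probes.tsv"
        write_probe_table(self.probes, paths["probes"])

        cfg = self.config
        paths["config"] = outdir / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump({
                "family_seed": cfg.family_seed,
                "body_layout": [list(x) for x in cfg.body_layout],
                "utr5_native": cfg.utr5_native,
                "utr3_native": cfg.utr3_native,
                "utr_target": cfg.utr_target,
                "clusters": {
                    k: {"groups": list(gs), "identity": float(i)}
                    for k, (gs, i) in cfg.clusters.items()
                },
                "pseudogene": cfg.pseudogene,
                "pseudogene_source": cfg.pseudogene_source,
                "pseudogene_block": list(cfg.pseudogene_block),
                "n_exonic_classes": cfg.n_exonic_classes,
                "n_noncoding_variants": cfg.n_noncoding_variants,
                "n_private_variants": cfg.n_private_variants,
                "masking_fraction": cfg.masking_fraction,
                "masking_overrides": dict(cfg.masking_overrides),
                "framework_gene": cfg.framework_gene,
            }, fh, sort_keys=False)
        return paths


def load_templates(path: str | Path) -> tuple[HaplotypeTemplate, ...]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(HaplotypeTemplate(name, content) for name, content in sorted(raw.items()))


def build_family(
    config: FamilyConfig | None = None, seed: int | None = None
) -> SyntheticFamily:
    """Deterministically build the synthetic family under the family seed."""
    cfg = config or FamilyConfig()
    rng = np.random.default_rng(cfg.family_seed if seed is None else seed)
    L = cfg.ext_len
    body0 = cfg.utr_target  # body start in extended coordinates

    for tmpl in cfg.templates:
        if tmpl.copies(cfg.framework_gene) < 1:
            raise ValueError(f"template {tmpl.name} lacks the framework gene")

    # feature layout in extended coordinates
    feats_ext: list[Feature] = [Feature("5UTR", 0, body0)]
    pos = body0
    for kind, n in cfg.body_layout:
        feats_ext.append(Feature(kind, pos, pos + n))
        pos += n
    feats_ext.append(Feature("3UTR", pos, L))
    exon_pool = np.concatenate([
        np.arange(f.start + 21, f.end - 21) for f in feats_ext if f.is_exon
    ])
    intron_pool = np.concatenate([
        np.arange(f.start + 5, f.end - 5) for f in feats_ext
        if f.kind.startswith("intron")
    ])

    # gene base sequences from per-cluster ancestors
    base: dict[str, np.ndarray] = {}
    for cname in sorted(cfg.clusters):
        members, identity = cfg.clusters[cname]
        if not 0.0 <= identity <= 1.0:
            raise ValueError(f"cluster {cname}: identity {identity} outside [0,1]")
        root = _rand_seq(rng, L)
        rate = (1.0 - identity) / 2.0
        for g in members:
            base[g] = _mutate(rng, root, rate) if rate > 0 else root.copy()

    # per-group variant site maps (extended coordinates)
    nc = cfg.n_exonic_classes
    site_maps: dict[str, dict] = {}
    for g in sorted(base):
        sm = {
            "exonic": _pick_positions(rng, exon_pool, nc - 1, 50),
            "noncoding": _pick_positions(
                rng, intron_pool, (nc - 1) + cfg.n_noncoding_variants, 30
            ),
        }
        site_maps[g] = sm

    def alt_base(rng: np.random.Generator, ref: int) -> int:
        choices = _BASES[_BASES != ref]
        return int(choices[rng.integers(0, 3)])

    # allele construction: classes 1..nc (class c carries the exonic and
    # noncoding tag of index c-2, classes >= 2), plus 7-digit variants of
    # classes 1 and 2, plus private substitutions per allele.
    allele_ext: dict[str, np.ndarray] = {}
    allele_names: dict[str, list[str]] = {}
    conv_group, conv_source, conv_span = cfg.conversion_allele
    priv_lo, priv_hi = body0 - 190, L - cfg.utr_target + 90
    for g in sorted(base):
        sm = site_maps[g]
        names: list[str] = []
        tag_alts = {
            p: alt_base(rng, base[g][p]) for p in sm["exonic"] + sm["noncoding"]
        }
        sm["tag_alts"] = tag_alts
        specs = [(c, 1) for c in range(1, nc + 1)]
        specs += [(c, 2) for c in range(1, cfg.n_noncoding_variants + 1)]
        for c, v in specs:
            seq = base[g].copy()
            if c >= 2:
                pe = sm["exonic"][c - 2]
                seq[pe] = tag_alts[pe]
                pn = sm["noncoding"][c - 2]
                seq[pn] = tag_alts[pn]
            if v == 2:
                pv = sm["noncoding"][(nc - 1) + (c - 1)]
                seq[pv] = tag_alts[pv]
            name = f"{g}*{c:03d}01{v:02d}"
            if g == conv_group and c == nc and v == 1:
                seq[conv_span[0]:conv_span[1]] = base[conv_source][conv_span[0]:conv_span[1]]
            # private substitutions
            taken = set(tag_alts)
            for _ in range(cfg.n_private_variants):
                while True:
                    p = int(rng.integers(priv_lo, priv_hi))
                    if p not in taken:
                        taken.add(p)
                        break
                seq[p] = alt_base(rng, seq[p])
            allele_ext[name] = seq
            names.append(name)
        allele_names[g] = names

    # pseudogene: mirror the source gene's alleles outside a unique block;
    # in-block class tags for classes 2 and 3 keep it minimally genotypeable
    ps = cfg.pseudogene
    b0, b1 = cfg.pseudogene_block
    ps_block = _rand_seq(rng, b1 - b0)
    block_exon = np.arange(b0 + 21, b1 - 21)
    ps_tags = _pick_positions(rng, block_exon, 2, 45)
    ps_names: list[str] = []
    src_tags = site_maps[cfg.pseudogene_source]
    for src_name in allele_names[cfg.pseudogene_source]:
        c, v = int(src_name.split("*")[1][:3]), int(src_name.split("*")[1][5:7])
        seq = allele_ext[src_name].copy()
        seq[b0:b1] = ps_block
        if c >= 2:
            # do not mirror the source gene's exonic class tag: those
            # windows must stay diagnostic for the source gene's probes
            pe = src_tags["exonic"][c - 2]
            seq[pe] = base[cfg.pseudogene_source][pe]
        if c in (2, 3):
            p = ps_tags[c - 2]
            seq[p] = alt_base(rng, seq[p])
        name = f"{ps}*{c:03d}01{v:02d}"
        allele_ext[name] = seq
        ps_names.append(name)
    allele_names[ps] = ps_names
    base[ps] = np.concatenate([base[cfg.pseudogene_source][:b0], ps_block,
                               base[cfg.pseudogene_source][b1:]])

    # cut raw alleles (native UTR extents), apply exons-only masking
    raw_lo = body0 - cfg.utr5_native
    raw_hi = body0 + cfg.body_len + cfg.utr3_native
    shift = -raw_lo
    feats_raw = [Feature("5UTR", 0, cfg.utr5_native)]
    feats_raw += [
        Feature(f.kind, f.start + shift, f.end + shift)
        for f in feats_ext if f.kind not in ("5UTR", "3UTR")
    ]
    feats_raw.append(
        Feature("3UTR", cfg.utr5_native + cfg.body_len, raw_hi - raw_lo)
    )
    feats_raw_t = tuple(feats_raw)
    exon_mask_raw = np.zeros(raw_hi - raw_lo, dtype=bool)
    for f in feats_raw_t:
        if f.is_exon:
            exon_mask_raw[f.start:f.end] = True

    alleles: dict[str, AlleleSequence] = {}
    msas: dict[str, GeneMSA] = {}
    groups: dict[str, list[str]] = {}
    conv_allele_name = f"{conv_group}*{nc:03d}0101"
    for g, names in sorted(allele_names.items()):
        gene = cfg.gene_of_group.get(g, g)
        groups.setdefault(gene, [])
        if g not in groups[gene]:
            groups[gene].append(g)
        frac = cfg.masking_overrides.get(g, cfg.masking_fraction)
        n_mask = int(round(frac * len(names)))
        # mask the highest classes first, never the sequestration allele
        mask_order = [n for n in sorted(names, key=_mask_priority) if n != conv_allele_name]
        masked = set(mask_order[:n_mask])
        for name in names:
            arr = allele_ext[name][raw_lo:raw_hi]
            states = np.full(len(arr), STATE_NATIVE, dtype=np.uint8)
            if name in masked:
                arr = arr.copy()
                arr[~exon_mask_raw] = ord("N")
                states[~exon_mask_raw] = STATE_UNCHARACTERIZED
            seq = arr.tobytes().decode()
            alleles[name] = AlleleSequence(
                gene=gene, major_group=g, allele_name=name,
                seq=seq, states=states, features=feats_raw_t,
            )
    # gap-free MSAs: rows are the raw sequences themselves
    for gene, gs in groups.items():
        rows = {}
        row_states = {}
        for g in gs:
            for name in allele_names[g]:
                rows[name] = alleles[name].seq
                row_states[name] = alleles[name].states.copy()
        msas[gene] = GeneMSA(gene=gene, rows=rows, row_states=row_states)

    donors = {
        (cfg.gene_of_group.get(g, g), g): (
            base[g][:cfg.utr_target].tobytes().decode(),
            base[g][cfg.utr_target + cfg.body_len:].tobytes().decode(),
        )
        for g in allele_names
    }

    db = AlleleDatabase(
        alleles=alleles, msas=msas, donors=donors, groups=groups,
        framework_gene=cfg.framework_gene,
    )

    # haplotype reference sequences: representative allele per group on the
    # template, joined by random intergenic spacers
    hap_seqs: dict[str, str] = {}
    for tmpl in cfg.templates:
        parts: list[str] = []
        for g in sorted(tmpl.gene_content):
            rep = allele_ext[f"{g}*0010101"]
            parts.append(_rand_seq(rng, 400).tobytes().decode())
            parts.append(rep.tobytes().decode())
        parts.append(_rand_seq(rng, 400).tobytes().decode())
        hap_seqs[tmpl.name] = "".join(parts)

    probes = _build_probes(cfg, allele_ext, site_maps, base)

    return SyntheticFamily(
        config=cfg, database=db, donors=donors, templates=cfg.templates,
        probes=probes, haplotype_seqs=hap_seqs,
        base_seqs={g: s.tobytes().decode() for g, s in base.items()},
    )


def _mask_priority(name: str) -> tuple:
    """Masking order: highest protein classes first, then 7-digit variants."""
    digits = name.split("*")[1]
    return (-int(digits[:3]), -int(digits[5:7]))


def _build_probes(
    cfg: FamilyConfig,
    allele_ext: Mapping[str, np.ndarray],
    site_maps: Mapping[str, dict],
    base: Mapping[str, np.ndarray],
) -> list[Probe]:
    """Refinement probes for HSA classes 4/5/6 (with precedence on class 4)
    plus a presence probe for the copy-variable gene."""
    probes: list[Probe] = []
    g = "HSA"
    nc = cfg.n_exonic_classes
    for c in (4, 5, 6):
        if c > nc:
            continue
        p = site_maps[g]["exonic"][c - 2]
        seq = allele_ext[f"{g}*{c:03d}0101"][p - 20:p + 21].tobytes().decode()
        probes.append(Probe(
            name=f"{g}-{c:03d}", target=f"{g}*{c:03d}", sequence=seq,
            threshold=10, action="add_reference_allele",
            action_arg=f"{g}*{c:03d}0101", precedence_group=f"{g}-rule",
        ))
    # presence probe: a window of the copy-variable gene's base sequence
    cseq = base["CNV1"][1510:1551].tobytes().decode()
    probes.append(Probe(
        name="CNV1-presence", target="CNV1*", sequence=cseq,
        threshold=10, action="presence_flag",
    ))
    return probes


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Simulated truth for one sample: copies, allele draws, read sources."""

    sample_id: str
    template_pair: tuple[str, str]
    copies: dict[str, int]                    # group -> copy number
    alleles: dict[str, tuple[str, ...]]       # group -> allele names drawn
    seqs: dict[str, str]                      # allele name -> patched sequence

    def allele_multiset(self, group: str) -> tuple[str, ...]:
        return self.alleles.get(group, ())


def sample_genotype(
    db: AlleleDatabase,
    templates: Sequence[HaplotypeTemplate],
    rng: np.random.Generator,
    sample_id: str,
) -> TruthRecord:
    """Draw a sample genotype: two templates with replacement, then alleles
    without replacement per group, patching uncharacterized stretches from a
    random fully characterized allele of the same group.

    ``db`` must be the imputed and UTR-extended database: simulated reads are
    drawn from the same sequence set the genotyper aligns against.
    """
    i, j = rng.integers(0, len(templates), size=2)
    ta, tb = templates[i], templates[j]
    copies: dict[str, int] = {}
    for g in db.group_names:
        copies[g] = ta.copies(g) + tb.copies(g)

    alleles: dict[str, tuple[str, ...]] = {}
    seqs: dict[str, str] = {}
    for g, cp in copies.items():
        if cp == 0:
            continue
        pool = [a.allele_name for a in db.alleles_of_group(g)]
        if cp > len(pool):
            raise ValueError(
                f"{sample_id}: copy {cp} for {g} exceeds allele pool ({len(pool)})"
            )
        drawn = list(rng.choice(len(pool), size=cp, replace=False))
        names = tuple(sorted(pool[k] for k in drawn))
        alleles[g] = names
        full = [a for a in db.alleles_of_group(g) if a.is_fully_characterized]
        for name in names:
            seqs[name] = _patch_uncharacterized(db.alleles[name], full, rng)
    return TruthRecord(
        sample_id=sample_id, template_pair=(ta.name, tb.name),
        copies=copies, alleles=alleles, seqs=seqs,
    )


def _patch_uncharacterized(
    allele: AlleleSequence, donors: Sequence[AlleleSequence],
    rng: np.random.Generator,
) -> str:
    arr = np.frombuffer(allele.seq.encode(), dtype=np.uint8).copy()
    unknown = arr == ord("N")
    if not unknown.any():
        return allele.seq
    if not donors:
        raise ValueError(
            f"{allele.allele_name}: uncharacterized regions but no fully "
            "characterized allele in its group to patch from"
        )
    # per uncharacterized run, pick one random donor of matching length
    edges = np.flatnonzero(np.diff(np.concatenate([[0], unknown.view(np.int8), [0]])))
    for s, e in zip(edges[::2], edges[1::2]):
        donor = donors[rng.integers(0, len(donors))]
        if len(donor.seq) != len(allele.seq):
            raise ValueError(
                f"patching {allele.allele_name}: donor {donor.allele_name} "
                "length mismatch"
            )
        arr[s:e] = np.frombuffer(donor.seq.encode(), dtype=np.uint8)[s:e]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def default_error_profile(read_len: int = 150) -> np.ndarray:
    """Per-cycle substitution rate: logistic ramp from ~0.2% to ~0.6%."""
    i = np.arange(read_len)
    return 0.002 + 0.004 / (1.0 + np.exp(-(i - 0.5 * read_len) / 15.0))


@dataclass
class ReadPairBatch:
    names: list[str]
    r1: list[str]
    r2: list[str]

    def __len__(self) -> int:
        return len(self.names)


def parse_read_name(name: str) -> tuple[str, str, int]:
    """Recover (sample, source allele, fragment index) from a read name."""
    sample, allele, frag = name.rsplit("|", 2)
    return sample, allele, int(frag)


def simulate_reads(
    truth: TruthRecord,
    *,
    read_len: int = 150,
    coverage: float = 50.0,
    frag_median: int = 200,
    frag_sd: int = 40,
    error_profile: np.ndarray | None = None,
    rng: np.random.Generator,
) -> ReadPairBatch:
    """Simulate paired-end reads from every allele copy of a sample.

    Fragment lengths are normal around the median (clipped to
    [read_len, 2*frag_median]); fragment starts are uniform; substitution
    errors follow the per-cycle profile.  Read names encode
    ``sample|allele|fragment`` so truth is recoverable from any read.
    """
    rate = default_error_profile(read_len) if error_profile is None else error_profile
    names: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    if coverage <= 0:
        return ReadPairBatch(names, r1, r2)
    for g in sorted(truth.alleles):
        for allele_name in truth.alleles[g]:
            seq = truth.seqs[allele_name]
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            if (arr == ord("N")).any():
                raise ValueError(f"{allele_name}: unpatched N in simulated sequence")
            L = len(arr)
            n_frags = int(round(L * coverage / (2.0 * read_len)))
            if n_frags == 0:
                continue
            flens = np.clip(
                np.rint(rng.normal(frag_median, frag_sd, size=n_frags)).astype(int),
                read_len, min(L, 2 * frag_median),
            )
            starts = (rng.random(n_frags) * (L - flens + 1)).astype(int)
            idx1 = starts[:, None] + np.arange(read_len)[None, :]
            m1 = arr[idx1]
            ends = starts + flens
            idx2 = ends[:, None] - 1 - np.arange(read_len)[None, :]
            m2 = _COMP_TABLE[arr[idx2]]
            for m in (m1, m2):
                err = rng.random(m.shape) < rate[None, :]
                if err.any():
                    rows, cols = np.nonzero(err)
                    cur = m[rows, cols]
                    # substitute with one of the three other bases
                    offs = rng.integers(1, 4, size=len(rows))
                    m[rows, cols] = _BASES[(_CODE[cur] + offs) % 4]
            for k in range(n_frags):
                names.append(f"{truth.sample_id}|{allele_name}|{k:05d}")
                r1.append(m1[k].tobytes().decode())
                r2.append(m2[k].tobytes().decode())
    return ReadPairBatch(names, r1, r2)


_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _CODE[_a] = _i


# ---------------------------------------------------------------------------
# FASTQ / truth table I/O
# ---------------------------------------------------------------------------

def write_fastq_pair(
    batch: ReadPairBatch, path1: str | Path, path2: str | Path
) -> None:
    for path, seqs in ((path1, batch.r1), (path2, batch.r2)):
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(str(path), "wt") as fh:
            for name, seq in zip(batch.names, seqs):
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_table(records: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttemplates\tgroup\tcopy\talleles\n")
        for t in records:
            for g in sorted(t.copies):
                alleles = ",".join(t.alleles.get(g, ()))
                fh.write(
                    f"{t.sample_id}\t{t.template_pair[0]},{t.template_pair[1]}\t"
                    f"{g}\t{t.copies[g]}\t{alleles}\n"
                )


def read_truth_table(path: str | Path) -> dict[str, dict[str, tuple[int, tuple[str, ...]]]]:
    out: dict[str, dict[str, tuple[int, tuple[str, ...]]]] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("sample")
        for line in fh:
            sample, _, group, cp, alleles = line.rstrip("\n").split("\t")
            allele_names = tuple(a for a in alleles.split(",") if a)
            out.setdefault(sample, {})[group] = (int(cp), allele_names)
    return out
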