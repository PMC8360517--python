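import numpy as np
import pytest

from paratyper.allele_db import (
    STATE_NATIVE,
    AlleleDatabase,
    AlleleSequence,
    Feature,
    GeneMSA,
)
from paratyper.pipeline import PreparedFamily, prepare_family
from paratyper.simulate import SyntheticFamily, build_family


@pytest.fixture(scope="session")
def family() -> SyntheticFamily:
    return build_family()


@pytest.fixture(scope="session")
def prepared(family) -> PreparedFamily:
    """Family with imputed+extended database and all reference indexes."""
    return prepare_family(family)


def make_allele(
    name: str,
    seq: str,
    *,
    gene: str | None = None,
    group: str | None = None,
    features: tuple[Feature, ...] | None = None,
) -> AlleleSequence:
    """Hand-rolled allele for toy fixtures; N positions are uncharacterized."""
    m = name.split("*")
    group = group or m[0]
    gene = gene or group
    states = np.where(
        np.frombuffer(seq.encode(), np.uint8) == ord("N"), 0, STATE_NATIVE
    ).astype(np.uint8)
    return AlleleSequence(
        gene=gene, major_group=group, allele_name=name, seq=seq,
        states=states,
        features=features or (Feature("gene", 0, len(seq)),),
    )


def make_db(alleles: list[AlleleSequence], framework: str,
            msas: dict[str, GeneMSA] | None = None) -> AlleleDatabase:
    groups: dict[str, list[str]] = {}
    for a in alleles:
        groups.setdefault(a.gene, [])
        if a.major_group not in groups[a.gene]:
            groups[a.gene].append(a.major_group)
    if msas is None:
        msas = {}
        for gene in groups:
            rows = {
                a.allele_name: a.seq for a in alleles if a.gene == gene
            }
            if len({len(s) for s in rows.values()}) == 1:
                msa = GeneMSA(gene=gene, rows=rows)
                for a in alleles:
                    if a.gene == gene:
                        msa.row_states[a.allele_name] = a.states.copy()
                msas[gene] = msa
    return AlleleDatabase(
        alleles={a.allele_name: a for a in alleles},
        msas=msas, donors={}, groups=groups, framework_gene=framework,
    )
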