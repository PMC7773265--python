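"""Shared fixtures: small hand-built pedigrees and genotype matrices."""

from __future__ import annotations

import numpy as np
import pytest

from pedlink.pedio import (
    GenotypeMatrix,
    Individual,
    Marker,
    Pedigree,
    Phenotype,
    Sex,
)


def make_individual(iid, fid="F1", father=None, mother=None, sex="M", pheno="U"):
    return Individual(
        individual_id=iid,
        family_id=fid,
        father_id=father,
        mother_id=mother,
        sex={"M": Sex.MALE, "F": Sex.FEMALE, "?": Sex.UNKNOWN}[sex],
        phenotype={
            "A": Phenotype.AFFECTED,
            "U": Phenotype.UNAFFECTED,
            "?": Phenotype.UNKNOWN,
        }[pheno],
    )


def make_markers(n, chromosome="1", spacing_cm=1.0, freq=0.5, start_bp=1_000_000):
    return [
        Marker(
            name=f"m{i:03d}",
            chromosome=chromosome,
            bp=start_bp + i * 1_000_000,
            cm=i * spacing_cm,
            freq=freq,
        )
        for i in range(n)
    ]


def make_matrix(pedigrees, markers, calls_by_iid):
    """calls_by_iid: {iid: [(a, b), ...]} aligned with `markers`."""
    samples, rows = [], []
    for ped in pedigrees:
        for ind in ped.members:
            samples.append((ped.family_id, ind.individual_id))
            rows.append(calls_by_iid[ind.individual_id])
    return GenotypeMatrix(
        markers=list(markers),
        samples=samples,
        calls=np.array(rows, dtype=np.uint8),
    )


@pytest.fixture
def trio():
    """Father 1/1, mother 1/2, child 1/2 at one marker."""
    ped = Pedigree(
        "F1",
        [
            make_individual("fa", sex="M", pheno="A"),
            make_individual("mo", sex="F", pheno="U"),
            make_individual("ch", father="fa", mother="mo", sex="M", pheno="A"),
        ],
    )
    markers = make_markers(1)
    geno = make_matrix([ped], markers, {"fa": [(1, 1)], "mo": [(1, 2)], "ch": [(1, 2)]})
    return ped, geno


@pytest.fixture
def nuclear5():
    """Two parents, three children; no genotypes attached."""
    return Pedigree(
        "F1",
        [
            make_individual("fa", sex="M", pheno="A"),
            make_individual("mo", sex="F", pheno="U"),
            make_individual("k1", father="fa", mother="mo", sex="M", pheno="A"),
            make_individual("k2", father="fa", mother="mo", sex="F", pheno="U"),
            make_individual("k3", father="fa", mother="mo", sex="M", pheno="A"),
        ],
    )


@pytest.fixture
def threegen8():
    """Eight members, five nonfounders (ten meiosis bits), three founders."""
    return Pedigree(
        "F1",
        [
            make_individual("gf", sex="M", pheno="A"),
            make_individual("gm", sex="F", pheno="U"),
            make_individual("c1", father="gf", mother="gm", sex="M", pheno="A"),
            make_individual("c2", father="gf", mother="gm", sex="F", pheno="U"),
            make_individual("c3", father="gf", mother="gm", sex="M", pheno="A"),
            make_individual("s1", sex="F", pheno="U"),
            make_individual("g1", father="c1", mother="s1", sex="M", pheno="A"),
            make_individual("g2", father="c1", mother="s1", sex="F", pheno="U"),
        ],
    )
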