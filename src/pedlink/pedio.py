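"""Pedigree and genotype I/O.

Core domain types (:class:`Individual`, :class:`Pedigree`, :class:`Marker`,
:class:`GenotypeMatrix`), whitespace-delimited PED/MAP readers and writers,
structural validation (parent references, cycles, marriage loops) and
Mendelian-error checking.

Conventions
-----------
* phenotype codes on disk: 0 = unknown, 1 = unaffected, 2 = affected;
* allele code 0 = missing; alleles are normalised internally to {1, 2}
  per marker (lexicographically smallest observed symbol becomes 1);
* a half-typed genotype (one allele missing) is treated as fully missing;
* physical coordinates are 1-based inclusive; intervals are closed;
* autosomes only -- sex chromosomes are rejected with an explicit error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Sex",
    "Phenotype",
    "Individual",
    "Pedigree",
    "Marker",
    "GenotypeMatrix",
    "PedigreeError",
    "ParseError",
    "read_ped_map",
    "write_ped_map",
    "mendelian_check",
    "set_violations_missing",
]

MISSING = 0

_SEX_CHROMS = {"X", "Y", "XY", "MT", "M", "23", "24", "25", "26"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree or genotype matrix."""


class ParseError(ValueError):
    """Malformed PED/MAP input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class Sex(enum.Enum):
    MALE = 1
    FEMALE = 2
    UNKNOWN = 0


class Phenotype(enum.Enum):
    UNKNOWN = 0
    UNAFFECTED = 1
    AFFECTED = 2


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.individual_id}: father and mother must be "
                "both present or both absent"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class Pedigree:
    """A single family: ordered members with validated structure."""

    family_id: str
    members: list[Individual]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {}
        for i, ind in enumerate(self.members):
            if ind.individual_id in self._index:
                raise PedigreeError(
                    f"family {self.family_id}: duplicated individual id "
                    f"{ind.individual_id!r}"
                )
            self._index[ind.individual_id] = i
        self._validate()

    def _validate(self):
        for ind in self.members:
            for pid, want in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {pid!r} of "
                        f"{ind.individual_id!r} is not a member"
                    )
                parent = self[pid]
                bad = Sex.FEMALE if want is Sex.MALE else Sex.MALE
                if parent.sex is bad:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {pid!r} has "
                        f"inconsistent sex for its role"
                    )
        # acyclicity of the parent->child relation
        g = nx.DiGraph()
        g.add_nodes_from(self._index)
        for ind in self.members:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    g.add_edge(pid, ind.individual_id)
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError(
                f"family {self.family_id}: pedigree contains an ancestry cycle"
            )
        if not any(
            self[ind.father_id].is_founder and self[ind.mother_id].is_founder
            for ind in self.members
            if not ind.is_founder
        ) and self.nonfounders():
            raise PedigreeError(
                f"family {self.family_id}: no founder couple present"
            )

    def __getitem__(self, individual_id: str) -> Individual:
        return self.members[self._index[individual_id]]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def __len__(self) -> int:
        return len(self.members)

    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def topological_order(self) -> list[Individual]:
        """Members ordered so every parent precedes its children."""
        g = nx.DiGraph()
        g.add_nodes_from(self._index)
        for ind in self.members:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    g.add_edge(pid, ind.individual_id)
        order = list(nx.lexicographical_topological_sort(g, key=lambda v: self._index[v]))
        return [self[i] for i in order]

    def couples(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for ind in self.members:
            if not ind.is_founder:
                seen.setdefault((ind.father_id, ind.mother_id), None)
        return list(seen)

    def has_loops(self) -> bool:
        """Marriage/ancestry loop detection on the couple graph.

        The pedigree graph with one node per individual, one node per
        couple, and edges partner--couple and couple--child is a tree for
        loop-free pedigrees.
        """
        g = nx.Graph()
        for ind in self.members:
            g.add_node(("i", ind.individual_id))
        for fa, mo in self.couples():
            cnode = ("c", fa, mo)
            g.add_edge(("i", fa), cnode)
            g.add_edge(("i", mo), cnode)
        for ind in self.members:
            if not ind.is_founder:
                g.add_edge(("c", ind.father_id, ind.mother_id), ("i", ind.individual_id))
        n_components = nx.number_connected_components(g)
        return g.number_of_edges() > g.number_of_nodes() - n_components


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with physical and genetic coordinates.

    ``freq`` is the population frequency of the first allele (internal
    code 1).
    """

    name: str
    chromosome: str
    bp: int
    cm: float
    alleles: tuple[str, str] = ("1", "2")
    freq: float = 0.5

    def __post_init__(self):
        if self.chromosome.upper() in _SEX_CHROMS:
            raise PedigreeError(
                f"marker {self.name}: sex chromosome {self.chromosome!r} is "
                "not supported (autosomal analysis only)"
            )
        if self.bp < 1:
            raise PedigreeError(f"marker {self.name}: bp must be >= 1")
        if not 0.0 < self.freq < 1.0:
            raise PedigreeError(f"marker {self.name}: freq must lie in (0, 1)")

    @property
    def maf(self) -> float:
        return min(self.freq, 1.0 - self.freq)


def sort_markers(markers: Iterable[Marker]) -> list[Marker]:
    """Within-chromosome order: by cM, ties broken by bp."""
    return sorted(markers, key=lambda m: (m.chromosome, m.cm, m.bp))


@dataclass
class GenotypeMatrix:
    """Unordered allele-pair calls for (sample, marker).

    ``calls`` has shape (n_samples, n_markers, 2), dtype uint8, allele
    codes 1/2 and 0 for missing.  Samples are keyed by
    (family_id, individual_id).
    """

    markers: list[Marker]
    samples: list[tuple[str, str]]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.shape != (len(self.samples), len(self.markers), 2):
            raise PedigreeError(
                f"genotype array shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        # half-typed genotypes count as fully missing
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        self._row = {s: i for i, s in enumerate(self.samples)}
        self._col = {m.name: j for j, m in enumerate(self.markers)}

    def row(self, family_id: str, individual_id: str) -> int:
        return self._row[(family_id, individual_id)]

    def col(self, marker_name: str) -> int:
        if marker_name not in self._col:
            raise KeyError(f"marker {marker_name!r} absent from genotype matrix")
        return self._col[marker_name]

    def get(self, family_id: str, individual_id: str, marker_name: str) -> tuple[int, int]:
        g = self.calls[self.row(family_id, individual_id), self.col(marker_name)]
        return int(g[0]), int(g[1])

    def has_sample(self, family_id: str, individual_id: str) -> bool:
        return (family_id, individual_id) in self._row

    def subset_markers(self, names: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.col(n) for n in names]
        return GenotypeMatrix(
            markers=[self.markers[c] for c in cols],
            samples=list(self.samples),
            calls=self.calls[:, cols].copy(),
        )

    def family_rows(self, family_id: str) -> dict[str, int]:
        return {iid: i for (fid, iid), i in self._row.items() if fid == family_id}

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.markers), list(self.samples), self.calls.copy())


# ---------------------------------------------------------------------------
# PED/MAP parsing


def _parse_sex(code: str, line: int) -> Sex:
    try:
        return {0: Sex.UNKNOWN, 1: Sex.MALE, 2: Sex.FEMALE}[int(code)]
    except (KeyError, ValueError):
        raise ParseError(f"bad sex code {code!r}", line) from None


def _parse_phenotype(code: str, line: int) -> Phenotype:
    try:
        return {
            0: Phenotype.UNKNOWN,
            -9: Phenotype.UNKNOWN,
            1: Phenotype.UNAFFECTED,
            2: Phenotype.AFFECTED,
        }[int(code)]
    except (KeyError, ValueError):
        raise ParseError(f"bad phenotype code {code!r}", line) from None


def read_map(map_path: str | Path) -> list[Marker]:
    """MAP columns: chromosome, name, cM, bp[, freq-of-first-allele]."""
    markers: list[Marker] = []
    with open(map_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) not in (4, 5):
                raise ParseError(f"expected 4 or 5 MAP columns, got {len(parts)}", ln)
            chrom, name, cm, bp = parts[:4]
            freq = float(parts[4]) if len(parts) == 5 else 0.5
            try:
                markers.append(
                    Marker(name=name, chromosome=chrom, bp=int(bp), cm=float(cm), freq=freq)
                )
            except ValueError as exc:
                if isinstance(exc, PedigreeError):
                    raise
                raise ParseError(str(exc), ln) from None
    return markers


def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[list[Pedigree], GenotypeMatrix]:
    """Read whitespace-delimited PED/MAP into validated pedigrees + genotypes.

    PED columns: family, id, father, mother, sex, phenotype, then two allele
    columns per marker.  Allele symbols may be 1/2/0 or ACGT/0 per marker;
    they are normalised to internal codes {1, 2} with 0 = missing.
    """
    markers = read_map(map_path)
    n_mark = len(markers)
    rows: list[tuple[str, str]] = []
    inds: dict[str, list[Individual]] = {}
    raw_calls: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 6 + 2 * n_mark:
                raise ParseError(
                    f"expected {6 + 2 * n_mark} PED columns for {n_mark} "
                    f"markers, got {len(parts)}",
                    ln,
                )
            fid, iid, fat, mot = parts[:4]
            ind = Individual(
                individual_id=iid,
                family_id=fid,
                father_id=None if fat == "0" else fat,
                mother_id=None if mot == "0" else mot,
                sex=_parse_sex(parts[4], ln),
                phenotype=_parse_phenotype(parts[5], ln),
            )
            inds.setdefault(fid, []).append(ind)
            rows.append((fid, iid))
            raw_calls.append(parts[6:])

    # per-marker allele normalisation
    calls = np.zeros((len(rows), n_mark, 2), dtype=np.uint8)
    norm_markers: list[Marker] = []
    for j, marker in enumerate(markers):
        symbols = sorted(
            {
                raw_calls[i][2 * j + k]
                for i in range(len(rows))
                for k in (0, 1)
            }
            - {"0"}
        )
        if len(symbols) > 2:
            raise ParseError(
                f"marker {marker.name}: more than two alleles observed: {symbols}"
            )
        table = {"0": MISSING}
        if set(symbols) <= {"1", "2"}:
            table.update({"1": 1, "2": 2})  # numeric codes pass through
            symbols = ["1", "2"]
        else:
            for code, sym in enumerate(symbols, start=1):
                table[sym] = code
        for i in range(len(rows)):
            a, b = raw_calls[i][2 * j], raw_calls[i][2 * j + 1]
            try:
                calls[i, j] = (table[a], table[b])
            except KeyError:
                raise ParseError(f"marker {marker.name}: unknown allele") from None
        alleles = tuple(symbols) if len(symbols) == 2 else (
            (symbols[0], "?") if symbols else ("1", "2")
        )
        norm_markers.append(replace(marker, alleles=alleles))

    pedigrees = [Pedigree(fid, members) for fid, members in inds.items()]
    genotypes = GenotypeMatrix(markers=norm_markers, samples=rows, calls=calls)
    return pedigrees, genotypes


def write_ped_map(
    pedigrees: Sequence[Pedigree],
    genotypes: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Inverse of :func:`read_ped_map` (internal 1/2/0 allele codes)."""
    with open(map_path, "w") as fh:
        for m in genotypes.markers:
            fh.write(f"{m.chromosome} {m.name} {m.cm:.10g} {m.bp} {m.freq:.10g}\n")
    sex_code = {Sex.UNKNOWN: 0, Sex.MALE: 1, Sex.FEMALE: 2}
    phe_code = {Phenotype.UNKNOWN: 0, Phenotype.UNAFFECTED: 1, Phenotype.AFFECTED: 2}
    with open(ped_path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.members:
                row = genotypes.row(ped.family_id, ind.individual_id)
                cols = [
                    ped.family_id,
                    ind.individual_id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    str(sex_code[ind.sex]),
                    str(phe_code[ind.phenotype]),
                ]
                cols.extend(str(int(a)) for a in genotypes.calls[row].ravel())
                fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Mendelian checking


def _compatible(child: tuple[int, int], father: tuple[int, int], mother: tuple[int, int]) -> bool:
    c1, c2 = child
    if c1 == MISSING:
        return True
    fa = set(father) - {MISSING}
    mo = set(mother) - {MISSING}
    if not fa and not mo:
        return True
    if fa and mo:
        return any(
            (p in fa and q in mo) for p, q in ((c1, c2), (c2, c1))
        )
    typed = fa or mo
    # one parent typed: the child must be able to receive one allele from it
    return c1 in typed or c2 in typed


def mendelian_check(
    pedigree: Pedigree, genotypes: GenotypeMatrix
) -> list[tuple[str, str]]:
    """All (child id, marker name) pairs with an impossible transmission.

    Missing calls never trigger violations; with a single typed parent the
    child must still be able to receive one allele from it.
    """
    violations: list[tuple[str, str]] = []
    fid = pedigree.family_id
    absent = (MISSING, MISSING)
    for ind in pedigree.nonfounders():
        if not genotypes.has_sample(fid, ind.individual_id):
            continue
        crow = genotypes.row(fid, ind.individual_id)
        frow = (
            genotypes.row(fid, ind.father_id)
            if genotypes.has_sample(fid, ind.father_id)
            else None
        )
        mrow = (
            genotypes.row(fid, ind.mother_id)
            if genotypes.has_sample(fid, ind.mother_id)
            else None
        )
        for j, marker in enumerate(genotypes.markers):
            child = tuple(genotypes.calls[crow, j])
            father = tuple(genotypes.calls[frow, j]) if frow is not None else absent
            mother = tuple(genotypes.calls[mrow, j]) if mrow is not None else absent
            if not _compatible(child, father, mother):
                violations.append((ind.individual_id, marker.name))
    return violations


def set_violations_missing(
    genotypes: GenotypeMatrix,
    violations: Iterable[tuple[str, str]],
    pedigrees: Sequence[Pedigree],
) -> GenotypeMatrix:
    """Zero out the whole trio (child + both parents) at each violating marker.

    Returns a new matrix; the input is left unchanged.  A violation naming a
    marker absent from the matrix is a contract breach and raises KeyError.
    """
    out = genotypes.copy()
    by_family = {p.family_id: p for p in pedigrees}
    by_iid = {
        (p.family_id, ind.individual_id): ind
        for p in pedigrees
        for ind in p.members
    }
    for iid, marker_name in violations:
        col = out.col(marker_name)
        hits = [key for key in by_iid if key[1] == iid]
        if not hits:
            raise KeyError(f"individual {iid!r} not found in any pedigree")
        for fid, _ in hits:
            child = by_iid[(fid, iid)]
            if child.is_founder:
                continue
            for member in (iid, child.father_id, child.mother_id):
                if out.has_sample(fid, member):
                    out.calls[out.row(fid, member), col] = MISSING
    del by_family
    return out
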