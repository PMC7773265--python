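"""Multipoint LOD curves against a naive full-enumeration HMM oracle.

The oracle works on the full 2^b inheritance-vector space with explicit
dense transition matrices, emissions summed over all founder-allele
assignments, and phenotype likelihoods summed over all founder
disease-allele assignments -- no founder-phase reduction, no pruning.
"""

import itertools
import math

import numpy as np
import pytest

from pedlink.disease_model import DiseaseModel
from pedlink._lander_green import CapacityError, InheritanceEngine
from pedlink.linkage import (
    AlignmentError,
    LodCurve,
    additive_lod,
    haldane_theta,
    multipoint_lod,
    thin_markers,
    twopoint_lod,
)
from pedlink.pedio import MISSING, Marker, Pedigree, Phenotype

from conftest import make_individual, make_markers, make_matrix

# ---------------------------------------------------------------------------
# oracle


class NaiveHMM:
    def __init__(self, pedigree):
        self.ped = pedigree
        self.members = pedigree.members  # fixtures are in topological order
        self.founders = [m.individual_id for m in self.members if m.is_founder]
        self.nonfounders = [m.individual_id for m in self.members if not m.is_founder]
        self.b = 2 * len(self.nonfounders)
        self.fno = {f: k for k, f in enumerate(self.founders)}

    def slots(self, v):
        """(paternal slot, maternal slot) per member for vector v."""
        bits = [(v >> i) & 1 for i in range(self.b)]
        out = {}
        for m in self.members:
            iid = m.individual_id
            if m.is_founder:
                out[iid] = (2 * self.fno[iid], 2 * self.fno[iid] + 1)
            else:
                k = self.nonfounders.index(iid)
                bp, bm = bits[2 * k], bits[2 * k + 1]
                out[iid] = (out[m.father_id][bp], out[m.mother_id][bm])
        return out

    def emission(self, v, genotypes, freq):
        slots = self.slots(v)
        total = 0.0
        for alleles in itertools.product((1, 2), repeat=2 * len(self.founders)):
            p = 1.0
            for a in alleles:
                p *= freq if a == 1 else 1 - freq
            ok = True
            for m in self.members:
                g = genotypes.get(m.individual_id, (MISSING, MISSING))
                if g[0] == MISSING:
                    continue
                sp, sm = slots[m.individual_id]
                if tuple(sorted((alleles[sp], alleles[sm]))) != tuple(sorted(g)):
                    ok = False
                    break
            if ok:
                total += p
        return total

    def phenotype_R(self, v, model):
        slots = self.slots(v)
        total = 0.0
        for d in itertools.product((0, 1), repeat=2 * len(self.founders)):
            p = 1.0
            for b in d:
                p *= model.q if b else 1 - model.q
            for m in self.members:
                if m.phenotype is Phenotype.UNKNOWN:
                    continue
                sp, sm = slots[m.individual_id]
                f = model.penetrances[d[sp] + d[sm]]
                p *= f if m.phenotype is Phenotype.AFFECTED else 1 - f
            total += p
        return total

    def transition_matrix(self, theta):
        n = 1 << self.b
        M = np.empty((n, n))
        for u in range(n):
            for w in range(n):
                diff = bin(u ^ w).count("1")
                M[u, w] = (theta ** diff) * ((1 - theta) ** (self.b - diff))
        return M

    def lod_curve(self, genotype_matrix, model, grid):
        markers = genotype_matrix.markers
        fid = self.ped.family_id
        rows = genotype_matrix.family_rows(fid)
        genos = []
        for j in range(len(markers)):
            genos.append(
                {
                    iid: tuple(int(x) for x in genotype_matrix.calls[r, j])
                    for iid, r in rows.items()
                }
            )
        n = 1 << self.b
        E = [
            np.array([self.emission(v, genos[j], markers[j].freq) for v in range(n)])
            for j in range(len(markers))
        ]
        R = np.array([self.phenotype_R(v, model) for v in range(n)])
        pos = np.array([m.cm for m in markers])

        fwd = [E[0] / n]
        for j in range(1, len(markers)):
            M = self.transition_matrix(haldane_theta(pos[j] - pos[j - 1]))
            fwd.append((fwd[-1] @ M) * E[j])
        bwd = [None] * len(markers)
        bwd[-1] = np.ones(n)
        for j in range(len(markers) - 2, -1, -1):
            M = self.transition_matrix(haldane_theta(pos[j + 1] - pos[j]))
            bwd[j] = M @ (E[j + 1] * bwd[j + 1])

        lods = []
        for x in grid:
            hit = np.nonzero(np.abs(pos - x) < 1e-9)[0]
            if hit.size:
                post = fwd[hit[0]] * bwd[hit[0]]
            elif x < pos[0]:
                post = self.transition_matrix(haldane_theta(pos[0] - x)) @ (
                    E[0] * bwd[0]
                ) / n
            elif x > pos[-1]:
                post = fwd[-1] @ self.transition_matrix(haldane_theta(x - pos[-1]))
            else:
                j = int(np.searchsorted(pos, x))
                left = fwd[j - 1] @ self.transition_matrix(haldane_theta(x - pos[j - 1]))
                right = self.transition_matrix(haldane_theta(pos[j] - x)) @ (
                    E[j] * bwd[j]
                )
                post = left * right
            post = post / post.sum()
            lods.append(math.log10(float(post @ R) / R.mean()))
        return np.array(lods)


# ---------------------------------------------------------------------------


def attach_genotypes(ped, markers, calls):
    return make_matrix([ped], markers, calls)


@pytest.fixture
def threegen8_data(threegen8):
    markers = make_markers(3, spacing_cm=5.0, freq=0.4)
    calls = {
        "gf": [(1, 2), (1, 1), (1, 2)],
        "gm": [(2, 2), (1, 2), (2, 2)],
        "c1": [(1, 2), (1, 1), (1, 2)],
        "c2": [(2, 2), (1, 2), (2, 2)],
        "c3": [(1, 2), (1, 2), (1, 2)],
        "s1": [(1, 1), (2, 2), (1, 2)],
        "g1": [(1, 1), (1, 2), (1, 2)],
        "g2": [(1, 2), (1, 2), (2, 2)],
    }
    return threegen8, attach_genotypes(threegen8, markers, calls)


class TestOracleEquivalence:
    def test_ten_bit_pedigree_three_markers(self, threegen8_data):
        """Engine vs exhaustive enumeration over all 2^10 vectors, on and
        off marker positions."""
        ped, geno = threegen8_data
        model = DiseaseModel(q=0.05, f0=0.0, f1=0.8, f2=0.8)
        grid = np.array([-2.0, 0.0, 2.5, 5.0, 7.1, 10.0, 14.0])
        got = multipoint_lod(ped, geno, model, grid)
        want = NaiveHMM(ped).lod_curve(geno, model, grid)
        np.testing.assert_allclose(got.lod, want, rtol=1e-9, atol=1e-12)

    def test_missing_data_and_phenocopies(self, threegen8):
        markers = make_markers(2, spacing_cm=10.0, freq=0.3)
        calls = {
            "gf": [(1, 2), (0, 0)],
            "gm": [(0, 0), (1, 2)],
            "c1": [(1, 1), (1, 2)],
            "c2": [(1, 2), (2, 2)],
            "c3": [(0, 0), (0, 0)],
            "s1": [(2, 2), (1, 1)],
            "g1": [(1, 2), (1, 2)],
            "g2": [(1, 2), (1, 1)],
        }
        geno = attach_genotypes(threegen8, markers, calls)
        model = DiseaseModel(q=0.1, f0=0.05, f1=0.7, f2=0.95)
        grid = np.array([0.0, 4.0, 10.0])
        got = multipoint_lod(threegen8, geno, model, grid)
        want = NaiveHMM(threegen8).lod_curve(geno, model, grid)
        np.testing.assert_allclose(got.lod, want, rtol=1e-9, atol=1e-12)

    def test_founder_reduction_matches_full_space(self, threegen8_data):
        ped, geno = threegen8_data
        model = DiseaseModel(q=0.02, f0=0.0, f1=0.8, f2=0.8)
        grid = np.linspace(-1.0, 12.0, 9)
        a = multipoint_lod(ped, geno, model, grid, founder_reduction=True)
        b = multipoint_lod(ped, geno, model, grid, founder_reduction=False)
        np.testing.assert_allclose(a.lod, b.lod, rtol=1e-10, atol=1e-12)

    def test_single_marker_equals_twopoint_at_theta_zero(self, nuclear5):
        markers = make_markers(1, freq=0.3)
        calls = {
            "fa": [(1, 2)],
            "mo": [(2, 2)],
            "k1": [(1, 2)],
            "k2": [(2, 2)],
            "k3": [(1, 2)],
        }
        geno = attach_genotypes(nuclear5, markers, calls)
        model = DiseaseModel(q=0.05, f0=0.0, f1=0.8, f2=0.8)
        mp = multipoint_lod(nuclear5, geno, model, np.array([markers[0].cm]))
        gmap = {iid: calls[iid][0] for iid in calls}
        tp = twopoint_lod(nuclear5, gmap, model, 0.0, marker_freq=0.3)
        assert mp.lod[0] == pytest.approx(tp, rel=1e-9, abs=1e-12)

    def test_far_position_limit_is_zero(self, nuclear5):
        markers = make_markers(1, freq=0.3)
        calls = {
            "fa": [(1, 2)],
            "mo": [(2, 2)],
            "k1": [(1, 2)],
            "k2": [(2, 2)],
            "k3": [(1, 2)],
        }
        geno = attach_genotypes(nuclear5, markers, calls)
        model = DiseaseModel(q=0.05, f0=0.0, f1=0.8, f2=0.8)
        mp = multipoint_lod(nuclear5, geno, model, np.array([400.0, 1500.0]))
        assert abs(mp.lod[0]) < 1e-3  # theta within 3e-4 of 1/2
        assert mp.lod[1] == pytest.approx(0.0, abs=1e-9)


class TestEngineContracts:
    def test_bit_cap_names_pedigree(self, threegen8):
        with pytest.raises(CapacityError, match="F1"):
            InheritanceEngine(threegen8, bit_cap=8)

    def test_empty_grid_rejected(self, threegen8_data):
        ped, geno = threegen8_data
        with pytest.raises(ValueError, match="grid"):
            multipoint_lod(ped, geno, DiseaseModel(q=0.02), np.array([]))

    def test_disconnected_pedigrees_add(self):
        """Joint analysis of two disconnected families equals the sum of
        their separate curves."""
        fam_a = [
            make_individual("a_fa", sex="M", pheno="A"),
            make_individual("a_mo", sex="F", pheno="U"),
            make_individual("a_k1", father="a_fa", mother="a_mo", pheno="A"),
            make_individual("a_k2", father="a_fa", mother="a_mo", pheno="U"),
        ]
        fam_b = [
            make_individual("b_fa", sex="M", pheno="A"),
            make_individual("b_mo", sex="F", pheno="U"),
            make_individual("b_k1", father="b_fa", mother="b_mo", pheno="A"),
        ]
        markers = make_markers(2, spacing_cm=8.0, freq=0.4)
        calls = {
            "a_fa": [(1, 2), (1, 2)],
            "a_mo": [(2, 2), (1, 1)],
            "a_k1": [(1, 2), (1, 2)],
            "a_k2": [(2, 2), (1, 1)],
            "b_fa": [(1, 2), (1, 1)],
            "b_mo": [(1, 1), (1, 2)],
            "b_k1": [(1, 1), (1, 2)],
        }
        model = DiseaseModel(q=0.05, f0=0.0, f1=0.8, f2=0.8)
        grid = np.array([0.0, 3.0, 8.0])
        joint = Pedigree("F1", fam_a + fam_b)
        gj = make_matrix([joint], markers, calls)
        joint_curve = multipoint_lod(joint, gj, model, grid)
        pa = Pedigree("F1", fam_a)
        pb = Pedigree("F1", fam_b)
        ca = multipoint_lod(pa, make_matrix([pa], markers, calls), model, grid)
        cb = multipoint_lod(pb, make_matrix([pb], markers, calls), model, grid)
        np.testing.assert_allclose(joint_curve.lod, ca.lod + cb.lod, rtol=1e-9)


class TestAdditive:
    def grid_curve(self, lods, fam):
        return LodCurve("1", np.arange(len(lods), dtype=float), np.array(lods), fam)

    def test_pointwise_sum(self):
        c = additive_lod(
            [
                self.grid_curve([1.2, 0.0], "F1"),
                self.grid_curve([1.1, 0.5], "F2"),
                self.grid_curve([1.15, -0.2], "F3"),
            ]
        )
        assert c.family_id == "combined"
        np.testing.assert_allclose(c.lod, [3.45, 0.3])

    def test_single_curve_identity(self):
        c1 = self.grid_curve([0.5, -0.5], "F1")
        out = additive_lod([c1])
        np.testing.assert_array_equal(out.lod, c1.lod)

    def test_grid_mismatch_raises(self):
        a = self.grid_curve([0.1, 0.2], "F1")
        b = LodCurve("1", np.array([0.0, 1.5]), np.array([0.1, 0.2]), "F2")
        with pytest.raises(AlignmentError):
            additive_lod([a, b])


class TestThinMarkers:
    def test_spacing_arithmetic(self):
        markers = [
            Marker(f"r{i}", "1", 1000 + i, i * 0.1, freq=0.5) for i in range(10)
        ]
        selected, sets = thin_markers(markers, 0.2, 50)
        assert len(selected) == 5

    def test_maf_preference(self):
        markers = [
            Marker("lo", "1", 1000, 0.00, freq=0.1),
            Marker("hi", "1", 2000, 0.05, freq=0.4),
        ]
        selected, _ = thin_markers(markers, 0.2, 50)
        assert [m.name for m in selected] == ["hi"]

    def test_230_markers_in_5_sets_of_50(self):
        markers = [
            Marker(f"r{i}", "1", 1000 + i, i * 0.2, freq=0.5) for i in range(230)
        ]
        selected, sets = thin_markers(markers, 0.2, 50)
        assert len(selected) == 230
        assert len(sets) == 5
        assert all(len(s) <= 50 for s in sets)
        # adjacent sets overlap by exactly one marker
        for a, b in zip(sets, sets[1:]):
            assert a[-1].name == b[0].name
        # coverage without gaps
        names = [m.name for s in sets for m in s]
        assert set(names) == {m.name for m in selected}

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            thin_markers([], 0.2, 50)
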