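import numpy as np
import pytest
from Bio.Align import substitution_matrices

from gcfkit.families import (
    GcfCriteriaParams,
    align_identity,
    assign_gcfs,
    categorize_gcfs,
    category_table,
    criteria_report,
)
from gcfkit.model import BgcRecord, DomainCount, GeneRecord, HitRecord, ValidationError

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_oracle(a, b, gap_open=-11.0, gap_extend=-1.0):
    """Plain affine-gap Smith-Waterman scored with BLOSUM62; returns
    (identity, coverage of the shorter sequence) from a traceback.
    Independent of the Biopython implementation under test."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    ptr = {}
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, M[i-1, j-1] + s, X[i-1, j-1] + s, Y[i-1, j-1] + s)
            X[i, j] = max(M[i-1, j] + gap_open, X[i-1, j] + gap_extend)
            Y[i, j] = max(M[i, j-1] + gap_open, Y[i, j-1] + gap_extend)
            if M[i, j] > best:
                best, best_pos = M[i, j], (i, j)
    if best <= 0:
        return 0.0, 0.0
    # traceback through the M/X/Y lattice
    i, j = best_pos
    state = "M"
    cols = ident = 0
    i0, i1 = i, i
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] == 0:
                break
            s = BLOSUM62[a[i - 1], b[j - 1]]
            prev = M[i, j] - s
            cols += 1
            ident += a[i - 1] == b[j - 1]
            i0 = i - 1
            if abs(prev - M[i-1, j-1]) < 1e-9:
                state = "M"
            elif abs(prev - X[i-1, j-1]) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            cols += 1
            i0 = i - 1
            state = "M" if abs(X[i, j] - (M[i-1, j] - 11)) < 1e-9 else "X"
            i -= 1
        else:
            cols += 1
            state = "M" if abs(Y[i, j] - (M[i, j-1] - 11)) < 1e-9 else "Y"
            j -= 1
    span_short = (i1 - i0) if n <= m else cols  # crude; only used on gapless cases
    return ident / cols, span_short / min(n, m)


class TestAlignIdentity:
    def test_identical_sequences(self):
        assert align_identity("MKTAYIAKQR", "MKTAYIAKQR") == (1.0, 1.0)

    def test_one_mismatch_4mer_matches_dp_oracle(self):
        got = align_identity("MKLV", "MKIV")
        expected = sw_oracle("MKLV", "MKIV")
        assert got == pytest.approx(expected)
        assert got == pytest.approx((0.75, 1.0))

    def test_no_positive_scoring_pair(self):
        # poly-A vs poly-D scores negatively everywhere in BLOSUM62
        ident, cov = align_identity("AAAAAAAA", "DDDDDDDD")
        assert (ident, cov) == (0.0, 0.0)
        assert cov < GcfCriteriaParams().gene_coverage_min

    def test_symmetric(self):
        a, b = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIE", "MKTAYIGKQRQISFVKHHFSRQLEERLG"
        assert align_identity(a, b) == align_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            align_identity("", "MK")


def _mk_bgc(bgc_id, genome, cls, genes, start=0):
    """genes: list of (role, protein, module_domains)."""
    recs = []
    pos = start
    for i, (role, protein, mods) in enumerate(genes):
        recs.append(GeneRecord(
            gene_id=f"{bgc_id}_g{i}", start=pos, end=pos + 300, role=role,
            protein=protein, module_domains=mods,
        ))
        pos += 400
    return BgcRecord(
        bgc_id=bgc_id, genome_id=genome, bgc_class=cls, start=start, end=pos,
        genes=recs, domains=[DomainCount("PF00001", 1)],
    )


P1 = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
P2 = "MSNKEQEIFALIDELKSKNIRVTPQRHAILSYLVNSMAHPTADDIYKALEGKFPNMSVATVYNNLR"
P3 = "MAHHHHHHVGTGSNITSLYKKAGSENLYFQGHMASMTGGQQMGRGSEFELRRQACGRTRAPPPPPL"


class TestCriteriaReport:
    def test_identical_clusters_pass_all(self):
        a = _mk_bgc("a", "g1", "NRPS", [("c1", P1, (("C", 1),)), ("c2", P2, ())])
        b = _mk_bgc("b", "g2", "NRPS", [("c1", P1, (("C", 1),)), ("c2", P2, ())])
        rep = criteria_report(a, b)
        assert rep.architecture and rep.function and rep.identity and rep.modules
        assert rep.same_gcf

    def test_majority_identity_two_of_three(self):
        """Per-gene best-hit identities {1.0, 1.0, ~0} at full coverage:
        criterion III holds because 2/3 > 1/2."""
        a = _mk_bgc("a", "g1", "RiPP",
                    [("r1", P1, ()), ("r2", P2, ()), ("r3", P3, ())])
        b = _mk_bgc("b", "g2", "RiPP",
                    [("r1", P1, ()), ("r2", P2, ()), ("r3", P1[::-1], ())])
        rep = criteria_report(a, b)
        assert rep.identity is True

    def test_disjoint_roles_and_class_fail(self):
        a = _mk_bgc("a", "g1", "PKS", [("r1", P1, ()), ("r2", P2, ())])
        b = _mk_bgc("b", "g2", "RiPP", [("r3", P1, ()), ("r4", P2, ())])
        rep = criteria_report(a, b)
        assert rep.architecture is False and rep.function is False
        assert not rep.same_gcf

    def test_gene_order_irrelevant_for_function(self):
        a = _mk_bgc("a", "g1", "RiPP", [("r1", P1, ()), ("r2", P2, ())])
        b = _mk_bgc("b", "g2", "RiPP", [("r2", P2, ()), ("r1", P1, ())])
        assert criteria_report(a, b).same_gcf

    def test_modular_without_module_annotation_warns_not_vetoes(self):
        a = _mk_bgc("a", "g1", "PKS", [("r1", P1, ()), ("r2", P2, ())])
        b = _mk_bgc("b", "g2", "PKS", [("r1", P1, ()), ("r2", P2, ())])
        rep = criteria_report(a, b)
        assert rep.modules is None
        assert rep.warnings
        assert rep.same_gcf  # IV not applicable does not veto

    def test_hit_table_replaces_alignment(self):
        a = _mk_bgc("a", "g1", "RiPP", [("r1", None, ()), ("r2", None, ())])
        b = _mk_bgc("b", "g2", "RiPP", [("r1", None, ()), ("r2", None, ())])
        hits = [
            HitRecord("a_g0", "b_g0", 0.9, 0.95),
            HitRecord("a_g1", "b_g1", 0.85, 0.9),
        ]
        assert criteria_report(a, b, hits=hits).same_gcf
        weak = [HitRecord("a_g0", "b_g0", 0.3, 0.95)]
        assert not criteria_report(a, b, hits=weak).same_gcf

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for trial in range(10):
            def mk(bid, gid, n):
                genes = []
                for i in range(n):
                    prot = "".join(rng.choice(aas, size=40))
                    genes.append((f"r{rng.integers(4)}", prot, ()))
                return _mk_bgc(bid, gid, "RiPP", genes)
            a, b = mk("a", "g1", int(rng.integers(2, 5))), mk("b", "g2", int(rng.integers(2, 5)))
            ra, rb = criteria_report(a, b), criteria_report(b, a)
            assert (ra.architecture, ra.function, ra.identity, ra.same_gcf) == (
                rb.architecture, rb.function, rb.identity, rb.same_gcf)


class TestAssignAndCategorize:
    def test_transitive_closure_single_family(self):
        """A~B and B~C but A and C share too little: single linkage still
        joins all three."""
        a = _mk_bgc("a", "g1", "RiPP", [("r1", P1, ()), ("r2", P2, ()), ("r3", P3, ())])
        b = _mk_bgc("b", "g2", "RiPP", [("r1", P1, ()), ("r2", P2, ()), ("r4", P3, ())])
        c = _mk_bgc("c", "g3", "RiPP", [("r1", P1, ()), ("r4", P3, ()), ("r5", P2, ())])
        part = assign_gcfs([a, b, c])
        assert part.family_of == {"a": "a", "b": "a", "c": "a"}

    def test_unrelated_bgcs_stay_separate(self):
        a = _mk_bgc("a", "g1", "RiPP", [("r1", P1, ()), ("r2", P2, ())])
        b = _mk_bgc("b", "g2", "Terpene", [("r3", P3, ()), ("r4", P1, ())])
        part = assign_gcfs([a, b])
        assert len(part.members) == 2

    def test_input_order_does_not_change_partition(self):
        bgcs = []
        for gid in ("g1", "g2", "g3"):
            bgcs.append(_mk_bgc(f"x_{gid}", gid, "RiPP",
                                [("r1", P1, ()), ("r2", P2, ())]))
            bgcs.append(_mk_bgc(f"y_{gid}", gid, "Terpene",
                                [("r5", P3, ()), ("r6", P3[::-1], ())]))
        p1 = assign_gcfs(bgcs)
        p2 = assign_gcfs(bgcs[::-1])
        assert p1.family_of == p2.family_of
        assert p1.category == p2.category

    @pytest.mark.parametrize("strains,expected", [
        (5, "common"),   # four or more strains
        (4, "common"),
        (3, "rare"),     # 2-3 strains
        (2, "rare"),
        (1, "unique"),   # a single strain
    ])
    def test_category_boundaries(self, strains, expected):
        from gcfkit.families import GcfPartition

        part = GcfPartition(
            family_of={}, members={"f": ["b"]},
            strains={"f": {f"s{i}" for i in range(strains)}},
            consensus_class={"f": "PKS"},
        )
        assert categorize_gcfs(part).category["f"] == expected

    def test_two_copies_in_one_strain_still_unique(self):
        a = _mk_bgc("a1", "g1", "RiPP", [("r1", P1, ()), ("r2", P2, ())])
        b = _mk_bgc("a2", "g1", "RiPP", [("r1", P1, ()), ("r2", P2, ())])
        part = assign_gcfs([a, b])
        assert len(part.members) == 1
        assert list(part.category.values()) == ["unique"]
        assert category_table(part) == {"unique": 1}
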