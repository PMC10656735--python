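import io
import math

import numpy as np
import pytest
from skbio import TreeNode

from oracles import oracle_best_topology, tree_cherry_topology
from mdmscan.placement import (
    MaskedMSA, ReferenceMSA, add_fragment, distance_matrix, jukes_cantor,
    mask_columns, nearest_lineage, nj_tree, place_fragments, read_newick,
    write_newick,
)
from mdmscan.seqio import Lineage, SequenceRecord


class TestMaskColumns:
    def test_gap_fraction_boundary(self):
        msa = ReferenceMSA({
            "a": "A-A-", "b": "A-A-", "c": "A-AA", "d": "AAAA",
        })
        # col1: 3/4 gaps (0.75) -> dropped; col3: 2/4 (0.5) -> kept
        masked = mask_columns(msa, 0.70)
        assert masked.keep_mask.tolist() == [True, False, True, True]

    def test_gapless_alignment_keeps_everything(self):
        msa = ReferenceMSA({"a": "ACGT", "b": "ACGT"})
        assert mask_columns(msa).keep_mask.all()

    def test_masking_is_idempotent(self):
        msa = ReferenceMSA({"a": "A--T", "b": "AC-T", "c": "ACGT", "d": "AC--"})
        m1 = mask_columns(msa)
        projected = ReferenceMSA({k: v for k, v in m1.masked_rows().items()})
        m2 = mask_columns(projected)
        assert m2.keep_mask.all()


class TestAddFragment:
    def _db(self, msa):
        from mdmscan.pairwise import ReferenceDB
        recs = [SequenceRecord(k, v.replace("-", "")) for k, v in msa.rows.items()]
        lins = {r.id: Lineage.from_string("Bacteria") for r in recs}
        return ReferenceDB(records=recs, lineages=lins)

    def test_reference_subsequence_projects_onto_reference_columns(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 120))
        msa = ReferenceMSA({"r1": seq, "r2": seq[:60] + "-" * 60})
        masked = mask_columns(msa, 0.70)
        frag = SequenceRecord("f", seq[20:100])
        row = add_fragment(masked, frag, self._db(msa))
        ref_row = masked.masked_rows()["r1"]
        for col, c in enumerate(row):
            if c != "-":
                assert c == ref_row[col]
        assert row.replace("-", "") == seq[20:100]

    def test_fragment_insertion_is_discarded(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 100))
        msa = ReferenceMSA({"r1": seq})
        masked = mask_columns(msa)
        frag = SequenceRecord("f", seq[:50] + "TTTTTTTT" + seq[50:])
        row = add_fragment(masked, frag, self._db(msa))
        assert len(row) == 100
        assert row == seq  # insertion projected away

    def test_fragment_without_any_hit_is_skipped(self):
        msa = ReferenceMSA({"r1": "ACGT" * 30})
        masked = mask_columns(msa)
        frag = SequenceRecord("f", "ANT" * 40)
        assert add_fragment(masked, frag, self._db(msa)) is None


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        ids, D, flagged = distance_matrix({"a": "ACGT" * 30, "b": "ACGT" * 30})
        assert D[0, 1] == 0.0 and not flagged

    def test_jukes_cantor_closed_form(self):
        # 1 difference in 100 shared columns
        row_a = "A" * 100
        row_b = "A" * 99 + "C"
        ids, D, _ = distance_matrix({"a": row_a, "b": row_b})
        assert D[0, 1] == pytest.approx(jukes_cantor(0.01), rel=1e-12)
        assert jukes_cantor(0.01) == pytest.approx(0.010067, abs=1e-6)

    def test_symmetric_with_zero_diagonal(self):
        rng = np.random.default_rng(11)
        rows = {f"t{i}": "".join(rng.choice(list("ACGT-"), 80)) for i in range(5)}
        ids, D, _ = distance_matrix(rows, min_shared_columns=10)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)

    def test_pairs_with_few_shared_columns_are_imputed_and_flagged(self):
        rows = {"a": "ACGT" * 25, "b": "ACGT" * 25,
                "c": "-" * 96 + "ACGT"}  # only 4 shared columns with a/b
        ids, D, flagged = distance_matrix(rows, min_shared_columns=50)
        assert ("a", "c") in flagged and ("b", "c") in flagged
        assert D[0, 2] > 0


class TestNeighborJoining:
    def test_three_taxa_solve_the_three_point_equations(self):
        ids = ["a", "b", "c"]
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(ids, D)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert tips["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert tips["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def _random_additive_5taxon(self, rng):
        """Path-distance matrix of a random 5-taxon binary tree."""
        taxa = [f"t{i}" for i in range(5)]
        order = rng.permutation(5)
        c1 = [taxa[order[0]], taxa[order[1]]]
        c2 = [taxa[order[2]], taxa[order[3]]]
        lone = taxa[order[4]]
        lens = {t: rng.uniform(0.05, 1.0) for t in taxa}
        int1, int2 = rng.uniform(0.05, 1.0, 2)

        def d(u, v):
            if {u, v} == set(c1) or {u, v} == set(c2):
                return lens[u] + lens[v]
            total = lens[u] + lens[v]
            if u in c1 or v in c1:
                total += int1
            if u in c2 or v in c2:
                total += int2
            return total

        D = np.zeros((5, 5))
        for i in range(5):
            for j in range(i + 1, 5):
                D[i, j] = D[j, i] = d(taxa[i], taxa[j])
        truth = frozenset({frozenset(c1), frozenset(c2)})
        return taxa, D, truth

    def test_additive_five_taxon_matrices_recover_topology(self):
        """NJ equals exhaustive least-squares topology search on tree metrics."""
        rng = np.random.default_rng(29)
        for _ in range(10):
            taxa, D, truth = self._random_additive_5taxon(rng)
            tree = nj_tree(taxa, D)
            got = tree_cherry_topology(tree, taxa)
            assert truth <= got or got <= truth or truth == got
            oracle_topo = oracle_best_topology(taxa, D)
            assert oracle_topo == truth

    def test_taxon_order_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(31)
        taxa, D, _ = self._random_additive_5taxon(rng)
        tree1 = nj_tree(taxa, D)
        perm = list(rng.permutation(5))
        taxa2 = [taxa[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        tree2 = nj_tree(taxa2, D2)
        assert tree1.compare_rfd(tree2) == 0.0

    def test_ultrametric_four_taxon_topology(self):
        # ((a,b),(c,d)) with clean ultrametric distances
        ids = ["a", "b", "c", "d"]
        D = np.array([
            [0.0, 0.2, 1.0, 1.0],
            [0.2, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 0.2],
            [1.0, 1.0, 0.2, 0.0],
        ])
        tree = nj_tree(ids, D)
        cherries = tree_cherry_topology(tree, ids)
        assert frozenset({"a", "b"}) in cherries
        assert frozenset({"c", "d"}) in cherries

    def test_newick_round_trip_preserves_lengths(self, tmp_path):
        rng = np.random.default_rng(37)
        taxa, D, _ = self._random_additive_5taxon(rng)
        tree = nj_tree(taxa, D)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert tree.compare_rfd(back) == 0.0
        d1 = tree.tip_tip_distances().data
        d2 = back.tip_tip_distances().data
        assert np.allclose(d1, d2, atol=1e-9)


class TestNearestLineage:
    def _tree(self, nwk):
        return TreeNode.read(io.StringIO(nwk), convert_underscores=False)

    def test_pendant_graft_reports_host_reference(self):
        tree = self._tree("((q:0.01,r1:0.02):0.5,(r2:0.1,r3:0.1):0.2);")
        lins = {f"r{i}": Lineage.from_string(f"Bacteria;P{i}") for i in (1, 2, 3)}
        call = nearest_lineage(tree, "q", lins)
        assert call.nearest_ref == "r1"
        assert call.nearest_lineage.ranks[1] == "P1"
        assert call.phylum_caveat  # runner-up r2/r3 is in another phylum

    def test_exact_tie_flags_ambiguous_and_picks_lexicographic(self):
        tree = self._tree("(q:0.1,rB:0.3,rA:0.3);")
        lins = {"rA": Lineage.from_string("Bacteria;PX"),
                "rB": Lineage.from_string("Bacteria;PX")}
        call = nearest_lineage(tree, "q", lins)
        assert call.ambiguous and call.nearest_ref == "rA"
        assert not call.phylum_caveat


class TestEndToEndPlacement:
    def test_planted_fragments_land_in_the_parent_phylum(self, synth_dir, synth_db,
                                                         synth_truth):
        """>=90% of sub-family-novelty plants place nearest their true phylum."""
        from mdmscan.seqio import read_fasta
        msa = ReferenceMSA.from_fasta(synth_dir / "refs_aln.fasta")
        reps = {r.id: r for r in read_fasta(synth_dir / "otus.fasta")}
        plants = synth_truth[
            synth_truth["kind"].isin(["novel", "novel_low_abundance"])
            & synth_truth["planted_rank"].isin(["GENUS", "FAMILY", "ORDER", "CLASS"])
        ]
        frags = [reps[o] for o in plants["otu_id"]]
        tree, calls = place_fragments(msa, frags, synth_db)
        by_id = {c.mdms_id: c for c in calls}
        ok = 0
        for row in plants.itertuples():
            call = by_id[row.otu_id]
            true_phylum = synth_db.lineages[row.parent].ranks[1]
            if (not call.skipped
                    and call.nearest_lineage.ranks[1] == true_phylum):
                ok += 1
        assert ok / len(plants) >= 0.9
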