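import itertools

import numpy as np
import pytest

from aflp_delimit import trees as T
from aflp_delimit.seq_characters import (
    Alignment,
    bootstrap_support,
    character_counts,
    fitch_length,
    read_alignment,
    search_mp_trees,
    simple_indel_coding,
)


def brute_small_parsimony(tree: T.UnrootedTree, masks: np.ndarray) -> int:
    """Independent oracle: enumerate all internal-node state assignments."""
    n = tree.n
    internals = [x for x in tree.adj if x >= n]
    edges = tree.edges()
    total = 0
    for col in range(masks.shape[1]):
        leaf_sets = {
            i: [s for s in range(4) if masks[i, col] >> s & 1] for i in range(n)
        }
        best = None
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            cost = 0
            for u, v in edges:
                su, sv = amap.get(u), amap.get(v)
                if su is None:
                    cost += 0 if sv in leaf_sets[u] else 1
                elif sv is None:
                    cost += 0 if su in leaf_sets[v] else 1
                else:
                    cost += su != sv
            best = cost if best is None else min(best, cost)
        total += best
    return total


class TestReadAlignment:
    def test_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">t1\nACGTACGTAC\n>t2\nACGTACGTAA\n>t3\nACG-ACGTAA\n")
        aln = read_alignment(p)
        assert aln.taxa == ["t1", "t2", "t3"]
        assert aln.length == 10

    def test_ragged_rows_name_taxon(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">t1\nACGTACGTAC\n>t2\nACGTACGTA\n")
        with pytest.raises(ValueError, match="t2"):
            read_alignment(p)

    def test_nexus_interleaved_equals_sequential(self, tmp_path):
        seq = {"t1": "ACGTACGT", "t2": "ACGAACGT", "t3": "ACGTACTT"}
        sequential = (
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=3 NCHAR=8;\n"
            "FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n"
            + "\n".join(f"{t} {s}" for t, s in seq.items())
            + "\n;\nEND;\n"
        )
        interleaved = (
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=3 NCHAR=8;\n"
            "FORMAT DATATYPE=DNA MISSING=? GAP=- INTERLEAVE;\nMATRIX\n"
            + "\n".join(f"{t} {s[:4]}" for t, s in seq.items())
            + "\n\n"
            + "\n".join(f"{t} {s[4:]}" for t, s in seq.items())
            + "\n;\nEND;\n"
        )
        (tmp_path / "s.nex").write_text(sequential)
        (tmp_path / "i.nex").write_text(interleaved)
        a = read_alignment(tmp_path / "s.nex", "nexus")
        b = read_alignment(tmp_path / "i.nex", "nexus")
        assert a.taxa == b.taxa
        assert a.rows == b.rows


class TestSimpleIndelCoding:
    def test_no_gaps_no_characters(self):
        cm = simple_indel_coding(Alignment(["a", "b"], ["ACGT", "ACGA"]))
        assert cm.n_indel == 0

    def test_shared_gap_scored_binary(self):
        aln = Alignment(
            ["A", "B", "C", "D"],
            ["ACGTACGT", "ACGTACGT", "AC---CGT", "AC---CGT"],
        )
        cm = simple_indel_coding(aln)
        assert cm.indel_spans == [(2, 5)]
        assert [r[0] for r in cm.indel] == ["0", "0", "1", "1"]

    def test_enclosing_gap_scored_missing(self):
        aln = Alignment(
            ["A", "B", "C", "D", "E"],
            ["ACGTACGTAC", "ACGTACGTAC", "AC---CGTAC", "AC---CGTAC", "A------TAC"],
        )
        cm = simple_indel_coding(aln)
        spans = dict(zip(cm.indel_spans, range(len(cm.indel_spans))))
        k = spans[(2, 5)]
        assert [cm.indel[i, k] for i in range(5)] == ["0", "0", "1", "1", "?"]

    def test_terminal_gaps_not_coded_but_mask_spans(self):
        aln = Alignment(
            ["A", "B", "C"],
            ["ACGTACGT", "AC--ACGT", "----ACGT"],
        )
        cm = simple_indel_coding(aln)
        assert cm.indel_spans == [(2, 4)]  # the leading run of C is terminal
        assert [cm.indel[i, 0] for i in range(3)] == ["0", "1", "?"]

    def test_one_character_per_distinct_signature_and_idempotence(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(6):
            row = list("ACGTACGTACGTACGT")
            if rng.random() < 0.8:
                s = int(rng.integers(1, 10))
                e = s + int(rng.integers(1, 4))
                row[s:e] = "-" * (e - s)
            rows.append("".join(row))
        aln = Alignment([f"t{i}" for i in range(6)], rows)
        cm = simple_indel_coding(aln)
        signatures = set()
        for row in rows:
            i = 0
            while i < len(row):
                if row[i] == "-":
                    j = i
                    while j < len(row) and row[j] == "-":
                        j += 1
                    if i > 0 and j < len(row):
                        signatures.add((i, j))
                    i = j
                else:
                    i += 1
        assert set(cm.indel_spans) == signatures
        # binary characters contain no gaps: re-coding adds nothing
        recoded = simple_indel_coding(
            Alignment(cm.taxa, ["".join(r) for r in cm.indel.astype(str)])
        )
        assert recoded.n_indel == 0


class TestCharacterCounts:
    def test_constant_and_singleton_columns(self):
        aln = Alignment(["a", "b", "c", "d"], ["AA", "AA", "AA", "AG"])
        cc = character_counts(simple_indel_coding(aln))
        assert (cc.n_constant, cc.n_variable, cc.n_parsimony_informative) == (1, 1, 0)

    def test_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(1)
        alphabet = list("ACGT-NRY")
        rows = ["".join(rng.choice(alphabet, 20)) for _ in range(6)]
        aln = Alignment([f"t{i}" for i in range(6)], rows)
        cm = simple_indel_coding(aln)
        cc = character_counts(cm, include_indels=False)
        # independent re-implementation of the definitions
        variable = informative = 0
        for j in range(20):
            col = [r[j] for r in aln.rows]
            tally = {}
            for ch in col:
                if ch in "ACGT":
                    tally[ch] = tally.get(ch, 0) + 1
            if len(tally) >= 2:
                variable += 1
                if sum(1 for v in tally.values() if v >= 2) >= 2:
                    informative += 1
        assert cc.n_variable == variable
        assert cc.n_parsimony_informative == informative
        assert cc.n_constant + cc.n_variable == 20

    def test_subset_monotonicity(self):
        rng = np.random.default_rng(2)
        rows = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
        aln = Alignment([f"t{i}" for i in range(6)], rows)
        cm = simple_indel_coding(aln)
        full = character_counts(cm)
        sub = character_counts(cm, taxa_subset=["t0", "t1", "t2", "t3"])
        assert full.n_variable >= sub.n_variable
        assert full.n_parsimony_informative >= sub.n_parsimony_informative

    def test_empty_subset_is_error(self):
        aln = Alignment(["a", "b"], ["AC", "AG"])
        with pytest.raises(ValueError, match="empty"):
            character_counts(simple_indel_coding(aln), taxa_subset=[])


class TestFitchLength:
    def test_constant_matrix_zero(self):
        aln = Alignment(["a", "b", "c", "d"], ["AAA"] * 4)
        assert fitch_length("((a,b),(c,d));", simple_indel_coding(aln)) == 0

    def test_textbook_single_column(self):
        aln = Alignment(["A1", "A2", "G1", "G2"], ["A", "A", "G", "G"])
        cm = simple_indel_coding(aln)
        assert fitch_length("((A1,A2),(G1,G2));", cm) == 1
        assert fitch_length("((A1,G1),(A2,G2));", cm) == 2

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n)]
            topos = list(T.enumerate_topologies(taxa))
            tree = topos[rng.integers(0, len(topos))]
            masks = (1 << rng.integers(0, 4, size=(n, 8))).astype(np.uint8)
            assert T.tree_length(tree, masks) == brute_small_parsimony(tree, masks)

    def test_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(6)]
        aln = Alignment([f"t{i}" for i in range(6)], rows)
        cm = simple_indel_coding(aln)
        nwk = "((t0,t1),(t2,t3),(t4,t5));"
        base = fitch_length(nwk, cm)
        mapping = {f"t{i}": f"x{i}" for i in range(6)}
        aln2 = Alignment([mapping[t] for t in aln.taxa], rows)
        cm2 = simple_indel_coding(aln2)
        nwk2 = "((x0,x1),(x2,x3),(x4,x5));"
        assert fitch_length(nwk2, cm2) == base

    def test_taxon_mismatch_is_error(self):
        aln = Alignment(["a", "b", "c", "d"], ["A", "A", "G", "G"])
        with pytest.raises(ValueError):
            fitch_length("((a,b),(c,x));", simple_indel_coding(aln))


class TestSearch:
    def test_single_informative_column_pairs_the_states(self):
        aln = Alignment(["a1", "a2", "g1", "g2"], ["A", "A", "G", "G"])
        ts = search_mp_trees(simple_indel_coding(aln), strategy="exact")
        assert ts.length == 1
        assert frozenset(["g1", "g2"]) in ts.binary_trees[0].splits()

    def test_uninformative_matrix_gives_star_consensus(self):
        aln = Alignment(["a", "b", "c", "d"], ["AAAA", "AAAA", "AAAA", "AAAT"])
        ts = search_mp_trees(simple_indel_coding(aln), strategy="exact")
        assert ts.n_trees == 3  # all quartet topologies tie
        assert ts.strict_consensus.splits() == set()

    def test_heuristic_never_beats_exact(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_runs = 20
        for run in range(n_runs):
            n = 7
            taxa = [f"t{i}" for i in range(n)]
            rows = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(n)]
            cm = simple_indel_coding(Alignment(taxa, rows))
            exact = search_mp_trees(cm, strategy="exact")
            heur = search_mp_trees(cm, strategy="heuristic", seed=run, n_starts=10)
            assert heur.length >= exact.length
            hits += heur.length == exact.length
        assert hits >= 0.95 * n_runs

    def test_exact_refuses_large_taxon_sets(self):
        taxa = [f"t{i}" for i in range(16)]
        aln = Alignment(taxa, ["A" * 4] * 16)
        with pytest.raises(ValueError, match="heuristic"):
            search_mp_trees(simple_indel_coding(aln), strategy="exact")

    def test_zero_length_branches_collapsed_in_reported_trees(self):
        # only one informative split: reported trees must show exactly it
        aln = Alignment(
            ["a1", "a2", "g1", "g2", "x"],
            ["AAC", "AAC", "GAC", "GAC", "GAC"],
        )
        ts = search_mp_trees(simple_indel_coding(aln), strategy="exact")
        for t in ts.trees:
            assert t.splits() == {frozenset(["g1", "g2", "x"])}


class TestBootstrap:
    def test_decisive_columns_give_full_support(self):
        aln = Alignment(["a1", "a2", "g1", "g2"], ["A" * 50, "A" * 50, "G" * 50, "G" * 50])
        bs = bootstrap_support(simple_indel_coding(aln), replicates=50, seed=1)
        assert bs[frozenset(["g1", "g2"])] == 100.0

    def test_uninformative_matrix_low_support(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT", "AGTC", "GTAC", "TACG"])
        bs = bootstrap_support(simple_indel_coding(aln), replicates=60, seed=2)
        assert all(v < 80.0 for v in bs.values())

    def test_reproducible_under_seed(self):
        aln = Alignment(
            ["a1", "a2", "g1", "g2", "h"],
            ["ACGTA", "ACGTA", "GCGTT", "GCGTT", "GCATT"],
        )
        cm = simple_indel_coding(aln)
        assert bootstrap_support(cm, 30, seed=3) == bootstrap_support(cm, 30, seed=3)

    def test_rejects_no_replicates(self):
        aln = Alignment(["a", "b", "c", "d"], ["AC", "AC", "GC", "GC"])
        with pytest.raises(ValueError):
            bootstrap_support(simple_indel_coding(aln), replicates=0)


def test_character_matrix_nexus_export(tmp_path):
    aln = Alignment(["a", "b", "c"], ["AC-T", "ACGT", "AC-T"])
    cm = simple_indel_coding(aln)
    cm.to_nexus(tmp_path / "m.nex")
    text = (tmp_path / "m.nex").read_text()
    assert "DATATYPE=DNA" in text
    assert 'SYMBOLS="01"' in text
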