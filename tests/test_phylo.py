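import io

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM, TreeNode
from skbio.tree import nj as skbio_nj

from helpers import (
    best_alignment_score,
    induced_pairwise_score,
    p_distance_oracle,
    tree_path_lengths,
)

from gliascan.cluster import ProteinCluster
from gliascan.phylo import (
    Alignment,
    DistanceMatrix,
    align_center_star,
    bipartitions,
    bootstrap_support,
    consensus,
    neighbor_joining,
    p_distance,
    p_distance_matrix,
    top_clusters,
    write_newick,
)


# --- top_clusters ------------------------------------------------------------


def _cl(size, rep):
    return ProteinCluster(representative=rep, size=size, genotype="g")


def test_top_clusters_takes_largest():
    clusters = [_cl(100, "MKA"), _cl(50, "MKB"), _cl(20, "MKC")]
    assert [c.size for c in top_clusters(clusters, k=2)] == [100, 50]


def test_top_clusters_tie_breaks_lexicographically():
    clusters = [_cl(10, "MKZ"), _cl(10, "MKA"), _cl(20, "MKB")]
    top = top_clusters(clusters, k=2)
    assert [c.representative for c in top] == ["MKB", "MKA"]


def test_top_clusters_fewer_than_k_returns_all():
    clusters = [_cl(5, "MKA")]
    assert top_clusters(clusters, k=10) == clusters
    with pytest.raises(ValueError):
        top_clusters([], k=3)


# --- center-star alignment ----------------------------------------------------


def test_identical_sequences_align_without_gaps():
    aln = align_center_star(["MKQPF"] * 4)
    assert set(aln.rows) == {"MKQPF"}


def test_two_sequences_equal_pairwise_score():
    a, b = "MKQPFL", "MKPFL"
    aln = align_center_star([a, b])
    assert induced_pairwise_score(aln.rows[0], aln.rows[1]) == best_alignment_score(a, b)


def test_center_star_matches_small_case_oracle():
    seqs = ["MKQPF", "MKPF", "MKQPFA"]
    aln = align_center_star(seqs)
    # oracle: center maximises summed optimal pairwise score
    sums = [
        sum(best_alignment_score(seqs[i], seqs[j]) for j in range(3) if j != i)
        for i in range(3)
    ]
    center = int(np.argmax(sums))
    # every row aligned against the center achieves the optimal pairwise score
    for j in range(3):
        if j == center:
            continue
        assert induced_pairwise_score(aln.rows[center], aln.rows[j]) == best_alignment_score(
            seqs[center], seqs[j]
        )
    # no all-gap column, rows reproduce their sequences
    assert all(set(col) != {"-"} for col in zip(*aln.rows))
    for row, seq in zip(aln.rows, seqs):
        assert row.replace("-", "") == seq


def test_single_sequence_alignment():
    aln = align_center_star(["MKQ"])
    assert aln.rows == ("MKQ",)


# --- consensus ----------------------------------------------------------------


def test_consensus_of_identical_rows():
    aln = Alignment(names=("a", "b"), rows=("MKQPF", "MKQPF"))
    assert consensus(aln) == "MKQPF"


def test_consensus_plurality_and_ties():
    aln = Alignment(names=("a", "b", "c"), rows=("A", "A", "C"))
    assert consensus(aln) == "A"
    tie = Alignment(names=("a", "b"), rows=("A", "C"))
    assert consensus(tie) == "A"  # lexicographic tie-break


def test_consensus_drops_majority_gap_columns_and_marks_low_plurality():
    aln = Alignment(
        names=("a", "b", "c", "d"),
        rows=("A-KL", "A-KF", "A-KY", "AQKV"),
    )
    # col 2 is gap in 3/4 rows -> dropped; col 4 has 4 distinct residues -> X
    assert consensus(aln) == "AKX"


# --- p-distance ---------------------------------------------------------------


def test_p_distance_examples():
    assert p_distance("PFPQPQLPY", "PFPQPQLPY") == 0.0
    assert p_distance("PFPQPQLPY", "PYPQPQLPY") == pytest.approx(1 / 9)


def test_p_distance_pairwise_deletion_matches_site_oracle():
    rng = np.random.default_rng(17)
    alphabet = list("MKQPFLY-X")
    for _ in range(100):
        n = int(rng.integers(4, 30))
        a = "".join(rng.choice(alphabet, size=n))
        b = "".join(rng.choice(alphabet, size=n))
        comparable = [
            (x, y) for x, y in zip(a, b) if x not in "-X" and y not in "-X"
        ]
        if not comparable:
            with pytest.raises(ValueError):
                p_distance(a, b)
        else:
            d = p_distance(a, b)
            assert d == pytest.approx(p_distance_oracle(a, b))
            assert 0 <= d <= 1
            assert p_distance(b, a) == d


# --- neighbor joining -----------------------------------------------------------


def test_nj_two_taxa_single_edge():
    dm = DistanceMatrix(("A", "B"), np.array([[0, 0.4], [0.4, 0]]))
    tree = neighbor_joining(dm)
    paths = tree_path_lengths(tree)
    assert paths[frozenset(("A", "B"))] == pytest.approx(0.4)
    assert write_newick(tree) in ("(A:0.2,B:0.2);", "(B:0.2,A:0.2);")


def test_nj_three_taxa_closed_form():
    d = {"AB": 0.3, "AC": 0.5, "BC": 0.6}
    dm = DistanceMatrix(
        ("A", "B", "C"),
        np.array([[0, d["AB"], d["AC"]], [d["AB"], 0, d["BC"]], [d["AC"], 0.6, 0]]),
    )
    tree = neighbor_joining(dm)
    paths = tree_path_lengths(tree)
    for pair, key in ((("A", "B"), "AB"), (("A", "C"), "AC"), (("B", "C"), "BC")):
        assert paths[frozenset(pair)] == pytest.approx(d[key])


def _additive_matrix(tree_newick, names):
    t = TreeNode.read(io.StringIO(tree_newick))
    n = len(names)
    d = np.zeros((n, n))
    tips = {tip.name: tip for tip in t.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tips[names[i]].distance(tips[names[j]])
    return d


@pytest.mark.parametrize(
    "newick,names,split",
    [
        ("((A:2,B:3):1,C:4,D:5);", ("A", "B", "C", "D"), {"C", "D"}),
        (
            "((A:1,B:2):1,(C:3,(D:1,E:2):1):2,F:4);",
            ("A", "B", "C", "D", "E", "F"),
            {"D", "E"},
        ),
    ],
)
def test_nj_recovers_additive_trees_exactly(newick, names, split):
    d = _additive_matrix(newick, names)
    tree = neighbor_joining(DistanceMatrix(names, d))
    paths = tree_path_lengths(tree)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            assert paths[frozenset((a, b))] == pytest.approx(d[names.index(a), names.index(b)])
    assert frozenset(split) in bipartitions(tree) or frozenset(
        set(names) - split
    ) in bipartitions(tree)


def test_nj_topology_agrees_with_skbio_oracle():
    rng = np.random.default_rng(23)
    names = tuple("ABCDEF")
    newick = "((A:1.5,B:0.7):0.9,(C:2.0,D:0.4):0.3,(E:1.1,F:0.8):0.6);"
    d = _additive_matrix(newick, names)
    ours = neighbor_joining(DistanceMatrix(names, d))
    theirs = skbio_nj(SkbioDM(d, ids=names))
    assert bipartitions(ours) == bipartitions(theirs)


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        DistanceMatrix(("A", "B"), np.array([[0, 1.0], [0.5, 0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(("A", "B"), np.array([[0, -0.1], [-0.1, 0]]))
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(("A",), np.zeros((1, 1))))


# --- bootstrap -----------------------------------------------------------------


def _two_pair_alignment(n_cols=60):
    a = "A" * n_cols
    b = "A" * (n_cols - 2) + "CC"
    c = "T" * n_cols
    d = "T" * (n_cols - 2) + "GG"
    return Alignment(names=("A", "B", "C", "D"), rows=(a, b, c, d))


def test_bootstrap_supports_clear_split():
    aln = _two_pair_alignment()
    tree, supports = bootstrap_support(aln, n_reps=200, seed=5)
    central = frozenset({"C", "D"})
    assert supports[central] >= 95
    assert all(0 <= s <= 100 for s in supports.values())


def test_bootstrap_deterministic_under_seed():
    aln = _two_pair_alignment()
    _, s1 = bootstrap_support(aln, n_reps=100, seed=9)
    _, s2 = bootstrap_support(aln, n_reps=100, seed=9)
    assert s1 == s2


def test_bootstrap_identical_sequences_star_like():
    aln = Alignment(names=("A", "B", "C"), rows=("MKQ", "MKQ", "MKQ"))
    tree, supports = bootstrap_support(aln, n_reps=20, seed=1)
    assert supports == {} or all(v == 0 for v in supports.values())


# --- newick --------------------------------------------------------------------


def test_newick_round_trip_with_quoted_names():
    names = ("Ae. juvenalis 'AE 537'", "Ae. tauschii 'AE 1600'", "plain")
    d = np.array([[0, 0.2, 0.5], [0.2, 0, 0.4], [0.5, 0.4, 0]])
    tree = neighbor_joining(DistanceMatrix(names, d))
    s = write_newick(tree)
    back = TreeNode.read(io.StringIO(s))
    assert {t.name for t in back.tips()} == set(names)
    paths = tree_path_lengths(back)
    assert paths[frozenset(names[:2])] == pytest.approx(0.2)
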