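"""Alignment preprocessing, NJ bootstrap trees and suppression dating."""

import numpy as np
import pytest

from neosexpipe.alignment import GametologAlignment
from neosexpipe.synthetic_data import (
    added_species_tree, ancestral_species_tree,
)
from neosexpipe.timing import (
    INCONCLUSIVE, INTERVAL, RESOLVED,
    Branch, DatedSpeciesTree, GeneTree, build_tree_nj,
    filter_alignments_for_timing, infer_suppression_added,
    infer_suppression_ancestral, mask_gene_conversion, remove_masked_columns,
    trim_alignment,
)


def aln_from(records, gene_id="g"):
    return GametologAlignment.from_sequences(gene_id, records)


# ---------------------------------------------------------------------------
# trimming and length filter
# ---------------------------------------------------------------------------

def test_trim_removes_ambiguous_and_gap_columns():
    aln = aln_from([("a|Z", "ACGT"), ("b|Z", "ACNT")])
    out = trim_alignment(aln)
    assert out.n_cols == 3
    assert out.sequence("b|Z") == "ACT"


def test_trim_is_identity_on_clean_alignment():
    aln = aln_from([("a|Z", "ACGT"), ("b|Z", "ACGT")])
    assert np.array_equal(trim_alignment(aln).matrix, aln.matrix)


def test_trim_can_empty_an_alignment():
    aln = aln_from([("a|Z", "----"), ("b|Z", "ACGT")])
    assert trim_alignment(aln).n_cols == 0


@pytest.mark.parametrize("lengths, kept", [([699], 0), ([700], 1),
                                           ([500, 700, 1200], 2), ([], 0)])
def test_short_alignment_filter(lengths, kept):
    alns = [aln_from([("a|Z", "A" * n), ("b|Z", "A" * n)], gene_id=f"g{n}")
            for n in lengths]
    assert len(filter_alignments_for_timing(alns)) == kept


# ---------------------------------------------------------------------------
# gene-conversion screen
# ---------------------------------------------------------------------------

def _pair_alignment(z_seq, w_seq):
    return aln_from([("sp|Z", z_seq), ("sp|W", w_seq), ("out|OUT", z_seq)])


def test_uniform_divergence_yields_no_tracts():
    rng = np.random.default_rng(0)
    z = rng.choice(list("ACGT"), 1000)
    w = z.copy()
    w[::10] = np.where(w[::10] == "A", "C", "A")  # evenly spaced mismatches
    mask = mask_gene_conversion(_pair_alignment("".join(z), "".join(w)),
                                n_perm=2000, seed=1)
    assert mask.tracts == []


def test_long_identical_leading_tract_is_flagged():
    rng = np.random.default_rng(1)
    z = rng.choice(list("ACGT"), 1000)
    w = z.copy()
    tail = np.arange(300, 1000)
    hit = tail[rng.random(tail.size) < 0.10]
    w[hit] = np.where(w[hit] == "A", "C", "A")
    mask = mask_gene_conversion(_pair_alignment("".join(z), "".join(w)),
                                n_perm=2000, seed=2)
    assert mask.tracts, "leading identical tract should be significant"
    start, end = mask.merged_intervals()[0]
    assert start == 0 and end >= 300
    trimmed = remove_masked_columns(_pair_alignment("".join(z), "".join(w)),
                                    mask)
    assert trimmed.n_cols < 1000


def test_identical_rows_give_empty_mask():
    mask = mask_gene_conversion(_pair_alignment("ACGT" * 100, "ACGT" * 100),
                                n_perm=500, seed=3)
    assert mask.tracts == []


# ---------------------------------------------------------------------------
# NJ + bootstrap
# ---------------------------------------------------------------------------

def _quartet(rng, length=2000):
    """Two cherries (a,b) and (c,d) with additive JC expectations."""
    from neosexpipe.synthetic_data import _evolve

    root = rng.integers(0, 4, size=length)
    left = _evolve(root, 10, 0.002, rng)
    right = _evolve(root, 10, 0.002, rng)
    NUC = np.array(list("ACGT"))
    seqs = {
        "a|Z": _evolve(left, 3, 0.002, rng),
        "b|Z": _evolve(left, 3, 0.002, rng),
        "c|Z": _evolve(right, 3, 0.002, rng),
        "d|OUT": _evolve(right, 3, 0.002, rng),
    }
    return aln_from([(k, "".join(NUC[v])) for k, v in seqs.items()])


def test_nj_recovers_generating_quartet():
    aln = _quartet(np.random.default_rng(4))
    tree = build_tree_nj(aln, n_bootstrap=50, seed=5)
    assert frozenset({"a|Z", "b|Z"}) in tree.clades()


def test_identical_sequences_pair_at_full_support():
    seq = "ACGT" * 300
    rng = np.random.default_rng(6)
    NUC = np.array(list("ACGT"))
    other = "".join(NUC[rng.integers(0, 4, 1200)])
    far = "".join(NUC[rng.integers(0, 4, 1200)])
    aln = aln_from([("a|Z", seq), ("b|Z", seq), ("c|Z", other),
                    ("d|OUT", far)])
    tree = build_tree_nj(aln, n_bootstrap=40, seed=7)
    assert tree.supports[frozenset({"a|Z", "b|Z"})] == 100.0


def test_bootstrap_supports_deterministic_for_seed():
    aln = _quartet(np.random.default_rng(8))
    t1 = build_tree_nj(aln, n_bootstrap=30, seed=9)
    t2 = build_tree_nj(aln, n_bootstrap=30, seed=9)
    assert t1.supports == t2.supports
    assert t1.newick == t2.newick


def test_nj_requires_four_rows():
    aln = aln_from([("a|Z", "ACGT"), ("b|OUT", "ACGT")])
    with pytest.raises(ValueError):
        build_tree_nj(aln)


def test_gene_tree_newick_round_trip():
    aln = _quartet(np.random.default_rng(10))
    tree = build_tree_nj(aln, n_bootstrap=20, seed=11)
    parsed = GeneTree.from_newick(tree.newick, gene_id="g")
    assert parsed.leaves == tree.leaves
    assert set(parsed.supports) == set(tree.supports)
    for clade, sup in tree.supports.items():
        assert parsed.supports[clade] == pytest.approx(sup)


# ---------------------------------------------------------------------------
# dated species tree
# ---------------------------------------------------------------------------

def test_focal_path_branches_of_default_tree():
    dated = added_species_tree()
    ids = [b.branch_id for b in dated.focal_path_branches()]
    assert ids == ["24-21", "21-17", "17-7", "7-5", "5-3", "3-0"]
    assert dated.split_age("panurus") == 21.0
    assert dated.split_age("locustella") == 17.0
    assert dated.crown_age(["great_reed_warbler", "iduna_opaca"]) == 7.0


def test_branch_invariants():
    with pytest.raises(ValueError):
        Branch("bad", 5.0, 7.0)
    with pytest.raises(ValueError):
        DatedSpeciesTree.from_newick("(a:1,b:1);", focal="zz")


# ---------------------------------------------------------------------------
# suppression inference (added region)
# ---------------------------------------------------------------------------

W4 = ["great_reed_warbler", "clamorous_reed_warbler", "marsh_warbler",
      "iduna_opaca"]


def synthetic_tree(supported, gene_id="g"):
    """GeneTree with the given supported clades (support 95) over the
    default six Sylvioidea species + outgroup."""
    species = W4 + ["locustella", "panurus"]
    leaves = frozenset([f"{s}|Z" for s in species]
                       + [f"{s}|W" for s in species] + ["great_tit|OUT"])
    supports = {frozenset(c): 95.0 for c in supported}
    return GeneTree(gene_id, leaves, supports)


def _w(names):
    return [f"{n}|W" for n in names]


def test_added_panurus_pair_and_young_w_clade_bracket_21_to_7():
    tree = synthetic_tree([
        {"panurus|Z", "panurus|W"},
        set(_w(W4)),
    ])
    call = infer_suppression_added(tree, added_species_tree())
    assert call.status == INTERVAL
    assert [b.branch_id for b in call.branches] == ["21-17", "17-7"]


def test_added_locustella_w_in_clade_narrows_to_21_17():
    tree = synthetic_tree([
        {"panurus|Z", "panurus|W"},
        set(_w(W4 + ["locustella"])),
    ])
    call = infer_suppression_added(tree, added_species_tree())
    assert call.status == RESOLVED
    assert call.branches[0].branch_id == "21-17"


def test_added_locustella_pair_instead_narrows_to_17_7():
    tree = synthetic_tree([
        {"panurus|Z", "panurus|W"},
        {"locustella|Z", "locustella|W"},
        set(_w(W4)),
    ])
    call = infer_suppression_added(tree, added_species_tree())
    assert call.status == RESOLVED
    assert call.branches[0].branch_id == "17-7"


def test_added_no_support_keeps_every_branch():
    tree = synthetic_tree([])
    call = infer_suppression_added(tree, added_species_tree())
    assert call.status == INTERVAL
    assert [b.branch_id for b in call.branches] == \
        ["24-21", "21-17", "17-7", "7-5", "5-3", "3-0"]


def test_added_conflicting_constraints_are_reported_not_dropped():
    # suppression both before 17 (W clade incl. locustella) and after 7
    # (iduna pair): empty candidate set
    tree = synthetic_tree([
        set(_w(W4 + ["locustella"])),
        {"iduna_opaca|Z", "iduna_opaca|W"},
    ])
    call = infer_suppression_added(tree, added_species_tree())
    assert call.status == INCONCLUSIVE
    assert call.branches == []
    assert "conflict" in call.notes


def test_added_constraints_only_shrink_candidates():
    base = synthetic_tree([{"panurus|Z", "panurus|W"}])
    more = synthetic_tree([{"panurus|Z", "panurus|W"}, set(_w(W4))])
    dated = added_species_tree()
    b1 = {b.branch_id for b in infer_suppression_added(base, dated).branches}
    b2 = {b.branch_id for b in infer_suppression_added(more, dated).branches}
    assert b2 <= b1


def test_added_candidates_form_contiguous_path():
    tree = synthetic_tree([{"panurus|Z", "panurus|W"}, set(_w(W4))])
    call = infer_suppression_added(tree, added_species_tree())
    ordered = sorted(call.branches, key=lambda b: b.child_age)
    for younger, older in zip(ordered, ordered[1:]):
        assert younger.parent_age == older.child_age


def test_added_low_support_ignored():
    tree = synthetic_tree([])
    tree.supports[frozenset({"panurus|Z", "panurus|W"})] = 60.0
    call = infer_suppression_added(tree, added_species_tree(), tau=70)
    assert len(call.branches) == 6  # below tau: treated as absent


def test_added_missing_focal_w_is_an_error():
    leaves = frozenset({"panurus|Z", "panurus|W", "great_tit|OUT",
                        "great_reed_warbler|Z"})
    tree = GeneTree("g", leaves, {})
    with pytest.raises(ValueError, match="focal W"):
        infer_suppression_added(tree, added_species_tree())


# ---------------------------------------------------------------------------
# suppression inference (ancestral region)
# ---------------------------------------------------------------------------

SYLV = ["great_reed_warbler", "clamorous_reed_warbler", "marsh_warbler",
        "iduna_opaca", "locustella", "panurus"]
BACKBONE_Z = ["great_tit", "zebra_finch", "manakin", "budgerigar", "chicken",
              "emu"]


def ancestral_tree(supported, clades_unsupported=()):
    leaves = frozenset([f"{s}|Z" for s in SYLV + BACKBONE_Z]
                       + [f"{s}|W" for s in SYLV] + ["anole|OUT"])
    supports = {frozenset(c): 95.0 for c in supported}
    for c in clades_unsupported:
        supports[frozenset(c)] = 40.0
    return GeneTree("g", leaves, supports)


def _z(names):
    return [f"{n}|Z" for n in names]


def test_ancestral_supported_flanks_resolve_single_branch():
    # W clade attaches between the passerine Z clade (crown 41 Ma) and
    # the budgerigar split (60 Ma)
    w_clade = set(_w(SYLV))
    passerines = set(_z(SYLV + ["great_tit", "zebra_finch", "manakin"]))
    tree = ancestral_tree([w_clade, passerines, w_clade | passerines])
    call = infer_suppression_ancestral(tree, ancestral_species_tree())
    assert call.status == RESOLVED
    assert call.branches[0].branch_id == "60-41"


def test_ancestral_unsupported_flanks_widen_interval():
    w_clade = set(_w(SYLV))
    passerines = set(_z(SYLV + ["great_tit", "zebra_finch", "manakin"]))
    tree = ancestral_tree([w_clade], clades_unsupported=[
        passerines, w_clade | passerines])
    call = infer_suppression_ancestral(tree, ancestral_species_tree())
    assert call.status == INTERVAL
    iv = call.age_interval
    assert iv[0] == 21.0  # crown of the W species set
    assert iv[1] == 280.0  # no supported node above: up to the root


def test_ancestral_paraphyletic_w_is_inconclusive():
    # a supported clade mixing W leaves with a Z leaf, and no W clade
    mixed = set(_w(SYLV[:3])) | {"great_tit|Z"}
    tree = ancestral_tree([mixed])
    call = infer_suppression_ancestral(tree, ancestral_species_tree())
    assert call.status == INCONCLUSIVE
    assert "monophyletic" in call.notes


def test_ancestral_requires_w_leaves():
    leaves = frozenset(_z(SYLV) + ["anole|OUT"])
    tree = GeneTree("g", leaves, {})
    with pytest.raises(ValueError, match="W leaves"):
        infer_suppression_ancestral(tree, ancestral_species_tree())
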