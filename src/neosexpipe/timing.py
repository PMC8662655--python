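"""Dating recombination suppression from gene-tree topology.

Once Z-W recombination stops at a gene, the W copy starts its own
history: in a gene tree, W sequences of species that diverged *after*
suppression form a clade (their W lineages share the suppressed
ancestor), whereas a species that diverged while the gene still
recombined shows its Z and W copies as sisters (suppression happened
later, on its own branch).  Reading supported clades (bootstrap >=
tau, default 70) against a dated species phylogeny therefore brackets
the suppression time of each gene to a set of branches along the
focal lineage:

- a supported {species Z, species W} pair excludes branches older
  than that species' split from the focal lineage;
- a supported all-W clade containing the focal species excludes
  branches younger than the crown age of the clade's species set.

For the ancestral (old) sex-chromosome region, where all ingroup W
sequences form one clade attached deep in the backbone, the interval
is instead delimited by the closest supported nodes flanking the W
clade's attachment point.

The module also provides the alignment preprocessing used before tree
building: removal of columns with gaps/ambiguities, a permutation
screen for Z-to-W gene-conversion tracts (a simplified Sawyer-style
maximal-identical-run test; a conversion event pastes a long identical
tract onto an otherwise diverged pair), the <700 bp alignment length
filter, and a seeded neighbor-joining + bootstrap tree builder on
Jukes-Cantor distances (externally built trees with supports are
accepted as first-class input, making the ML step pluggable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .alignment import TAG_OUT, TAG_W, TAG_Z, GametologAlignment, parse_label

logger = logging.getLogger(__name__)

RESOLVED = "RESOLVED"
INTERVAL = "INTERVAL"
INCONCLUSIVE = "INCONCLUSIVE"


# ---------------------------------------------------------------------------
# dated species tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    """A branch of the focal lineage, delimited by node ages in Ma."""

    branch_id: str
    parent_age: float
    child_age: float

    def __post_init__(self) -> None:
        if not self.parent_age > self.child_age >= 0:
            raise ValueError("branch ages must satisfy parent > child >= 0")


class DatedSpeciesTree:
    """Ultrametric species tree with node ages (Ma), a focal species and,
    for the added region, the fusion age bounding the oldest possible
    suppression time."""

    def __init__(self, tree: dendropy.Tree, focal: str,
                 fusion_age: float | None = None) -> None:
        self.tree = tree
        self.focal = focal
        self.fusion_age = fusion_age
        self.tree.is_rooted = True
        self.tree.calc_node_ages(ultrametricity_precision=1e-3)
        labels = {t.label for t in tree.taxon_namespace}
        if focal not in labels:
            raise ValueError(f"focal species {focal!r} not in tree")
        if fusion_age is not None and fusion_age > self.root_age:
            raise ValueError("fusion age older than the root")

    @classmethod
    def from_newick(cls, newick: str, focal: str,
                    fusion_age: float | None = None) -> "DatedSpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 rooting="force-rooted")
        return cls(tree, focal, fusion_age)

    @property
    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    def species(self) -> list[str]:
        return [t.label for t in self.tree.taxon_namespace]

    def crown_age(self, species: Iterable[str]) -> float:
        labels = list(species)
        if len(labels) == 1:
            return 0.0
        mrca = self.tree.mrca(taxon_labels=labels)
        return float(mrca.age)

    def split_age(self, species: str) -> float:
        """Age at which ``species`` diverged from the focal lineage.
        For the focal species itself: its divergence from its sister."""
        if species == self.focal:
            leaf = self.tree.find_node_with_taxon_label(self.focal)
            return float(leaf.parent_node.age)
        return self.crown_age([species, self.focal])

    def focal_path_ages(self, max_age: float | None = None) -> list[float]:
        """Node ages along the focal lineage, ascending, clipped at
        ``max_age`` (fusion age if set, else root age)."""
        if max_age is None:
            max_age = self.fusion_age if self.fusion_age is not None else self.root_age
        leaf = self.tree.find_node_with_taxon_label(self.focal)
        ages = []
        node = leaf.parent_node
        while node is not None:
            ages.append(float(node.age))
            node = node.parent_node
        ages = sorted(a for a in ages if a < max_age)
        return [0.0] + ages + [float(max_age)]

    def focal_path_branches(self, max_age: float | None = None) -> list[Branch]:
        """Branches of the focal lineage from ``max_age`` to the present,
        ordered oldest first."""
        ages = self.focal_path_ages(max_age)
        branches = []
        for hi, lo in zip(ages[::-1], ages[-2::-1]):
            branches.append(Branch(f"{hi:g}-{lo:g}", hi, lo))
        return branches


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    """A gene-tree topology with bootstrap supports on its clades.

    Clades are stored as frozensets of leaf labels on the side of each
    bipartition away from the (first) outgroup leaf, i.e. rooted-by-
    outgroup semantics; ``supports`` maps each internal clade of the
    point estimate to a bootstrap percentage in [0, 100].
    """

    gene_id: str
    leaves: frozenset[str]
    supports: dict[frozenset[str], float]
    newick: str = ""

    def __post_init__(self) -> None:
        self.out_leaves = frozenset(
            n for n in self.leaves if parse_label(n)[1] == TAG_OUT)
        if not self.out_leaves:
            raise ValueError(f"{self.gene_id}: no outgroup leaf for rooting")

    def clades(self) -> set[frozenset[str]]:
        return set(self.supports)

    def supported_clades(self, tau: float) -> set[frozenset[str]]:
        return {c for c, s in self.supports.items() if s >= tau}

    def leaves_by_tag(self, tag: str) -> frozenset[str]:
        return frozenset(n for n in self.leaves if parse_label(n)[1] == tag)

    @classmethod
    def from_newick(cls, newick: str, gene_id: str = "") -> "GeneTree":
        """Parse an externally built tree whose internal node labels are
        bootstrap supports (RAxML-style)."""
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        leaves = frozenset(t.label for t in tree.taxon_namespace)
        ref = _reference_out_leaf(leaves, gene_id)
        supports: dict[frozenset[str], float] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in clade:
                clade = leaves - clade
            if len(clade) < 2:
                continue
            label = node.label
            support = float(label) if label not in (None, "") else 0.0
            supports[clade] = max(supports.get(clade, 0.0), support)
        return cls(gene_id, leaves, supports, newick)


def _reference_out_leaf(leaves: frozenset[str], gene_id: str = "") -> str:
    outs = sorted(n for n in leaves if parse_label(n)[1] == TAG_OUT)
    if not outs:
        raise ValueError(f"{gene_id}: no outgroup leaf for rooting")
    return outs[0]


# ---------------------------------------------------------------------------
# alignment preprocessing
# ---------------------------------------------------------------------------

def trim_alignment(aln: GametologAlignment) -> GametologAlignment:
    """Remove every column containing a character outside {A,C,G,T} in
    any row (gaps, Ns, ambiguity codes)."""
    clean = np.isin(aln.matrix, list("ACGT")).all(axis=0)
    return aln.subset_columns(clean)


def filter_alignments_for_timing(
    alns: Iterable[GametologAlignment], min_len: int = 700
) -> list[GametologAlignment]:
    """Drop trimmed alignments shorter than ``min_len`` columns."""
    return [a for a in alns if a.n_cols >= min_len]


@dataclass
class ConversionTract:
    start: int  # 0-based half-open alignment columns
    end: int
    score: int  # run length in columns
    p_value: float


@dataclass
class ConversionMask:
    gene_id: str
    tracts: list[ConversionTract] = field(default_factory=list)

    def merged_intervals(self) -> list[tuple[int, int]]:
        ivs = sorted((t.start, t.end) for t in self.tracts)
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]


def _max_run_null(n_cols: int, n_mismatch: int, n_perm: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the longest identical run when ``n_mismatch``
    mismatches are placed uniformly among ``n_cols`` columns."""
    null = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, 2_000_000 // max(1, n_cols)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        r = rng.random((m, n_cols))
        pos = np.sort(np.argpartition(r, n_mismatch - 1, axis=1)[:, :n_mismatch],
                      axis=1)
        bounded = np.hstack([np.full((m, 1), -1), pos, np.full((m, 1), n_cols)])
        gaps = np.diff(bounded, axis=1) - 1
        null[done:done + m] = gaps.max(axis=1)
        done += m
    return null


def mask_gene_conversion(
    aln: GametologAlignment,
    zw_pairs: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ConversionMask:
    """Permutation screen for Z-to-W gene-conversion tracts.

    For each within-species (Z row, W row) pair of a *trimmed*
    alignment, the maximal runs of identical columns are scored by
    length and referred to a null obtained by permuting the positions
    of the pair's mismatch columns (seeded, ``n_perm`` permutations).
    Runs with permutation p < ``alpha`` are reported as tracts; the
    caller removes the flagged columns before tree building.  This is
    a deliberately simplified Sawyer-style inner-fragment test, not a
    reimplementation of GENECONV.
    """
    if zw_pairs is None:
        zw_pairs = autodetect_zw_pairs(aln)
    rng = np.random.default_rng(seed)
    mask = ConversionMask(aln.gene_id)
    n_cols = aln.n_cols
    for z_name, w_name in zw_pairs:
        z = aln.matrix[aln.names.index(z_name)]
        w = aln.matrix[aln.names.index(w_name)]
        mismatch = np.flatnonzero(z != w)
        if mismatch.size == 0 or n_cols == 0:
            continue  # identical pair: nothing to test
        null = _max_run_null(n_cols, mismatch.size, n_perm, rng)
        bounded = np.r_[-1, mismatch, n_cols]
        starts = bounded[:-1] + 1
        ends = bounded[1:]
        for s, e in zip(starts, ends):
            run = e - s
            if run <= 0:
                continue
            p = float((null >= run).mean())
            if p < alpha:
                mask.tracts.append(ConversionTract(int(s), int(e), int(run), p))
    return mask


def autodetect_zw_pairs(aln: GametologAlignment) -> list[tuple[str, str]]:
    """(Z row, W row) pairs for every species carrying both copies."""
    by_species: dict[str, dict[str, str]] = {}
    for name in aln.names:
        species, tag = parse_label(name)
        by_species.setdefault(species, {})[tag] = name
    return [(tags[TAG_Z], tags[TAG_W]) for tags in by_species.values()
            if TAG_Z in tags and TAG_W in tags]


def remove_masked_columns(aln: GametologAlignment,
                          mask: ConversionMask) -> GametologAlignment:
    keep = np.ones(aln.n_cols, dtype=bool)
    for s, e in mask.merged_intervals():
        keep[s:e] = False
    return aln.subset_columns(keep)


# ---------------------------------------------------------------------------
# neighbor-joining + bootstrap tree builder
# ---------------------------------------------------------------------------

def _jc_distance_matrix(p: np.ndarray, cap: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        d = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.74999) / 3.0),
                     cap)
    if np.any(p >= 0.75):
        logger.warning("saturated distance(s) capped at %g", cap)
    np.fill_diagonal(d, 0.0)
    return d


def _nj_clades(dist: np.ndarray, names: list[str], ref: str,
               leaves: frozenset[str]) -> set[frozenset[str]]:
    tree = nj(DistanceMatrix(dist, ids=names))
    clades: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if ref in clade:
            clade = leaves - clade
        if 2 <= len(clade) < len(leaves):
            clades.add(clade)
    return clades


def build_tree_nj(aln: GametologAlignment, n_bootstrap: int = 100,
                  seed: int = 0, max_dist: float = 5.0) -> GeneTree:
    """Neighbor joining on Jukes-Cantor distances with bootstrap supports.

    Supports are the percentage of column-resampled replicates whose NJ
    tree contains each clade of the point-estimate tree (rooted on the
    outgroup).  Saturated distances (p >= 0.75) are capped at
    ``max_dist`` with a warning.  Deterministic for a given seed.
    """
    if aln.n_rows < 4:
        raise ValueError("need at least four sequences for NJ")
    leaves = frozenset(aln.names)
    ref = _reference_out_leaf(leaves, aln.gene_id)
    names = list(aln.names)

    codes = aln.matrix.view(np.uint32).reshape(aln.matrix.shape)
    diff = codes[:, None, :] != codes[None, :, :]  # (n, n, L)
    p_point = diff.mean(axis=2)
    point_clades = _nj_clades(_jc_distance_matrix(p_point, max_dist),
                              names, ref, leaves)

    rng = np.random.default_rng(seed)
    counts = {c: 0 for c in point_clades}
    length = aln.n_cols
    for _ in range(n_bootstrap):
        idx = rng.integers(0, length, size=length)
        p = diff[:, :, idx].mean(axis=2)
        rep = _nj_clades(_jc_distance_matrix(p, max_dist), names, ref, leaves)
        for c in point_clades & rep:
            counts[c] += 1
    supports = {c: 100.0 * counts[c] / n_bootstrap for c in point_clades}
    newick = _clades_to_newick(leaves, supports, ref)
    return GeneTree(aln.gene_id, leaves, supports, newick)


def _clades_to_newick(leaves: frozenset[str],
                      supports: dict[frozenset[str], float], ref: str) -> str:
    """Render the clade set (nested by construction) as a rooted newick
    string with supports as internal labels."""
    children = sorted(supports, key=len, reverse=True)

    def render(members: frozenset[str], nested: list[frozenset[str]]) -> str:
        direct = []
        used: set[str] = set()
        for c in nested:
            if c < members and not any(c < d for d in direct):
                direct.append(c)
        parts = []
        for c in direct:
            inner = [d for d in nested if d < c]
            parts.append(render(c, inner) + f"{supports[c]:g}")
            used |= set(c)
        for leaf in sorted(members - used):
            parts.append(leaf)
        return "(" + ",".join(parts) + ")"

    return render(leaves, children) + ";"


# ---------------------------------------------------------------------------
# suppression inference
# ---------------------------------------------------------------------------

@dataclass
class SuppressionCall:
    gene_id: str
    branches: list[Branch]
    status: str  # RESOLVED / INTERVAL / INCONCLUSIVE
    notes: str = ""

    @property
    def age_interval(self) -> tuple[float, float] | None:
        """(youngest, oldest) bound in Ma, None when inconclusive."""
        if not self.branches:
            return None
        return (min(b.child_age for b in self.branches),
                max(b.parent_age for b in self.branches))


def _status(branches: list[Branch]) -> str:
    if not branches:
        return INCONCLUSIVE
    return RESOLVED if len(branches) == 1 else INTERVAL


def infer_suppression_added(tree: GeneTree, dated: DatedSpeciesTree,
                            tau: float = 70.0) -> SuppressionCall:
    """Date suppression of an added-region gene from supported clades.

    Candidates start as every focal-lineage branch between the fusion
    age and the present.  A supported {Z, W} pair of species *s*
    removes branches older than *s*'s split (recombination continued
    past that split); a supported all-W clade containing the focal
    species removes branches younger than the clade's crown age on the
    dated tree (suppression predates the radiation).  Boundary
    branches are retained (closed-interval semantics).
    """
    focal = dated.focal
    focal_w = f"{focal}|{TAG_W}"
    if focal_w not in tree.leaves:
        raise ValueError(f"{tree.gene_id}: focal W leaf {focal_w!r} missing")
    candidates = dated.focal_path_branches()
    supported = tree.supported_clades(tau)
    notes = []

    species_in_tree = {parse_label(n)[0] for n in tree.leaves}
    for sp in sorted(species_in_tree):
        pair = frozenset({f"{sp}|{TAG_Z}", f"{sp}|{TAG_W}"})
        if pair <= tree.leaves and pair in supported:
            a = dated.split_age(sp)
            candidates = [b for b in candidates if b.child_age < a]
            notes.append(f"pair:{sp}@{a:g}")

    w_leaves = tree.leaves_by_tag(TAG_W)
    for clade in supported:
        if clade <= w_leaves and focal_w in clade and len(clade) >= 2:
            crown = dated.crown_age([parse_label(n)[0] for n in clade])
            candidates = [b for b in candidates if b.parent_age > crown]
            notes.append(f"wclade:n{len(clade)}@{crown:g}")

    status = _status(candidates)
    if status == INCONCLUSIVE:
        notes.append("conflicting constraints")
    return SuppressionCall(tree.gene_id, candidates, status, ";".join(notes))


def infer_suppression_ancestral(tree: GeneTree, dated: DatedSpeciesTree,
                                tau: float = 70.0) -> SuppressionCall:
    """Date suppression of an ancestral-region gene.

    The ingroup W sequences are expected to be monophyletic (reported
    as inconclusive if not); the candidate interval spans the backbone
    branches between the closest supported nodes flanking the W
    clade's attachment: supported all-Z clades containing the focal Z
    bound the time from below (suppression predates their crown),
    supported clades containing the whole W clade bound it from above
    (suppression postdates the split of the closest Z lineage outside).
    """
    focal = dated.focal
    focal_z = f"{focal}|{TAG_Z}"
    w_leaves = tree.leaves_by_tag(TAG_W)
    if not w_leaves:
        raise ValueError(f"{tree.gene_id}: no W leaves")
    supported = tree.supported_clades(tau)
    all_clades = tree.clades()

    if len(w_leaves) >= 2 and w_leaves not in all_clades:
        return SuppressionCall(tree.gene_id, [], INCONCLUSIVE,
                               "W leaves not monophyletic")

    w_species = [parse_label(n)[0] for n in w_leaves]
    lower = dated.crown_age(w_species)  # suppression predates the W radiation
    upper = dated.root_age
    notes = [f"wcrown@{lower:g}"]

    non_w_species = {parse_label(n)[0] for n in tree.leaves - w_leaves}
    for clade in supported:
        species = [parse_label(n)[0] for n in clade]
        if focal_z in clade and not clade & w_leaves:
            crown = dated.crown_age(species)
            if crown > lower:
                lower = crown
                notes.append(f"below@{crown:g}")
        elif w_leaves < clade and clade != tree.leaves:
            # a supported clade joining the W clade with its closest Z
            # relatives: suppression postdates the split of the nearest
            # Z lineage left outside
            outside = non_w_species - set(species)
            if outside:
                d = min(dated.split_age(sp) for sp in outside)
                if d < upper:
                    upper = d
                    notes.append(f"above@{d:g}")

    branches = [b for b in dated.focal_path_branches(max_age=dated.root_age)
                if b.parent_age > lower and b.child_age < upper]
    status = _status(branches)
    return SuppressionCall(tree.gene_id, branches, status, ";".join(notes))


def calls_to_rows(calls: Iterable[SuppressionCall]) -> list[dict]:
    rows = []
    for c in calls:
        iv = c.age_interval
        rows.append({
            "gene_id": c.gene_id,
            "status": c.status,
            "branches": ",".join(b.branch_id for b in c.branches),
            "age_min": iv[0] if iv else float("nan"),
            "age_max": iv[1] if iv else float("nan"),
            "notes": c.notes,
        })
    return rows
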