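"""Seeded generators for every pipeline input, with known truth.

The generators emulate the statistical structure of a songbird
neo-sex-chromosome dataset:

- gametolog alignments evolved under Jukes-Cantor along a dated,
  Sylvioidea-like species tree (focal-lineage splits at 21, 17, 7, 5
  and 3 Ma; a sex-chromosome/autosome fusion at 24 Ma; an outgroup at
  44 Ma; an avian backbone up to a reptile outgroup for the ancestral
  region), with Z-W recombination suppression at a chosen time: before
  suppression the Z and W histories of a gene are identical, after it
  the W detaches and accumulates divergence independently;
- optional Z-to-W gene-conversion tracts pasted post hoc;
- per-scaffold coverage/heterozygosity profiles per chromosome class
  (autosome, Z, W, PAR) for ZZ males and ZW females, with per-sample
  medians taken over negative-binomial per-site coverage;
- sex-stratified genotype tables projected from known Z/W haplotypes,
  and neutral-SFS variant tables for diversity runs where the expected
  per-site heterozygosity equals theta.

Every generator is a pure function of its config (bit-identical
reruns for a fixed seed) and returns truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import GametologAlignment
from .phasing import SampleGenotype, SiteGenotypes
from .popgen import GenotypeCall, VariantSite
from .sexlink import SampleObservation, ScaffoldProfile
from .timing import Branch, DatedSpeciesTree

NUC = np.array(list("ACGT"))

FOCAL = "great_reed_warbler"

#: Sylvioidea-like ingroup with a non-Sylvioidea outgroup; ages in Ma.
ADDED_TREE_NEWICK = (
    "((((((great_reed_warbler:3,clamorous_reed_warbler:3):2,"
    "marsh_warbler:5):2,iduna_opaca:7):10,locustella:17):4,"
    "panurus:21):23,great_tit:44);"
)
ADDED_FUSION_AGE = 24.0

#: The same ingroup on an avian backbone down to a reptile outgroup.
ANCESTRAL_TREE_NEWICK = (
    "((((((((((((great_reed_warbler:3,clamorous_reed_warbler:3):2,"
    "marsh_warbler:5):2,iduna_opaca:7):10,locustella:17):4,panurus:21):3,"
    "great_tit:24):9,zebra_finch:33):8,manakin:41):19,budgerigar:60):15,"
    "chicken:75):18,emu:93):187,anole:280);"
)

SYLVIOIDEA = ("great_reed_warbler", "clamorous_reed_warbler", "marsh_warbler",
              "iduna_opaca", "locustella", "panurus")


def added_species_tree() -> DatedSpeciesTree:
    return DatedSpeciesTree.from_newick(ADDED_TREE_NEWICK, FOCAL,
                                        fusion_age=ADDED_FUSION_AGE)


def ancestral_species_tree() -> DatedSpeciesTree:
    return DatedSpeciesTree.from_newick(ANCESTRAL_TREE_NEWICK, FOCAL)


# ---------------------------------------------------------------------------
# gametolog sequence evolution
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("age", "children", "label")

    def __init__(self, age: float, children: list | None = None,
                 label: str | None = None) -> None:
        self.age = age
        self.children = children or []
        self.label = label


def _species_subtree(node, subset: frozenset[str], tag_of: dict[str, str]) -> _SimNode | None:
    """Restrict a dendropy subtree to ``subset``, suppressing unifurcations."""
    if node.is_leaf():
        name = node.taxon.label
        if name not in subset:
            return None
        return _SimNode(0.0, label=f"{name}|{tag_of[name]}")
    kids = [k for k in (_species_subtree(c, subset, tag_of)
                        for c in node.child_nodes()) if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return _SimNode(float(node.age), kids)


def _insert_on_path(node: _SimNode, target_leaf: str, age: float,
                    graft: _SimNode) -> bool:
    """Insert a node at ``age`` on the edge of the path toward
    ``target_leaf`` and attach ``graft`` as its second child."""
    for i, child in enumerate(node.children):
        if target_leaf in _leaf_labels(child):
            if child.age < age < node.age:
                node.children[i] = _SimNode(age, [child, graft])
                return True
            return _insert_on_path(child, target_leaf, age, graft)
    return False


def _leaf_labels(node: _SimNode) -> set[str]:
    if node.label is not None:
        return {node.label}
    out: set[str] = set()
    for c in node.children:
        out |= _leaf_labels(c)
    return out


@dataclass
class GametologSimConfig:
    """Study conditions for the gametolog simulator.

    ``mu`` is the substitution rate per site per My; the Z-W
    divergence accrued since suppression at time t is then ~2 mu t.
    ``suppression_time`` (Ma) may be a scalar or one value per gene;
    it must not coincide with a node age of the species tree.
    """

    seed: int = 0
    region: str = "added"  # 'added' or 'ancestral'
    mu: float = 0.002
    gene_length: int = 3000
    n_genes: int = 100
    suppression_time: float | Sequence[float] = 12.0
    w_species: tuple[str, ...] = SYLVIOIDEA
    conversion_tract_bp: int | None = None  # paste focal Z onto focal W
    gene_prefix: str = "gene"


@dataclass
class SimulatedGene:
    alignment: GametologAlignment
    suppression_time: float
    true_branch: Branch
    conversion_tract: tuple[int, int] | None  # alignment columns, half-open


def _evolve(seq: np.ndarray, t: float, mu: float,
            rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor evolution for time t: each site changes with
    probability 3/4 (1 - exp(-4 mu t / 3)), uniformly to another base."""
    p = 0.75 * -math.expm1(-4.0 * mu * t / 3.0)
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _simulate_down(node: _SimNode, seq: np.ndarray, mu: float,
                   rng: np.random.Generator,
                   sink: dict[str, np.ndarray]) -> None:
    if node.label is not None:
        sink[node.label] = seq
        return
    for child in node.children:
        child_seq = _evolve(seq, node.age - child.age, mu, rng)
        _simulate_down(child, child_seq, mu, rng, sink)


def _build_gene_genealogy(dated: DatedSpeciesTree, w_species: Sequence[str],
                          t_s: float) -> _SimNode:
    """Species-tree Z genealogy with W lineages attached per the
    suppression model: species diverging after t_s share one W lineage
    detaching from the focal Z at t_s; species diverging before t_s
    suppressed independently on their own branch at the same time."""
    focal = dated.focal
    tag_of = {s: "W" for s in w_species}
    z_tags = {s: ("OUT" if _is_rooting_outgroup(s, dated) else "Z")
              for s in dated.species()}

    root = _species_subtree(dated.tree.seed_node, frozenset(dated.species()),
                            z_tags)
    shared = frozenset(s for s in w_species
                       if s == focal or dated.split_age(s) < t_s)
    w_sub = _species_subtree(dated.tree.seed_node, shared, tag_of)
    if not _insert_on_path(root, f"{focal}|Z", t_s, w_sub):
        raise ValueError(f"cannot place suppression time {t_s} on the focal path")
    for sp in w_species:
        if sp in shared:
            continue
        leaf = _SimNode(0.0, label=f"{sp}|W")
        if not _insert_on_path(root, f"{sp}|Z", t_s, leaf):
            raise ValueError(f"cannot place W of {sp} at {t_s}")
    return root


def _is_rooting_outgroup(species: str, dated: DatedSpeciesTree) -> bool:
    """The earliest-diverging species serves as the rooting outgroup."""
    return dated.split_age(species) == dated.root_age


def _branch_containing(dated: DatedSpeciesTree, t_s: float) -> Branch:
    for b in dated.focal_path_branches(max_age=dated.root_age):
        if b.child_age < t_s <= b.parent_age:
            return b
    raise ValueError(f"time {t_s} outside the focal path")


def simulate_gametologs(cfg: GametologSimConfig
                        ) -> tuple[list[SimulatedGene], DatedSpeciesTree]:
    """Simulate per-gene gametolog alignments with suppression truth."""
    dated = added_species_tree() if cfg.region == "added" else ancestral_species_tree()
    rng = np.random.default_rng(cfg.seed)
    times = (list(cfg.suppression_time)
             if isinstance(cfg.suppression_time, (list, tuple, np.ndarray))
             else [float(cfg.suppression_time)] * cfg.n_genes)
    if len(times) != cfg.n_genes:
        raise ValueError("need one suppression time per gene")

    genes: list[SimulatedGene] = []
    for g, t_s in enumerate(times):
        genealogy = _build_gene_genealogy(dated, cfg.w_species, t_s)
        root_seq = rng.integers(0, 4, size=cfg.gene_length)
        sink: dict[str, np.ndarray] = {}
        _simulate_down(genealogy, root_seq, cfg.mu, rng, sink)

        tract = None
        if cfg.conversion_tract_bp:
            tlen = min(cfg.conversion_tract_bp, cfg.gene_length)
            start = int(rng.integers(0, cfg.gene_length - tlen + 1))
            tract = (start, start + tlen)
            w_key = f"{dated.focal}|W"
            z_key = f"{dated.focal}|Z"
            sink[w_key] = sink[w_key].copy()
            sink[w_key][start:tract[1]] = sink[z_key][start:tract[1]]

        records = [(name, "".join(NUC[sink[name]])) for name in sorted(sink)]
        aln = GametologAlignment.from_sequences(
            f"{cfg.gene_prefix}{g:04d}", records,
            suppression_time=t_s, region=cfg.region)
        genes.append(SimulatedGene(aln, t_s, _branch_containing(dated, t_s),
                                   tract))
    return genes, dated


def expected_zw_pdistance(mu: float, t_s: float) -> float:
    """Closed-form JC expectation of the focal Z-W p-distance for
    suppression at t_s: 3/4 (1 - exp(-8 mu t / 3))."""
    return 0.75 * -math.expm1(-8.0 * mu * t_s / 3.0)


# ---------------------------------------------------------------------------
# coverage / heterozygosity profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileSimConfig:
    """Coverage means follow the chromosome-class expectations at total
    autosomal (diploid) depth ``coverage``: autosome/PAR both sexes c;
    Z females c/2, males c; W females c/2, males exactly 0.  The
    default of 60x is a realistic resequencing depth for this design:
    the >25x rule for W scaffolds presupposes haploid coverage (c/2)
    clearing 25x.  A sample's recorded value is the median of per-site
    negative-binomial draws, as in real profiles;
    ``nb_dispersion=None`` gives the degenerate noise-free mode."""

    seed: int = 0
    n_per_class: int = 50
    classes: tuple[str, ...] = ("AUTOSOME", "Z", "W", "PAR")
    coverage: float = 60.0
    nb_dispersion: float | None = 10.0
    n_sites: int = 201
    n_males: int = 5
    n_females: int = 5
    scaffold_length: int = 100_000
    het_diploid: float = 0.20
    het_hemizygous: float = 0.01
    het_sd: float = 0.02


_CLASS_MEANS = {
    # (female multiplier, male multiplier)
    "AUTOSOME": (1.0, 1.0),
    "PAR": (1.0, 1.0),
    "Z": (0.5, 1.0),
    "W": (0.5, 0.0),
}

#: expected classifier output per simulated class (PAR is not separable
#: from autosomes by coverage/heterozygosity alone)
TRUTH_CALL = {"AUTOSOME": "AUTOSOME", "PAR": "AUTOSOME", "Z": "Z", "W": "W"}


def _sample_median_coverage(mean: float, cfg: ProfileSimConfig,
                            rng: np.random.Generator) -> float:
    if mean == 0.0:
        return 0.0
    if cfg.nb_dispersion is None:
        return mean
    r = cfg.nb_dispersion
    p = r / (r + mean)
    return float(np.median(rng.negative_binomial(r, p, size=cfg.n_sites)))


def _het(mean: float, cfg: ProfileSimConfig, rng: np.random.Generator) -> float:
    if cfg.nb_dispersion is None:
        return mean
    return float(np.clip(rng.normal(mean, cfg.het_sd), 0.0, 1.0))


def simulate_profiles(cfg: ProfileSimConfig
                      ) -> tuple[list[ScaffoldProfile], dict[str, str]]:
    """Simulate scaffold profiles; returns (profiles, truth class per id).

    Heterozygosity is the diploid rate for samples diploid on the
    class (both sexes on autosomes/PAR, males on Z) and near zero for
    hemizygous contexts (females on Z and W)."""
    rng = np.random.default_rng(cfg.seed)
    profiles: list[ScaffoldProfile] = []
    truth: dict[str, str] = {}
    for cls in cfg.classes:
        fmul, mmul = _CLASS_MEANS[cls]
        for i in range(cfg.n_per_class):
            sid = f"{cls.lower()}_{i:03d}"
            prof = ScaffoldProfile(sid, cfg.scaffold_length)
            for m in range(cfg.n_males):
                cov = _sample_median_coverage(cfg.coverage * mmul, cfg, rng)
                het = cfg.het_diploid if cls != "W" else 0.0
                prof.samples.append(SampleObservation(
                    f"M{m}", "M", cov, _het(het, cfg, rng) if mmul else 0.0))
            for f in range(cfg.n_females):
                cov = _sample_median_coverage(cfg.coverage * fmul, cfg, rng)
                het = (cfg.het_diploid if cls in ("AUTOSOME", "PAR")
                       else cfg.het_hemizygous)
                prof.samples.append(SampleObservation(
                    f"F{f}", "F", cov, _het(het, cfg, rng)))
            profiles.append(prof)
            truth[sid] = TRUTH_CALL[cls]
    return profiles, truth


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSimConfig:
    seed: int = 0
    n_males: int = 5
    n_females: int = 5
    depth: int = 30            # mean per-genotype depth
    depth_dispersion: float | None = None  # None = constant depth
    qual: float = 60.0
    male_poly_rate: float = 0.0  # chance a variant site carries a second Z allele
    low_depth_sites: tuple[int, ...] = ()  # 1-based positions forced to depth 15
    scaffold: str = "scaffold_Z"


def genotypes_from_haplotypes(
    z_hap: str, w_hap: str, cfg: GenotypeSimConfig
) -> list[SiteGenotypes]:
    """Project known Z and W haplotypes onto male/female genotypes.

    Males are two Z draws (homozygous Z unless ``male_poly_rate``
    introduces a second Z allele), females carry (Z, W).  A site row is
    emitted for every position where any allele differs from the Z
    reference.  Positions in ``low_depth_sites`` get depth 15 in one
    female, exercising the coverage-20 masking rule.
    """
    if len(z_hap) != len(w_hap):
        raise ValueError("haplotypes differ in length")
    rng = np.random.default_rng(cfg.seed)
    sites: list[SiteGenotypes] = []
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    for pos0, (z, w) in enumerate(zip(z_hap.upper(), w_hap.upper())):
        male_alt = None
        if cfg.male_poly_rate and rng.random() < cfg.male_poly_rate:
            male_alt = others[z][rng.integers(0, 3)]
        if z == w and male_alt is None:
            continue
        pos = pos0 + 1
        alts = sorted({a for a in (w, male_alt) if a and a != z})
        samples: list[SampleGenotype] = []
        for m in range(cfg.n_males):
            alleles = (z, z)
            if male_alt is not None and m == 0:
                alleles = (z, male_alt)
            samples.append(SampleGenotype(f"M{m}", "M", alleles,
                                          _depth(cfg, rng)))
        for f in range(cfg.n_females):
            depth = _depth(cfg, rng)
            if pos in cfg.low_depth_sites and f == 0:
                depth = 15
            samples.append(SampleGenotype(f"F{f}", "F", (z, w), depth))
        sites.append(SiteGenotypes(cfg.scaffold, pos, z, tuple(alts),
                                   cfg.qual, samples))
    return sites


def _depth(cfg: GenotypeSimConfig, rng: np.random.Generator) -> int:
    if cfg.depth_dispersion is None:
        return cfg.depth
    r = cfg.depth_dispersion
    return int(rng.negative_binomial(r, r / (r + cfg.depth)))


# ---------------------------------------------------------------------------
# neutral-SFS diversity tables
# ---------------------------------------------------------------------------

@dataclass
class DiversitySimConfig:
    """Neutral mutations on ``length`` bp for ``n_samples`` samples.

    Segregating-site count ~ Poisson(theta a_k L) with a_k the
    Watterson harmonic number for k sampled allele copies, and derived
    allele counts drawn from the neutral SFS P(j) proportional to 1/j;
    together these make the expected per-site diversity equal theta.
    """

    seed: int = 0
    theta: float = 0.003
    length: int = 1_000_000
    n_samples: int = 5
    haploid: bool = True
    depth: int = 30
    scaffold: str = "sim_scaffold"


def simulate_diversity_sites(cfg: DiversitySimConfig
                             ) -> tuple[list[VariantSite], np.ndarray]:
    """Returns (variant sites, per-sample per-site depth matrix)."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_samples if cfg.haploid else 2 * cfg.n_samples
    if k < 2:
        raise ValueError("need at least two allele copies")
    a_k = sum(1.0 / i for i in range(1, k))
    n_mut = rng.poisson(cfg.theta * a_k * cfg.length)
    positions = rng.choice(cfg.length, size=min(n_mut, cfg.length),
                           replace=False)
    sfs_p = np.array([1.0 / j for j in range(1, k)])
    sfs_p /= sfs_p.sum()
    sites: list[VariantSite] = []
    sexes = ["F"] * cfg.n_samples
    for pos0 in np.sort(positions):
        j = int(rng.choice(np.arange(1, k), p=sfs_p))
        carriers = rng.choice(k, size=j, replace=False)
        genotypes = []
        for s in range(cfg.n_samples):
            if cfg.haploid:
                alleles = (1 if s in carriers else 0,)
            else:
                alleles = (1 if 2 * s in carriers else 0,
                           1 if 2 * s + 1 in carriers else 0)
            genotypes.append(GenotypeCall(f"S{s}", sexes[s], alleles,
                                          cfg.depth))
        half = max(1, cfg.depth // 2)
        sites.append(VariantSite(cfg.scaffold, int(pos0) + 1, "A", ("G",),
                                 60.0, half, half, half, half, genotypes))
    depths = np.full((cfg.n_samples, cfg.length), cfg.depth, dtype=np.int32)
    return sites, depths
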