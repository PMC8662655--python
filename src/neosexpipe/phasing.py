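"""Phasing of coding sequence into Z and W haplotypes.

Reads from ZW females are mapped to a reference from which all
W-linked scaffolds have been removed, so female W reads co-map onto
the homologous Z scaffold.  At a site where every ZZ male is
homozygous for allele ``a`` and every female carries a second allele
``b``, the sex-stratified genotype configuration identifies ``a`` as
the Z allele and ``b`` as the W allele.  Any configuration not
explained by this hemizygosity model -- male heterozygosity or
polymorphism, several female-specific alleles, mixed female genotypes
-- is uninformative and masked to N, as are sites failing the site
quality or per-sample depth threshold (both default 20).

A per-gene deletion screen protects downstream gametolog sets from
genes whose W copy is partly or wholly deleted: a hemizygous deletion
halves the normalized female read dose relative to males and removes
female-private alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

N = "N"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

INTACT = "INTACT"
W_DELETED = "W_DELETED"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class SampleGenotype:
    sample_id: str
    sex: str  # 'M' or 'F'
    alleles: tuple[str | None, ...]  # nucleotides; None = missing call
    depth: int

    @property
    def called(self) -> bool:
        return all(a is not None for a in self.alleles)

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(a for a in self.alleles if a is not None)


@dataclass
class SiteGenotypes:
    scaffold: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    qual: float
    samples: list[SampleGenotype] = field(default_factory=list)


@dataclass
class PhasingConfig:
    min_q: float = 20.0
    min_depth: int = 20


def phase_site(site: SiteGenotypes, cfg: PhasingConfig | None = None
               ) -> tuple[str, str]:
    """Return the (Z, W) allele call for one site, each in {A,C,G,T,N}.

    Masks to (N, N) when the site quality or any used sample's depth
    falls below the configured thresholds, and for any genotype
    configuration the male-homozygous/female-carrier model does not
    explain.
    """
    cfg = cfg or PhasingConfig()
    males = [s for s in site.samples if s.sex == "M"]
    females = [s for s in site.samples if s.sex == "F"]
    if not females:
        raise ValueError(
            f"{site.scaffold}:{site.pos}: no female samples; W phasing undefined")

    if site.qual < cfg.min_q:
        return N, N
    if any(s.depth < cfg.min_depth for s in males + females):
        return N, N
    if any(not s.called for s in males + females):
        return N, N

    all_alleles = set().union(*(s.allele_set for s in males + females))
    if len(all_alleles) == 1:
        a = next(iter(all_alleles))
        return a, a

    # every male must be homozygous for the same (Z) allele
    male_sets = {s.allele_set for s in males}
    if not males or len(male_sets) != 1 or len(next(iter(male_sets))) != 1:
        return N, N
    z = next(iter(next(iter(male_sets))))

    # every female must carry one and the same non-Z allele
    w_candidates = set()
    for s in females:
        non_z = s.allele_set - {z}
        if not non_z:  # a female without the W-specific allele
            return N, N
        w_candidates |= non_z
    if len(w_candidates) != 1:
        logger.debug("%s:%d: multiallelic female-specific alleles %s; masked",
                     site.scaffold, site.pos, sorted(w_candidates))
        return N, N
    return z, w_candidates.pop()


@dataclass
class PhasedGametolog:
    gene_id: str
    species: str
    z_sequence: str
    w_sequence: str
    n_masked: int
    n_w_specific: int


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def phase_gene(
    gene_id: str,
    species: str,
    sites: Iterable[SiteGenotypes],
    cds_intervals: Sequence[tuple[int, int]],  # 0-based half-open, genomic order
    strand: str,
    scaffold_seq: str,
    cfg: PhasingConfig | None = None,
) -> PhasedGametolog:
    """Splice per-site phased calls into full-length Z and W CDS copies.

    The reference base fills every position without an informative
    variant; ``cds_intervals`` must be non-overlapping and ordered by
    genomic coordinate; minus-strand genes are reverse-complemented so
    output sequences read in transcription order.  Sites outside the
    CDS are ignored.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    prev_end = 0
    for s, e in cds_intervals:
        if e <= s or s < prev_end:
            raise ValueError("cds_intervals must be ordered and non-overlapping")
        if e > len(scaffold_seq):
            raise ValueError(f"CDS interval ({s}, {e}) outside scaffold")
        prev_end = e

    # genomic position -> index in the genomic-order concatenated CDS
    pos_to_idx: dict[int, int] = {}
    chunks = []
    idx = 0
    for s, e in cds_intervals:
        chunks.append(scaffold_seq[s:e].upper())
        for p in range(s, e):
            pos_to_idx[p] = idx
            idx += 1
    z = list("".join(chunks))
    w = list(z)

    n_masked = 0
    for site in sites:
        i = pos_to_idx.get(site.pos - 1)
        if i is None:
            continue
        za, wa = phase_site(site, cfg)
        if za == N and wa == N:
            n_masked += 1
        z[i], w[i] = za, wa

    z_seq, w_seq = "".join(z), "".join(w)
    if strand == "-":
        z_seq, w_seq = reverse_complement(z_seq), reverse_complement(w_seq)
    n_w_specific = sum(1 for a, b in zip(z_seq, w_seq) if a != b)
    return PhasedGametolog(gene_id, species, z_seq, w_seq, n_masked, n_w_specific)


# ---------------------------------------------------------------------------
# W-deletion screen
# ---------------------------------------------------------------------------

@dataclass
class ExonEvidence:
    gene_id: str
    exon_index: int
    female_coverage: float  # normalized to the female autosomal median
    male_coverage: float    # normalized to the male autosomal median
    female_private: int
    male_private: int


@dataclass
class DeletionConfig:
    cov_drop: float = 0.75  # flag exons with female/male dose below this
    min_private: int = 1    # ... and fewer female-private alleles than this


def screen_w_deletion(
    evidence: Iterable[ExonEvidence], cfg: DeletionConfig | None = None
) -> dict[str, str]:
    """Flag genes whose W copy shows signs of (partial) deletion.

    An exon is deleted when the normalized female coverage drops below
    ``cov_drop`` x the normalized male coverage *and* females show
    fewer than ``min_private`` private alleles (a true hemizygous
    deletion leaves females with only the Z copy: dose ratio 0.5 and
    no W-specific variation).  A coverage drop contradicted by ample
    female-private variation is ambiguous.  Per gene: W_DELETED if any
    exon is deleted, else AMBIGUOUS if any exon is ambiguous, else
    INTACT.
    """
    cfg = cfg or DeletionConfig()
    flags: dict[str, str] = {}
    for ev in evidence:
        if ev.male_coverage < 0 or ev.female_coverage < 0:
            raise ValueError("negative coverage")
        cov_low = ev.female_coverage < cfg.cov_drop * ev.male_coverage
        priv_low = ev.female_private < cfg.min_private
        if cov_low and priv_low:
            status = W_DELETED
        elif cov_low:
            status = AMBIGUOUS
        else:
            status = INTACT
        prev = flags.get(ev.gene_id, INTACT)
        order = {INTACT: 0, AMBIGUOUS: 1, W_DELETED: 2}
        if order[status] > order[prev]:
            flags[ev.gene_id] = status
        else:
            flags.setdefault(ev.gene_id, prev)
    return flags
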