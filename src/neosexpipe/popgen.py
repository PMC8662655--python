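"""Variant filtering, callable sites and windowed nucleotide diversity.

Diversity on sex chromosomes must be computed with sex- and
ploidy-aware bookkeeping: W and (in females) Z scaffolds are haploid,
so females contribute one allele copy per site there, and a lower
per-genotype depth threshold applies (half the diploid expectation).
Per-site diversity uses the unbiased pairwise estimator

    pi_site = 2 j (k - j) / (k (k - 1))

for j alternate copies among k observed allele copies, and window
estimates divide the per-site sum by the number of *callable* sites --
positions passing the same depth/missingness/repeat filters as the
variants -- rather than by window length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for a missing/filtered call


@dataclass
class GenotypeCall:
    sample_id: str
    sex: str
    alleles: tuple[int, ...]  # allele indices; (-1,) or (-1,-1) when missing
    depth: int

    @property
    def called(self) -> bool:
        return all(a >= 0 for a in self.alleles)


@dataclass
class VariantSite:
    scaffold: str
    pos: int  # 1-based (VCF convention)
    ref: str
    alts: tuple[str, ...]
    qual: float
    saf: int  # reads supporting the alternate on the forward strand
    sar: int  # ... reverse strand
    rpl: int  # reads placing the variant left of read centre
    rpr: int  # ... right of read centre
    genotypes: list[GenotypeCall] = field(default_factory=list)

    @property
    def is_biallelic_snp(self) -> bool:
        return (len(self.alts) == 1 and len(self.ref) == 1
                and len(self.alts[0]) == 1)

    def mean_depth(self) -> float:
        if not self.genotypes:
            return 0.0
        return float(np.mean([g.depth for g in self.genotypes]))


@dataclass
class PopgenConfig:
    min_qual: float = 20.0       # site quality must exceed this (strict)
    dp_diploid: int = 10         # per-genotype depth, males & autosomal females
    dp_hap_female: int = 5       # per-genotype depth, females on sex-linked scaffolds
    call_rate: float = 0.8       # fraction of genotypes that must be called
    cov_cap_mult: float = 2.0    # drop sites with mean depth >= mult x median mean depth
    window: int = 100_000


# ---------------------------------------------------------------------------
# interval helpers (BED convention: 0-based half-open)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping half-open intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _in_intervals(pos0: int, merged: Sequence[tuple[int, int]]) -> bool:
    """Membership of a 0-based position in merged sorted intervals."""
    import bisect
    i = bisect.bisect_right(merged, (pos0, float("inf"))) - 1
    return i >= 0 and merged[i][0] <= pos0 < merged[i][1]


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def _depth_threshold(g: GenotypeCall, cfg: PopgenConfig, sex_linked: bool) -> int:
    if sex_linked and g.sex == "F":
        return cfg.dp_hap_female
    return cfg.dp_diploid


def filter_variants(
    sites: Sequence[VariantSite],
    repeat_mask: dict[str, list[tuple[int, int]]] | None,
    cfg: PopgenConfig | None = None,
    sex_linked: bool = False,
    drop_log: list[tuple[VariantSite, str]] | None = None,
) -> list[VariantSite]:
    """Apply the variant filters in order; returns surviving sites.

    Order: repeat overlap -> mean-coverage cap (mean site depth at
    least ``cov_cap_mult`` times the median of per-site mean depths,
    computed on the input set for this context) -> site quality > Q20
    -> strand support (SAF > 0 and SAR > 0) -> read-placement support
    (RPL > 0 and RPR > 0) -> per-genotype depth (genotypes below the
    context's depth threshold are set missing) -> site call rate >=
    80% -> biallelic SNPs only.

    ``drop_log`` (optional list) receives (site, reason) for every
    removal.  Genotype masking mutates depth-failing calls to missing,
    so re-running the filter on its own output is a no-op.
    """
    cfg = cfg or PopgenConfig()
    log = drop_log if drop_log is not None else []

    masks = {k: merge_intervals(v) for k, v in (repeat_mask or {}).items()}
    stage = [s for s in sites]

    kept = []
    for s in stage:
        if s.scaffold in masks and _in_intervals(s.pos - 1, masks[s.scaffold]):
            log.append((s, "repeat_overlap"))
        else:
            kept.append(s)
    stage = kept

    if stage:
        means = np.array([s.mean_depth() for s in stage])
        cap = cfg.cov_cap_mult * float(np.median(means))
        kept = []
        for s, m in zip(stage, means):
            if m >= cap:
                log.append((s, "coverage_cap"))
            else:
                kept.append(s)
        stage = kept

    kept = []
    for s in stage:
        if not s.qual > cfg.min_qual:
            log.append((s, "quality"))
        elif not (s.saf > 0 and s.sar > 0):
            log.append((s, "strand_support"))
        elif not (s.rpl > 0 and s.rpr > 0):
            log.append((s, "read_placement"))
        else:
            kept.append(s)
    stage = kept

    kept = []
    for s in stage:
        for g in s.genotypes:
            if g.called and g.depth < _depth_threshold(g, cfg, sex_linked):
                g.alleles = tuple(MISSING for _ in g.alleles)
        n = len(s.genotypes)
        called = sum(g.called for g in s.genotypes)
        if n == 0 or called / n < cfg.call_rate:
            log.append((s, "call_rate"))
        elif not s.is_biallelic_snp:
            log.append((s, "not_biallelic_snp"))
        else:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# callable sites
# ---------------------------------------------------------------------------

@dataclass
class CallableMask:
    scaffold: str
    intervals: list[tuple[int, int]]  # 0-based half-open, sorted, disjoint

    def total_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)


def callable_sites(
    depths: np.ndarray,
    sexes: Sequence[str],
    scaffold: str,
    repeat_mask: Sequence[tuple[int, int]] | None = None,
    cfg: PopgenConfig | None = None,
    sex_linked: bool = False,
) -> CallableMask:
    """Callable positions for one scaffold and one (sex, ploidy) context.

    ``depths`` is a (n_samples, length) per-site depth matrix; a site is
    callable when >= ``call_rate`` of samples meet their depth
    threshold, its mean depth is below the coverage cap, and it is
    outside repeats.
    """
    cfg = cfg or PopgenConfig()
    depths = np.asarray(depths)
    n, length = depths.shape
    thr = np.array([
        cfg.dp_hap_female if (sex_linked and s == "F") else cfg.dp_diploid
        for s in sexes])[:, None]
    frac_ok = (depths >= thr).mean(axis=0)
    mean_depth = depths.mean(axis=0)
    cap = cfg.cov_cap_mult * float(np.median(mean_depth))
    ok = (frac_ok >= cfg.call_rate) & (mean_depth < cap)
    if repeat_mask:
        rep = np.zeros(length, dtype=bool)
        for s, e in merge_intervals(repeat_mask):
            rep[max(0, s):min(length, e)] = True
        ok &= ~rep
    return CallableMask(scaffold, _bool_to_intervals(ok))


def _bool_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


# ---------------------------------------------------------------------------
# windowed diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityWindow:
    scaffold: str
    start: int
    end: int
    pi_sum: float
    callable_bp: int
    n_snps: int

    @property
    def pi(self) -> float:
        if self.callable_bp == 0:
            return float("nan")
        return self.pi_sum / self.callable_bp


def site_pi(j: int, k: int) -> float:
    """Unbiased per-site pairwise diversity: 2 j (k - j) / (k (k - 1))."""
    if k < 2:
        raise ValueError("need at least two allele copies")
    if not 0 <= j <= k:
        raise ValueError("alternate count outside [0, k]")
    return 2.0 * j * (k - j) / (k * (k - 1))


def _allele_counts(site: VariantSite, haploid: bool) -> tuple[int, int]:
    """(alt copies, total called copies) at a site.

    In the haploid context each called genotype contributes its first
    allele only (hemizygous calls on sex-linked scaffolds)."""
    j = k = 0
    for g in site.genotypes:
        if not g.called:
            continue
        alleles = g.alleles[:1] if haploid else g.alleles
        k += len(alleles)
        j += sum(1 for a in alleles if a > 0)
    return j, k


def pi_windows(
    sites: Sequence[VariantSite],
    mask: CallableMask,
    scaffold_length: int,
    window: int = 100_000,
    haploid: bool = False,
) -> list[DiversityWindow]:
    """Per-window nucleotide diversity over callable sites.

    ``sites`` must already be filtered and lie inside ``mask`` (a site
    outside its own callable mask is a contract violation).  Window
    boundaries are half-open multiples of ``window`` from position 0.
    """
    merged = merge_intervals(mask.intervals)
    n_windows = max(1, -(-scaffold_length // window))
    wins = [DiversityWindow(mask.scaffold, i * window,
                            min((i + 1) * window, scaffold_length), 0.0, 0, 0)
            for i in range(n_windows)]
    for s, e in merged:
        for w in wins:
            lo, hi = max(s, w.start), min(e, w.end)
            if hi > lo:
                w.callable_bp += hi - lo
    for site in sites:
        pos0 = site.pos - 1
        if not _in_intervals(pos0, merged):
            raise ValueError(
                f"site {site.scaffold}:{site.pos} outside callable mask")
        j, k = _allele_counts(site, haploid)
        if k < 2:
            continue
        w = wins[pos0 // window]
        w.pi_sum += site_pi(j, k)
        w.n_snps += 1
    return wins


# ---------------------------------------------------------------------------
# repeat summaries
# ---------------------------------------------------------------------------

def repeat_fraction(
    windows: Sequence[tuple[int, int]],
    repeats: Sequence[tuple[int, int]],
) -> list[float]:
    """Fraction of each half-open window covered by the repeat-interval
    union (overlapping repeat records are merged first)."""
    merged = merge_intervals(repeats)
    out = []
    for start, end in windows:
        if end <= start:
            raise ValueError("empty window")
        covered = 0
        for s, e in merged:
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                covered += hi - lo
        out.append(covered / (end - start))
    return out


def region_repeat_fraction(
    regions: dict[str, Sequence[tuple[int, int]]],
    repeats_by_scaffold: dict[str, Sequence[tuple[int, int]]],
) -> float:
    """Length-weighted repeat fraction over a set of scaffold regions."""
    covered = total = 0
    for scaf, regs in regions.items():
        merged = merge_intervals(repeats_by_scaffold.get(scaf, []))
        for start, end in regs:
            total += end - start
            for s, e in merged:
                lo, hi = max(s, start), min(e, end)
                if hi > lo:
                    covered += hi - lo
    if total == 0:
        raise ValueError("no region length")
    return covered / total


def windows_to_frame(windows: Iterable[DiversityWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.scaffold, w.start, w.end, w.pi, w.callable_bp, w.n_snps)
         for w in windows],
        columns=["scaffold", "start", "end", "pi", "callable_bp", "n_snps"])


def read_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """Minimal BED reader (0-based half-open, first three columns)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            scaf, s, e = line.split("\t")[:3]
            out.setdefault(scaf, []).append((int(s), int(e)))
    return out
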