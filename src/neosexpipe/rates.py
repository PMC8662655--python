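"""Pairwise synonymous/nonsynonymous divergence and group contrasts.

Divergence between gametologs (and between each gametolog and an
autosomal/Z ortholog in an outgroup) is estimated with the
Nei-Gojobori (1986) counting method: synonymous and nonsynonymous
sites per codon by mutational opportunity, observed differences
averaged over all single-step substitution pathways (pathways through
stop codons excluded), and a Jukes-Cantor multiple-hit correction

    d = -3/4 ln(1 - 4/3 p).

Counting methods are deterministic and exactly checkable; they stand
in for ML codon models, which are out of scope here.

The module also bundles the nonparametric machinery used for the
standard contrasts: Mann-Whitney U (unpaired), Wilcoxon signed-rank
(paired, reporting R's V = sum of positive ranks), Spearman rank
correlation, and Kruskal-Wallis followed by Dunn's pairwise z tests
with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NUCS = "TCAG"

# standard genetic code, indexed by codon string
_BASES = [a + b + c for a in NUCS for b in NUCS for c in NUCS]
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE: dict[str, str] = dict(zip(_BASES, _AA))
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


def _norm_codon(codon: str) -> str:
    return codon.upper().replace("U", "T")


def syn_fraction_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its three possible point
    mutations that preserve the amino acid.  Mutations creating a stop
    codon count as nonsynonymous.
    """
    codon = _norm_codon(codon)
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} cannot be counted")
    s = 0.0
    for i in range(3):
        for n in NUCS:
            if n == codon[i]:
                continue
            mut = codon[:i] + n + codon[i + 1:]
            if GENETIC_CODE[mut] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Codons differing at several positions are scored by averaging the
    per-step classification over all orderings of the single-step
    mutational pathway; orderings passing through a stop codon are
    excluded.  If every ordering passes through a stop, all orderings
    are used (stop-intermediate steps classified against the genetic
    code as usual); this is a degenerate case kept for completeness.
    """
    c1, c2 = _norm_codon(c1), _norm_codon(c2)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[cur] == "*" or GENETIC_CODE[nxt] == "*":
                through_stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if through_stop else paths).append((sd, nd))
    use = paths if paths else blocked
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differences; NaN when saturated."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class RateEstimate:
    gene_id: str
    pair: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float  # NaN when saturated
    dn: float
    omega: float  # NaN when undefined (dS == 0 or saturated)
    aligned_bp: int
    saturated: bool

    @property
    def omega_defined(self) -> bool:
        return math.isfinite(self.omega)


def _clean_codons(seq1: str, seq2: str) -> list[tuple[str, str]]:
    """Pairwise-complete codons: drop any codon with a non-ACGT character
    in either sequence, and terminal/internal stop codons."""
    pairs = []
    for i in range(0, len(seq1), 3):
        c1, c2 = _norm_codon(seq1[i:i + 3]), _norm_codon(seq2[i:i + 3])
        if len(c1) < 3:
            break
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        pairs.append((c1, c2))
    return pairs


def ng86_rates(seq1: str, seq2: str, gene_id: str = "", pair: str = "",
               max_ds: float = 3.0) -> RateEstimate:
    """Nei-Gojobori (1986) pairwise dN/dS with JC correction.

    Sequences must be equal-length, in-frame CDS.  Codons containing N
    (or a gap/ambiguity) in either sequence are excluded pairwise;
    ``aligned_bp`` counts only retained codons.  Estimates with
    p >= 3/4 in either class, or dS > ``max_ds``, carry a ``saturated``
    flag (downstream filtering drops them).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("alignment length not divisible by 3")
    codons = _clean_codons(seq1, seq2)
    if not codons:
        raise ValueError("no codons left after masking")

    s_sites = n_sites = sd = nd = 0.0
    for c1, c2 in codons:
        s1, n1 = syn_fraction_sites(c1)
        s2, n2 = syn_fraction_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        dsd, dnd = pathway_differences(c1, c2)
        sd += dsd
        nd += dnd

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    saturated = math.isnan(ds) or math.isnan(dn) or (not math.isnan(ds) and ds > max_ds)
    if math.isnan(ds) or math.isnan(dn) or ds == 0.0:
        omega = float("nan")
    else:
        omega = dn / ds
    return RateEstimate(gene_id, pair, s_sites, n_sites, sd, nd, ps, pn,
                        ds, dn, omega, aligned_bp=3 * len(codons),
                        saturated=saturated)


def filter_rates(estimates: Iterable[RateEstimate], min_len: int = 500,
                 max_ds: float = 3.0) -> list[RateEstimate]:
    """Keep estimates from alignments of >= ``min_len`` retained bp with
    unsaturated dS < ``max_ds``."""
    out = []
    for r in estimates:
        if r.aligned_bp < min_len:
            continue
        if r.saturated or math.isnan(r.ds) or r.ds >= max_ds:
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Group contrasts and correlations
# ---------------------------------------------------------------------------

def compare_groups(a: Sequence[float], b: Sequence[float],
                   test: str = "mann_whitney") -> tuple[float, float]:
    """Two-sided nonparametric contrast of two value sets.

    ``mann_whitney`` returns (U, p) with U counted for the first group
    (number of (a, b) pairs with a > b, ties counted half), exact p for
    small tie-free samples.  ``wilcoxon_signed`` requires paired inputs
    of equal length and returns (V, p) with V the sum of ranks of
    positive differences (R's convention).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon_signed":
        if len(a) != len(b):
            raise ValueError("wilcoxon_signed requires paired inputs")
        d = a - b
        nz = d[d != 0]
        if nz.size == 0:
            return 0.0, 1.0
        ranks = stats.rankdata(np.abs(nz))
        v = float(ranks[nz > 0].sum())
        res = stats.wilcoxon(a, b, alternative="two-sided",
                             zero_method="wilcox")
        return v, float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def correlate_omega(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties), two-sided p."""
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_dunn_bh(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Kruskal-Wallis followed by Dunn's pairwise z tests, BH-adjusted.

    Returns one row per group pair with the Dunn z statistic, the raw
    two-sided p and the Benjamini-Hochberg adjusted p across all pairs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    sizes = {k: len(groups[k]) for k in labels}
    n = values.size
    ranks = stats.rankdata(values)
    mean_ranks: dict[str, float] = {}
    ofs = 0
    for k in labels:
        mean_ranks[k] = float(ranks[ofs:ofs + sizes[k]].mean())
        ofs += sizes[k]

    # tie correction shared by KW and Dunn
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(((counts ** 3) - counts).sum())
    tie_term = tie_sum / (12.0 * (n - 1))

    h, kw_p = stats.kruskal(*[groups[k] for k in labels])

    rows = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            sigma = math.sqrt(
                (n * (n + 1) / 12.0 - tie_term)
                * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            if sigma == 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[gi] - mean_ranks[gj]) / sigma
                p = 2.0 * stats.norm.sf(abs(z))
            rows.append((gi, gj, z, p))
    raw = [r[3] for r in rows]
    adj = multipletests(raw, method="fdr_bh")[1] if rows else []
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    df["p_adj"] = adj
    df.attrs["kruskal_h"] = float(h)
    df.attrs["kruskal_p"] = float(kw_p)
    return df


def rates_to_frame(estimates: Iterable[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.pair, r.s_sites, r.n_sites, r.sd, r.nd, r.ps, r.pn,
          r.ds, r.dn, r.omega, r.aligned_bp, r.saturated) for r in estimates],
        columns=["gene_id", "pair", "S_sites", "N_sites", "Sd", "Nd", "pS",
                 "pN", "dS", "dN", "omega", "aligned_bp", "saturated"],
    )
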