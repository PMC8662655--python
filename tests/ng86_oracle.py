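"""Independent brute-force oracle for Nei-Gojobori codon counting.

Written against Biopython's genetic-code table (an independent source
for the code) and structured as plain enumeration: synonymous site
fractions by listing all nine point mutations of a codon, and observed
differences by recursively enumerating every ordering of the
single-step mutational pathway, skipping orderings that visit a stop
codon.  Deliberately naive; used only to check the package's counting.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)


def _aa(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _TABLE.forward_table[codon]


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    syn = 0
    for i in range(3):
        for nt in "ACGT":
            if nt == codon[i]:
                continue
            mutant = codon[:i] + nt + codon[i + 1:]
            if mutant not in _STOPS and _aa(mutant) == _aa(codon):
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def _paths(c_from: str, c_to: str):
    """Yield (syn_steps, nonsyn_steps, visits_stop) for every ordering."""
    positions = [i for i in range(3) if c_from[i] != c_to[i]]

    def walk(cur, remaining, syn, nonsyn, stop_seen):
        if not remaining:
            yield syn, nonsyn, stop_seen
            return
        for pos in remaining:
            nxt = cur[:pos] + c_to[pos] + cur[pos + 1:]
            seen = stop_seen or nxt in _STOPS or cur in _STOPS
            step_syn = (nxt not in _STOPS and cur not in _STOPS
                        and _aa(cur) == _aa(nxt))
            yield from walk(nxt, [p for p in remaining if p != pos],
                            syn + (1 if step_syn else 0),
                            nonsyn + (0 if step_syn else 1), seen)

    yield from walk(c_from, positions, 0, 0, False)


def oracle_codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    if c1 == c2:
        return 0.0, 0.0
    all_paths = list(_paths(c1, c2))
    clean = [p for p in all_paths if not p[2]]
    use = clean if clean else all_paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def oracle_pair_counts(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """(S_sites, N_sites, Sd, Nd) over all clean, stop-free codons."""
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq1) - len(seq1) % 3, 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if set(c1 + c2) - set("ACGT"):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            continue
        s1, n1 = oracle_codon_sites(c1)
        s2, n2 = oracle_codon_sites(c2)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        d_s, d_n = oracle_codon_diffs(c1, c2)
        sd += d_s
        nd += d_n
    return s_sites, n_sites, sd, nd
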