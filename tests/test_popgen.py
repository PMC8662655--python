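"""Variant filters, callable masks, windowed diversity, repeat summaries."""

import numpy as np
import pytest

from neosexpipe.popgen import (
    CallableMask, GenotypeCall, VariantSite,
    callable_sites, filter_variants, merge_intervals, pi_windows,
    region_repeat_fraction, repeat_fraction, site_pi,
)


def make_site(pos, qual=60.0, saf=5, sar=5, rpl=5, rpr=5, depths=None,
              called=None, scaffold="s", alts=("G",), ref="A",
              n_samples=10, het_every=2):
    depths = depths or [30] * n_samples
    called = called if called is not None else [True] * n_samples
    genotypes = []
    for i in range(n_samples):
        if not called[i]:
            alleles = (-1, -1)
        elif i % het_every == 0:
            alleles = (0, 1)
        else:
            alleles = (0, 0)
        genotypes.append(GenotypeCall(f"S{i}", "F" if i < 5 else "M",
                                      alleles, depths[i]))
    return VariantSite(scaffold, pos, ref, alts, qual, saf, sar, rpl, rpr,
                       genotypes)


# ---------------------------------------------------------------------------
# per-site and per-window diversity
# ---------------------------------------------------------------------------

def test_site_pi_hand_values():
    assert site_pi(2, 5) == pytest.approx(0.6)
    assert site_pi(5, 10) == pytest.approx(2 * 5 * 5 / 90)
    assert site_pi(0, 5) == 0.0
    with pytest.raises(ValueError):
        site_pi(3, 1)


def test_window_pi_toy_example():
    """One site with 2/5 haploid alt copies over 100 callable bp."""
    gts = [GenotypeCall(f"S{i}", "F", (1,) if i < 2 else (0,), 30)
           for i in range(5)]
    site = VariantSite("s", 10, "A", ("G",), 60, 3, 3, 3, 3, gts)
    mask = CallableMask("s", [(0, 100)])
    [win] = pi_windows([site], mask, scaffold_length=100, window=100_000,
                       haploid=True)
    assert win.pi_sum == pytest.approx(0.6)
    assert win.callable_bp == 100
    assert win.pi == pytest.approx(0.006)


def test_no_snps_gives_zero_pi_and_empty_mask_gives_nan():
    mask = CallableMask("s", [(0, 100_000)])
    [win] = pi_windows([], mask, scaffold_length=100_000)
    assert win.pi == 0.0
    empty = CallableMask("s", [])
    [win] = pi_windows([], empty, scaffold_length=50_000)
    assert np.isnan(win.pi)


def test_diploid_equals_equivalent_haploid_set():
    """pi from n diploids equals pi from their 2n phased haplotypes."""
    rng = np.random.default_rng(0)
    mask = CallableMask("s", [(0, 1000)])
    dip_sites, hap_sites = [], []
    for pos in range(1, 30):
        hap_alleles = rng.integers(0, 2, size=10)
        dip = [GenotypeCall(f"S{i}", "F",
                            (int(hap_alleles[2 * i]), int(hap_alleles[2 * i + 1])),
                            30) for i in range(5)]
        hap = [GenotypeCall(f"H{j}", "F", (int(hap_alleles[j]),), 30)
               for j in range(10)]
        dip_sites.append(VariantSite("s", pos, "A", ("G",), 60, 3, 3, 3, 3, dip))
        hap_sites.append(VariantSite("s", pos, "A", ("G",), 60, 3, 3, 3, 3, hap))
    [dw] = pi_windows(dip_sites, mask, 1000, haploid=False)
    [hw] = pi_windows(hap_sites, mask, 1000, haploid=True)
    assert dw.pi_sum == pytest.approx(hw.pi_sum)


def test_site_outside_mask_is_contract_violation():
    mask = CallableMask("s", [(0, 5)])
    site = make_site(50)
    with pytest.raises(ValueError, match="outside callable mask"):
        pi_windows([site], mask, 100)


# ---------------------------------------------------------------------------
# variant filters
# ---------------------------------------------------------------------------

def test_filters_drop_reasons_and_survivors():
    """A constructed fixture where every site's fate is known per filter."""
    sites = [
        make_site(5),                                  # in repeat -> dropped
        make_site(100, depths=[200] * 10),             # coverage cap
        make_site(200, qual=20.0),                     # Q exactly 20: dropped
        make_site(300, saf=0),                         # strand support
        make_site(400, rpr=0),                         # read placement
        make_site(500, depths=[30] * 7 + [5] * 3),     # 3 genotypes masked -> 70%
        make_site(600, called=[True] * 7 + [False] * 3),  # 70% called
        make_site(700, alts=("G", "T")),               # not biallelic
        make_site(800),                                # survivor
        make_site(900),                                # survivor
    ]
    repeat_mask = {"s": [(0, 10)]}
    log = []
    kept = filter_variants(sites, repeat_mask, drop_log=log)
    assert [s.pos for s in kept] == [800, 900]
    reasons = {s.pos: reason for s, reason in log}
    assert reasons == {5: "repeat_overlap", 100: "coverage_cap",
                       200: "quality", 300: "strand_support",
                       400: "read_placement", 500: "call_rate",
                       600: "call_rate", 700: "not_biallelic_snp"}


def test_filters_idempotent():
    sites = [make_site(p) for p in (100, 200, 300)]
    once = filter_variants(sites, {})
    twice = filter_variants(once, {})
    assert twice == once


def test_female_sexlinked_depth_threshold_is_five():
    # depth 6 in females: fails the 10x diploid rule, passes the 5x rule
    depths = [6] * 5 + [30] * 5
    site = make_site(100, depths=depths)
    assert filter_variants([site], {}, sex_linked=False) == []
    site2 = make_site(100, depths=depths)
    assert len(filter_variants([site2], {}, sex_linked=True)) == 1


def test_missing_support_field_is_an_error():
    site = make_site(100)
    site.saf = None
    with pytest.raises(TypeError):
        filter_variants([site], {})


# ---------------------------------------------------------------------------
# callable sites
# ---------------------------------------------------------------------------

def test_uniform_depth_everything_callable():
    depths = np.full((4, 1000), 30)
    mask = callable_sites(depths, ["F", "F", "M", "M"], "s")
    assert mask.intervals == [(0, 1000)]
    assert mask.total_bp() == 1000


def test_female_depth_four_not_callable_on_sexlinked():
    depths = np.full((5, 100), 4)
    mask = callable_sites(depths, ["F"] * 5, "s", sex_linked=True)
    assert mask.total_bp() == 0
    depths5 = np.full((5, 100), 5)
    mask5 = callable_sites(depths5, ["F"] * 5, "s", sex_linked=True)
    assert mask5.total_bp() == 100


def test_repeat_removed_from_callable():
    depths = np.full((4, 10_000), 30)
    mask = callable_sites(depths, ["F", "F", "M", "M"], "s",
                          repeat_mask=[(2000, 3000)])
    assert mask.total_bp() == 9000
    assert (2000, 3000) not in mask.intervals


# ---------------------------------------------------------------------------
# repeat fractions
# ---------------------------------------------------------------------------

def test_repeat_fraction_examples():
    assert repeat_fraction([(0, 1000)], [(0, 2000)]) == [1.0]
    assert repeat_fraction([(0, 100_000)],
                           [(10_000, 20_000), (20_000, 30_000)]) == [0.2]
    # overlapping records merged: 50k + 50k overlapping by 25k -> 75k
    assert repeat_fraction([(0, 100_000)],
                           [(0, 50_000), (25_000, 75_000)]) == [0.75]


def test_interval_union_against_boolean_oracle():
    rng = np.random.default_rng(1)
    repeats = [(int(s), int(s + rng.integers(1, 500)))
               for s in rng.integers(0, 9500, size=40)]
    frac = repeat_fraction([(0, 10_000)], repeats)[0]
    arr = np.zeros(10_000, dtype=bool)
    for s, e in repeats:
        arr[s:e] = True
    assert frac == pytest.approx(arr.mean())
    merged = merge_intervals(repeats)
    assert all(a[1] < b[0] for a, b in zip(merged, merged[1:]))


def test_region_repeat_fraction_length_weighted():
    regions = {"s1": [(0, 1000)], "s2": [(0, 3000)]}
    repeats = {"s1": [(0, 1000)], "s2": []}
    assert region_repeat_fraction(regions, repeats) == pytest.approx(0.25)
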