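"""Spearman classifier: rank-correlation oracle, expected profiles, decisions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from rhdocall.errors import ValidationError
from rhdocall.inference import (
    call_haplotype,
    expected_plasma_frequency,
    expected_profiles,
    spearman_rho,
)
from rhdocall.types import (
    AlleleCounts,
    Call,
    ExpectedProfiles,
    Parent,
    PhasedParent,
    QcFlag,
    SnpSite,
)


def naive_spearman(x, y):
    """Brute-force oracle: sort-based average ranks, then textbook Pearson."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1  # ranks are 1-based
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def test_spearman_identity_and_reversal():
    assert spearman_rho([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]).rho == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)


def test_spearman_with_ties_matches_naive_oracle():
    x, y = [0.1, 0.4, 0.2, 0.2], [1, 4, 2, 3]
    assert spearman_rho(x, y).rho == pytest.approx(naive_spearman(x, y), abs=1e-15)


def test_spearman_oracle_equivalence_bulk():
    """1000 random vectors, with and without ties, agree to 1e-12 with both
    the brute-force oracle and scipy's independent implementation."""
    rng = np.random.default_rng(123)
    for i in range(1000):
        n = int(rng.integers(3, 30))
        if i % 2:  # force ties half the time
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
        else:
            x = rng.random(n)
            y = rng.random(n)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        mine = spearman_rho(x, y).rho
        assert mine == pytest.approx(naive_spearman(x, y), abs=1e-12)
        assert mine == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=6), min_size=3, max_size=20),
    st.data(),
)
def test_spearman_property_matches_oracle(xs, data):
    ys = data.draw(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                            min_size=len(xs), max_size=len(xs)))
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        return
    assert spearman_rho(xs, ys).rho == pytest.approx(naive_spearman(xs, ys), abs=1e-12)


def test_spearman_rejects_constant_and_short_vectors():
    with pytest.raises(ValidationError):
        spearman_rho([1.0, 1.0, 1.0], [1, 2, 3])
    with pytest.raises(ValidationError):
        spearman_rho([1.0], [2.0])


def make_phased(parent, h0, co):
    n = len(h0)
    return PhasedParent(
        parent=parent,
        sites=[SnpSite("chr11", 100 + i, "A", "G") for i in range(n)],
        h0=list(h0), h1=[1 - h for h in h0], co_parent=list(co),
    )


def counts_map(phased, freqs, depth=1000):
    out = {}
    for site, f in zip(phased.sites, freqs):
        alt = round(f * depth)
        out[site.key] = AlleleCounts(site=site, ref_count=depth - alt, alt_count=alt)
    return out


def test_expected_profile_values_paternal():
    """Paternal site over a ref-hom mother: background 0, fetal adds ff*h/2."""
    phased = make_phased(Parent.PATERNAL, h0=[1, 0], co=[0, 0])
    prof = expected_profiles(phased, counts_map(phased, [0.05, 0.0]), ff=0.1)
    assert prof.e0 == pytest.approx([0.05, 0.0])
    assert prof.e1 == pytest.approx([0.0, 0.05])


def test_expected_profile_values_maternal():
    """Maternal site over a ref-hom father: (1-ff)/2 + ff*h/2 -> {0.45, 0.50}."""
    phased = make_phased(Parent.MATERNAL, h0=[1, 0], co=[0, 0])
    prof = expected_profiles(phased, counts_map(phased, [0.5, 0.45]), ff=0.1)
    assert prof.e0 == pytest.approx([0.50, 0.45])
    assert prof.e1 == pytest.approx([0.45, 0.50])


def test_expected_profile_alt_hom_backgrounds():
    # Paternal site over an alt-hom mother: 1 - ff*(1-h)/2.
    assert expected_plasma_frequency(2, 1, 1, 0.1) == pytest.approx(1.0)
    assert expected_plasma_frequency(2, 1, 0, 0.1) == pytest.approx(0.95)
    # Maternal site with alt-hom father: 0.5 + ff/2 + ff*h/2 - adjusted form.
    assert expected_plasma_frequency(1, 1, 0, 0.1) == pytest.approx(0.50)
    assert expected_plasma_frequency(1, 1, 1, 0.1) == pytest.approx(0.55)


def test_maternal_profiles_collapse_as_ff_vanishes():
    phased = make_phased(Parent.MATERNAL, h0=[1, 0, 1], co=[0, 0, 1])
    prof = expected_profiles(phased, counts_map(phased, [0.5, 0.45, 0.55]), ff=1e-9)
    assert prof.e0 == pytest.approx(prof.e1, abs=1e-8)


def test_zero_depth_sites_are_excluded():
    phased = make_phased(Parent.MATERNAL, h0=[1, 0, 1], co=[0, 0, 0])
    cm = counts_map(phased, [0.5, 0.45, 0.5])
    key = phased.sites[1].key
    cm[key] = AlleleCounts(site=phased.sites[1], ref_count=0, alt_count=0)
    prof = expected_profiles(phased, cm, ff=0.1)
    assert prof.n_sites == 2


def test_ff_out_of_range_rejected():
    phased = make_phased(Parent.MATERNAL, h0=[1, 0], co=[0, 0])
    with pytest.raises(ValidationError):
        expected_profiles(phased, counts_map(phased, [0.5, 0.45]), ff=0.0)


def profiles_from(o, e0, e1, parent=Parent.MATERNAL, ff=0.1):
    n = len(o)
    return ExpectedProfiles(
        parent=parent,
        sites=[SnpSite("chr11", 100 + i, "A", "G") for i in range(n)],
        e0=list(e0), e1=list(e1), o=list(o), ff=ff,
    )


def test_call_follows_better_correlated_hypothesis():
    o = [0.51, 0.44, 0.56, 0.46]
    e0 = [0.50, 0.45, 0.55, 0.45]
    e1 = [0.45, 0.50, 0.45, 0.55]
    res = call_haplotype(profiles_from(o, e0, e1), ff_ok=True, n_ok=True)
    assert res.call is Call.H0
    assert res.rho_h0 > res.rho_h1


def test_label_symmetry():
    o = [0.51, 0.44, 0.56, 0.46]
    e0 = [0.50, 0.45, 0.55, 0.45]
    e1 = [0.45, 0.50, 0.45, 0.55]
    a = call_haplotype(profiles_from(o, e0, e1), ff_ok=True, n_ok=True)
    b = call_haplotype(profiles_from(o, e1, e0), ff_ok=True, n_ok=True)
    assert (a.call, b.call) == (Call.H0, Call.H1)
    assert a.rho_h0 == pytest.approx(b.rho_h1)
    assert a.rho_h1 == pytest.approx(b.rho_h0)


def test_gates_override_data():
    prof = profiles_from([0.51, 0.44, 0.56, 0.46],
                         [0.50, 0.45, 0.55, 0.45],
                         [0.45, 0.50, 0.45, 0.55])
    low_ff = call_haplotype(prof, ff_ok=False, n_ok=True)
    assert low_ff.call is Call.NO_CALL and QcFlag.LOW_FF in low_ff.qc_flags
    few = call_haplotype(prof, ff_ok=True, n_ok=False)
    assert few.call is Call.NO_CALL and QcFlag.FEW_SNPS in few.qc_flags


def test_exact_tie_and_degenerate_input_are_no_calls():
    # e0 and e1 rank identically against o -> equal rho -> tie.
    tie = call_haplotype(
        profiles_from([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], [0.2, 0.3, 0.4]),
        ff_ok=True, n_ok=True,
    )
    assert tie.call is Call.NO_CALL and QcFlag.TIE in tie.qc_flags
    degenerate = call_haplotype(
        profiles_from([0.1, 0.2, 0.3], [0.5, 0.5, 0.5], [0.45, 0.45, 0.45]),
        ff_ok=True, n_ok=True,
    )
    assert degenerate.call is Call.NO_CALL and QcFlag.TIE in degenerate.qc_flags


def test_margin_makes_calls_conservative():
    o = [0.51, 0.44, 0.56, 0.46, 0.5]
    e0 = [0.50, 0.45, 0.55, 0.45, 0.5]
    e1 = [0.45, 0.50, 0.45, 0.55, 0.5]
    strict = call_haplotype(profiles_from(o, e0, e1), ff_ok=True, n_ok=True, margin=0.0)
    assert strict.call is Call.H0
    timid = call_haplotype(profiles_from(o, e0, e1), ff_ok=True, n_ok=True, margin=1.99)
    assert timid.call is Call.NO_CALL and QcFlag.TIE in timid.qc_flags


def test_count_scaling_leaves_call_unchanged():
    """O's ranks are scale-free: multiplying all plasma counts by a constant
    changes nothing."""
    rng = np.random.default_rng(42)
    for _ in range(500):
        n = int(rng.integers(5, 15))
        h0 = rng.integers(0, 2, size=n)
        if len(set(h0.tolist())) < 2:
            continue
        phased = make_phased(Parent.MATERNAL, h0=h0.tolist(), co=[0] * n)
        depth = 500
        alts = rng.binomial(depth, 0.45 + 0.05 * h0)
        cm1 = {s.key: AlleleCounts(site=s, ref_count=depth - a, alt_count=int(a))
               for s, a in zip(phased.sites, alts)}
        cm2 = {s.key: AlleleCounts(site=s, ref_count=7 * (depth - a), alt_count=7 * int(a))
               for s, a in zip(phased.sites, alts)}
        p1 = expected_profiles(phased, cm1, ff=0.1)
        p2 = expected_profiles(phased, cm2, ff=0.1)
        r1 = call_haplotype(p1, ff_ok=True, n_ok=True)
        r2 = call_haplotype(p2, ff_ok=True, n_ok=True)
        assert r1.call is r2.call
        assert r1.rho_h0 == pytest.approx(r2.rho_h0)
        assert r1.rho_h1 == pytest.approx(r2.rho_h1)
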