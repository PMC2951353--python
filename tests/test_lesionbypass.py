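import numpy as np
import pytest

from igtls.errors import DataError
from igtls.lesionbypass import (
    LesionPlasmidArchitecture,
    classify_pqto,
    classify_pqts,
    classify_products,
    deletion_fraction,
    incorporation_profile,
    tls_fraction,
)
from igtls.seq_io import reverse_complement
from igtls.synth import BypassSimParams, simulate_bypass_products

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _with_site(arch, site, dinuc):
    ref = list(arch.reference)
    ref[site[0]], ref[site[1] - 1] = dinuc[0], dinuc[1]
    return "".join(ref)


def _with_deletion(arch, start, length):
    ref = arch.reference
    return ref[:start] + ref[start + length :]


def test_marker_form_product_is_error_free(pqts_arch):
    call = classify_pqts("r", pqts_arch.reference, pqts_arch)
    assert call.mode == "error_free"
    assert call.deletion_length == 0


def test_accurate_tls_top(pqts_arch):
    # AA inserted opposite the top-strand lesion reads TT on the top strand
    product = _with_site(pqts_arch, pqts_arch.top_site, "TT")
    call = classify_pqts("r", product, pqts_arch)
    assert call.mode == "TLS_top"
    assert call.bases["3pT"] == "A" and call.bases["5pT"] == "A"
    assert call.accurate


def test_accurate_tls_bottom_reads_insertion_directly(pqts_arch):
    product = _with_site(pqts_arch, pqts_arch.bottom_site, "AA")
    call = classify_pqts("r", product, pqts_arch)
    assert call.mode == "TLS_bottom"
    assert call.accurate
    # +1/+2 follow the template to the right of the bottom site
    s = pqts_arch.bottom_site[0]
    assert call.bases["plus1"] == pqts_arch.reference[s + 2]


def test_inaccurate_tls_records_bases(pqts_arch):
    t = pqts_arch.top_site[0]
    product = _with_site(pqts_arch, pqts_arch.top_site, "GT")
    call = classify_pqts("r", product, pqts_arch)
    assert call.mode == "TLS_top" and not call.accurate
    assert call.bases["5pT"] == _COMP["G"] and call.bases["3pT"] == _COMP["T"]


def test_deletion_covering_top_site(pqts_arch):
    product = _with_deletion(pqts_arch, pqts_arch.top_site[0], 3)
    call = classify_pqts("r", product, pqts_arch)
    assert call.mode == "TLS_top"
    assert call.deletion_length == 3
    assert call.bases["3pT"] == "del" and call.bases["5pT"] == "del"
    assert not call.accurate


def test_both_sites_non_marker_flagged_other(pqts_arch):
    product = _with_site(pqts_arch, pqts_arch.top_site, "TT")
    arch2 = pqts_arch
    product = _with_site(
        LesionPlasmidArchitecture(
            arch2.id, arch2.arrangement, product, arch2.top_site, arch2.bottom_site,
            arch2.marker, arch2.accurate, arch2.spacer,
        ),
        arch2.bottom_site,
        "AA",
    )
    assert classify_pqts("r", product, pqts_arch).mode == "other"


def test_classification_invariant_under_reverse_complement(pqts_arch):
    product = _with_site(pqts_arch, pqts_arch.top_site, "TT")
    fwd = classify_pqts("r", product, pqts_arch)
    rev = classify_pqts("r", reverse_complement(product), pqts_arch)
    assert (fwd.mode, fwd.bases, fwd.deletion_length) == (rev.mode, rev.bases, rev.deletion_length)


def test_garbage_read_unclassifiable(pqts_arch):
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), len(pqts_arch.reference)))
    call = classify_pqts("r", junk, pqts_arch, min_identity=0.90)
    assert call.mode == "unclassifiable"


def test_pqto_full_length_site_is_tls(pqto_arch):
    call = classify_pqto("r", pqto_arch.reference, pqto_arch)
    assert call.mode == "TLS"
    assert call.accurate  # reads the template's own TT


def test_pqto_two_nt_deletion_is_deletion_class(pqto_arch):
    product = _with_deletion(pqto_arch, pqto_arch.top_site[0], 2)
    call = classify_pqto("r", product, pqto_arch)
    assert call.mode == "deletion"
    assert call.deletion_length == 2


def test_pqto_one_nt_deletion_stays_tls(pqto_arch):
    product = _with_deletion(pqto_arch, pqto_arch.top_site[0], 1)
    call = classify_pqto("r", product, pqto_arch)
    assert call.mode == "TLS"
    assert call.deletion_length == 1


def test_arrangement_validation(pqts_arch, pqto_arch):
    with pytest.raises(DataError):
        classify_pqts("r", pqts_arch.reference, pqto_arch)
    with pytest.raises(DataError):
        LesionPlasmidArchitecture("x", "staggered", "ACGTACGTAC", (2, 4), (3, 5))
    with pytest.raises(DataError):
        LesionPlasmidArchitecture("x", "opposing", "ACGTACGTAC", (2, 4), (5, 7))


def test_tls_fraction_trivial_cases(pqts_arch):
    ef = [classify_pqts(f"e{i}", pqts_arch.reference, pqts_arch) for i in range(10)]
    frac = tls_fraction(ef)
    assert frac.percent_tls == 0.0 and frac.percent_error_free == 100.0
    tls_prod = _with_site(pqts_arch, pqts_arch.top_site, "TT")
    mixed = ef[:5] + [classify_pqts(f"t{i}", tls_prod, pqts_arch) for i in range(5)]
    assert tls_fraction(mixed).percent_tls == 50.0


def test_fraction_percentages_sum_to_100(pqts_arch):
    products, _ = simulate_bypass_products(
        pqts_arch, BypassSimParams(mode_weights={"TLS_top": 0.3, "TLS_bottom": 0.2,
                                                 "error_free": 0.45, "other": 0.05},
                                   n_products=120, seed=12),
    )
    calls = classify_products(products.reads, pqts_arch)
    frac = tls_fraction(calls)
    assert frac.percent_tls + frac.percent_error_free + frac.percent_other == pytest.approx(100.0)


def test_tls_fraction_requires_classifiable():
    with pytest.raises(DataError):
        tls_fraction([])


def test_incorporation_profile_all_accurate(pqts_arch):
    prod = _with_site(pqts_arch, pqts_arch.top_site, "TT")
    calls = [classify_pqts(f"r{i}", prod, pqts_arch) for i in range(4)]
    prof = incorporation_profile(calls)
    assert prof.frequency("3pT", "A") == 1.0
    assert prof.frequency("5pT", "A") == 1.0
    assert np.allclose(prof.frequencies.sum(axis=1), 1.0)


def test_incorporation_profile_single_call_one_hot(pqts_arch):
    prod = _with_site(pqts_arch, pqts_arch.top_site, "GT")
    prof = incorporation_profile([classify_pqts("r", prod, pqts_arch)])
    assert prof.n_calls == 1
    assert set(np.unique(prof.frequencies.values)) <= {0.0, 1.0}


def test_incorporation_profile_requires_tls(pqts_arch):
    ef = [classify_pqts("r", pqts_arch.reference, pqts_arch)]
    with pytest.raises(DataError):
        incorporation_profile(ef)


def test_pqto_deletion_fraction(pqto_arch):
    products, truth = simulate_bypass_products(
        pqto_arch, BypassSimParams(mode_weights={"TLS": 0.6, "deletion": 0.4},
                                   n_products=150, seed=21),
    )
    calls = classify_products(products.reads, pqto_arch)
    truth_pct = 100.0 * sum(t.mode == "deletion" for t in truth) / len(truth)
    assert deletion_fraction(calls) == pytest.approx(truth_pct)
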