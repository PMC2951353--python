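import numpy as np
import pytest

from igtls.errors import DataError
from igtls.gcclass import classify_clone_set
from igtls.mutcall import call_clone_set
from igtls.spectra import tally_spectrum
from igtls.synth import (
    BypassSimParams,
    DonorSimParams,
    HypermutSimParams,
    event_recovery,
    simulate_bypass_products,
    simulate_clone_set,
    simulate_parent,
    simulate_pseudogene_db,
)


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def test_donor_db_seed_determinism(parent):
    p = DonorSimParams(n_donors=5, divergence=0.02, seed=7)
    db1 = simulate_pseudogene_db(parent, p)
    db2 = simulate_pseudogene_db(parent, p)
    assert [(d.id, d.sequence) for d in db1] == [(d.id, d.sequence) for d in db2]


def test_donor_divergence_zero_rejected():
    with pytest.raises(DataError):
        DonorSimParams(divergence=0.0)


def test_donor_pairwise_distance_honoured(parent):
    db = simulate_pseudogene_db(parent, DonorSimParams(n_donors=3, min_inter_donor_diff=3, seed=1))
    seqs = [d.sequence for d in db]
    for i in range(len(seqs)):
        assert _hamming(seqs[i], parent) >= 1
        for j in range(i + 1, len(seqs)):
            assert _hamming(seqs[i], seqs[j]) >= 3


def test_clone_set_determinism_and_truth_consistency(parent, donor_db):
    params = HypermutSimParams(n_clones=5, event_mean=4, gc_fraction=0.5, seed=17)
    cs1, tr1 = simulate_clone_set(parent, donor_db, params)
    cs2, _ = simulate_clone_set(parent, donor_db, params)
    assert cs1.clones == cs2.clones
    # applying truth events (plus recorded errors) rebuilds each clone exactly
    for (cid, seq), truth in zip(cs1.clones, tr1):
        rebuilt = list(parent)
        for ev in truth.events:
            for pos, ref, alt in ev.mutations:
                assert rebuilt[pos] == ref
                rebuilt[pos] = alt
        for pos, _ref, alt in truth.errors:
            rebuilt[pos] = alt
        assert "".join(rebuilt) == seq


def test_zero_event_mean_gives_parental_clones(parent, donor_db):
    cs, truth = simulate_clone_set(parent, donor_db, HypermutSimParams(event_mean=0, seed=3))
    assert all(seq == parent for _, seq in cs.clones)
    assert all(not t.events for t in truth)


def test_pure_ct_spectrum_recovered(parent, donor_db):
    params = HypermutSimParams(
        n_clones=6, event_mean=3, gc_fraction=0.0, pm_spectrum={"C>T": 1.0}, seed=23
    )
    cs, _ = simulate_clone_set(parent, donor_db, params)
    calls = call_clone_set(parent, cs.clones)
    events = classify_clone_set(parent, calls, donor_db)
    spec = tally_spectrum([e for evs in events.values() for e in evs], "PM")
    assert spec.total > 0
    assert spec.count("C", "T") == spec.total


def test_gc_only_simulation_recovered_as_gc(parent, donor_db):
    params = HypermutSimParams(
        n_clones=8, event_mean=2, gc_fraction=1.0, gc_min_tract_diffs=2, seed=29
    )
    cs, truth = simulate_clone_set(parent, donor_db, params)
    assert all(ev.category == "GC" for t in truth for ev in t.events)
    calls = call_clone_set(parent, cs.clones)
    events = classify_clone_set(parent, calls, donor_db)
    ok, total = event_recovery(truth, events)
    assert total > 0 and ok == total


def test_bypass_product_determinism(pqts_arch):
    p = BypassSimParams(n_products=30, seed=5)
    r1, t1 = simulate_bypass_products(pqts_arch, p)
    r2, _ = simulate_bypass_products(pqts_arch, p)
    assert r1.reads == r2.reads
    assert len(t1) == 30


def test_error_free_mixture_yields_reference_copies(pqts_arch):
    products, truth = simulate_bypass_products(
        pqts_arch, BypassSimParams(mode_weights={"error_free": 1.0}, n_products=10, seed=2)
    )
    assert all(seq == pqts_arch.reference for _, seq in products.reads)
    assert all(t.mode == "error_free" for t in truth)


def test_opposing_rejects_error_free_weight(pqto_arch):
    with pytest.raises(DataError):
        simulate_bypass_products(
            pqto_arch, BypassSimParams(mode_weights={"TLS": 0.5, "error_free": 0.5})
        )


def test_truth_modes_follow_mixture(pqts_arch):
    products, truth = simulate_bypass_products(
        pqts_arch,
        BypassSimParams(mode_weights={"TLS_top": 0.3, "TLS_bottom": 0.1, "error_free": 0.6},
                        n_products=600, seed=11),
    )
    frac_top = sum(t.mode == "TLS_top" for t in truth) / len(truth)
    assert abs(frac_top - 0.3) < 0.06  # ~3 sigma for n=600
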