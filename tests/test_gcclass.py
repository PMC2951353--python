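import numpy as np
import pytest

from oracles import oracle_classify

from igtls.errors import DataError
from igtls.gcclass import (
    ClassifierParams,
    EventCall,
    SeqProfile,
    classify_clone,
    find_donor_matches,
)
from igtls.mutcall import Mutation
from igtls.seq_io import PseudogeneDB
from igtls.synth import simulate_parent, simulate_pseudogene_db, DonorSimParams

OTHER = {"A": "G", "C": "T", "G": "A", "T": "C"}


def _sub(parent, pos, alt=None):
    alt = alt or OTHER[parent[pos]]
    return Mutation("substitution", pos, parent[pos], alt)


def _donor_with_diffs(parent, positions):
    d = list(parent)
    for p in positions:
        d[p] = OTHER[parent[p]]
    return "".join(d)


@pytest.fixture()
def parent60():
    return simulate_parent(60, seed=33)


def test_single_diff_donor_yields_maximal_match(parent60):
    """A donor differing only at the mutated position matches over the full
    shared flank, found by brute-force substring enumeration too."""
    donor = _donor_with_diffs(parent60, [30])
    db = PseudogeneDB.from_records([("d1", donor)])
    mut = _sub(parent60, 30, donor[30])
    prof = SeqProfile.from_mutations(parent60, [mut])
    matches = find_donor_matches(mut, prof, db)
    assert len(matches) == 1
    assert matches[0].length == 60  # whole sequence is the maximal shared string
    assert matches[0].interval == (0, 60)


def test_min_length_bound_excludes_short_matches(parent60):
    donor = _donor_with_diffs(parent60, [30])
    db = PseudogeneDB.from_records([("d1", donor)])
    mut = _sub(parent60, 30, donor[30])
    prof = SeqProfile.from_mutations(parent60, [mut])
    assert find_donor_matches(mut, prof, db, ClassifierParams(min_length=61)) == []


def test_alt_absent_from_donors_has_no_match(parent60):
    donor = _donor_with_diffs(parent60, [30])
    db = PseudogeneDB.from_records([("d1", donor)])
    third = next(b for b in "ACGT" if b not in (parent60[30], donor[30]))
    mut = _sub(parent60, 30, third)
    prof = SeqProfile.from_mutations(parent60, [mut])
    assert find_donor_matches(mut, prof, db) == []


def test_two_codiffs_form_one_gc_event(parent60):
    donor = _donor_with_diffs(parent60, [20, 35])
    db = PseudogeneDB.from_records([("dA", donor)])
    muts = [_sub(parent60, 20, donor[20]), _sub(parent60, 35, donor[35])]
    events = classify_clone(muts, parent60, db)
    assert [e.category for e in events] == ["GC"]
    assert events[0].donor_id == "dA"
    assert len(events[0].members) == 2
    lo, hi = events[0].tract
    assert lo <= 20 and hi >= 36  # tract covers both copied diffs


def test_single_codiff_is_ambiguous(parent60):
    donor = _donor_with_diffs(parent60, [20, 35])
    db = PseudogeneDB.from_records([("dA", donor)])
    events = classify_clone([_sub(parent60, 20, donor[20])], parent60, db)
    assert [e.category for e in events] == ["AMB"]
    assert events[0].donor_id == "dA"


def test_independent_unmatched_diffs_are_two_pms(parent60):
    donor = _donor_with_diffs(parent60, [20, 35])
    db = PseudogeneDB.from_records([("dA", donor)])
    muts = []
    for pos in (10, 45):
        third = next(b for b in "ACGT" if b not in (parent60[pos], donor[pos]))
        muts.append(_sub(parent60, pos, third))
    events = classify_clone(muts, parent60, db)
    assert [e.category for e in events] == ["PM", "PM"]


def test_empty_input_empty_output(parent60, donor_db):
    assert classify_clone([], parent60, donor_db) == []


def test_partition_and_event_contracts(parent, donor_db):
    rng = np.random.default_rng(5)
    donors = list(donor_db)
    muts = []
    d = donors[0]
    diffs = [i for i in range(len(parent)) if d.sequence[i] != parent[i]][:3]
    for p in diffs:
        muts.append(Mutation("substitution", p, parent[p], d.sequence[p]))
    for _ in range(3):
        p = int(rng.integers(len(parent)))
        if any(m.pos == p for m in muts) or any(x.sequence[p] != parent[p] for x in donors):
            continue
        muts.append(_sub(parent, p))
    events = classify_clone(muts, parent, donor_db)
    # partition: every mutation in exactly one event
    assert sum(len(e.members) for e in events) == len(muts)
    seen = [m.pos for e in events for m in e.members]
    assert len(seen) == len(set(seen))
    for e in events:
        if e.category in ("PM", "AMB"):
            assert len(e.members) == 1
        else:
            assert len(e.members) >= 2 and e.donor_id is not None


def test_event_call_contracts():
    m = Mutation("substitution", 0, "A", "C")
    with pytest.raises(DataError):
        EventCall("GC", (m,))
    with pytest.raises(DataError):
        EventCall("PM", (m, m))


def test_mutation_outside_parent_rejected(parent60, donor_db):
    with pytest.raises(DataError):
        classify_clone([Mutation("substitution", 99, "A", "C")], parent60, donor_db)


def test_raising_min_length_only_demotes_toward_pm(parent60):
    """Monotonicity: a larger string bound can only convert GC/AMB to PM."""
    donor = _donor_with_diffs(parent60, [20, 28])
    db = PseudogeneDB.from_records([("dA", donor)])
    muts = [_sub(parent60, 20, donor[20]), _sub(parent60, 28, donor[28])]
    rank = {"PM": 0, "AMB": 1, "GC": 2}
    prev = None
    for L in (6, 10, 20, 40, 61):
        events = classify_clone(muts, parent60, db, ClassifierParams(min_length=L))
        cat = {m.pos: e.category for e in events for m in e.members}
        if prev is not None:
            assert all(rank[cat[p]] <= rank[prev[p]] for p in cat)
        prev = cat


def test_donor_order_does_not_change_result(parent60):
    d1 = _donor_with_diffs(parent60, [20, 35])
    d2 = _donor_with_diffs(parent60, [20, 35, 50])
    muts = [_sub(parent60, 20, d1[20]), _sub(parent60, 35, d1[35])]
    ev_a = classify_clone(muts, parent60, PseudogeneDB.from_records([("a", d1), ("b", d2)]))
    ev_b = classify_clone(muts, parent60, PseudogeneDB.from_records([("b", d2), ("a", d1)]))
    assert [(e.category, e.donor_id, e.tract) for e in ev_a] == [
        (e.category, e.donor_id, e.tract) for e in ev_b
    ]


def _random_instance(rng):
    """A small random instance: parent <= 200 nt, <= 5 co-linear donors, a
    clone mixing donor-copied tracts and random substitutions."""
    n = int(rng.integers(120, 201))
    parent = simulate_parent(n, seed=int(rng.integers(2**31)))
    n_donors = int(rng.integers(1, 6))
    db = simulate_pseudogene_db(
        parent,
        DonorSimParams(
            n_donors=n_donors,
            divergence=float(rng.uniform(0.02, 0.06)),
            min_inter_donor_diff=1,
            seed=int(rng.integers(2**31)),
        ),
    )
    donors = [(d.id, d.sequence) for d in db]
    subs: dict[int, str] = {}
    # copy a donor tract
    if rng.random() < 0.8:
        did, dseq = donors[int(rng.integers(len(donors)))]
        length = int(rng.integers(15, 60))
        start = int(rng.integers(0, n - length))
        for p in range(start, start + length):
            if dseq[p] != parent[p]:
                subs[p] = dseq[p]
    # some random substitutions
    for _ in range(int(rng.integers(0, 4))):
        p = int(rng.integers(n))
        if p in subs:
            continue
        alt = "ACGT"[int(rng.integers(4))]
        if alt != parent[p]:
            subs[p] = alt
    return parent, subs, db, donors


def test_classifier_matches_bruteforce_oracle_small_instances():
    """On random small instances the classifier reproduces the category map
    of a brute-force substring-enumeration oracle."""
    rng = np.random.default_rng(404)
    checked = 0
    for _ in range(60):
        parent, subs, db, donors = _random_instance(rng)
        if not subs:
            continue
        muts = [Mutation("substitution", p, parent[p], a) for p, a in sorted(subs.items())]
        events = classify_clone(muts, parent, db)
        got = {m.pos: e.category for e in events for m in e.members}
        expected = oracle_classify(parent, subs, donors)
        assert got == expected
        checked += 1
    assert checked >= 40
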