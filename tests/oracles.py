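"""Independent brute-force oracles used only by the test suite.

These deliberately take different computational routes from the package:
the donor-string oracle uses plain substring containment over enumerated
windows, the classifier oracle applies the PM/GC/Amb rule with direct string
operations on co-linear donors, and the Mann-Whitney oracle enumerates every
group labelling.
"""

from itertools import combinations


def donor_has_string(clone: str, pos: int, donor_seq: str, min_len: int = 10) -> bool:
    """Does any donor substring of length >= min_len match a clone window
    covering ``pos``?  Checking length == min_len suffices for existence."""
    lo = max(0, pos - min_len + 1)
    hi = min(pos, len(clone) - min_len)
    for cs in range(lo, hi + 1):
        if clone[cs : cs + min_len] in donor_seq:
            return True
    return False


def oracle_classify(parent: str, sub_positions: dict[int, str], donors: list[tuple[str, str]],
                    min_len: int = 10) -> dict[int, str]:
    """Category per mutated position by direct application of the rule.

    ``sub_positions`` maps parent position -> clone base (substitutions only;
    donors must be co-linear with the parent).  Returns pos -> PM|GC|AMB.
    """
    clone = list(parent)
    for p, alt in sub_positions.items():
        clone[p] = alt
    clone = "".join(clone)

    # the string search is containment anywhere in the donor (offset-free)
    anchored = {
        p: {did for did, dseq in donors if donor_has_string(clone, p, dseq, min_len)}
        for p in sub_positions
    }
    explained = {
        did: {p for p in sub_positions if dseq[p] == clone[p]} for did, dseq in donors
    }

    category: dict[int, str] = {}
    remaining = set(sub_positions)
    while True:
        candidates = []
        for did, exp in explained.items():
            live = exp & remaining
            if len(live) >= 2 and any(did in anchored[p] for p in live):
                candidates.append((-len(live), did, live))
        if not candidates:
            break
        candidates.sort(key=lambda c: c[:2])
        _, did, live = candidates[0]
        for p in live:
            category[p] = "GC"
        remaining -= live
    for p in remaining:
        category[p] = "AMB" if anchored[p] else "PM"
    return category


def expected_site_marginals(p3: dict, p5: dict, forbidden=("G", "C")):
    """Per-position (3'T, 5'T) symbol marginals implied by the generating
    process: draws are independent, marker-mimicking non-deletion pairs are
    re-drawn, and any pair containing a deletion removes the whole site."""
    z3 = sum(p3.values())
    z5 = sum(p5.values())
    marg3: dict[str, float] = {}
    marg5: dict[str, float] = {}
    total = 0.0
    for b3, w3 in p3.items():
        for b5, w5 in p5.items():
            w = (w3 / z3) * (w5 / z5)
            if "del" not in (b3, b5) and (b3, b5) == forbidden:
                continue
            total += w
            if "del" in (b3, b5):
                marg3["del"] = marg3.get("del", 0.0) + w
                marg5["del"] = marg5.get("del", 0.0) + w
            else:
                marg3[b3] = marg3.get(b3, 0.0) + w
                marg5[b5] = marg5.get(b5, 0.0) + w
    return (
        {k: v / total for k, v in marg3.items()},
        {k: v / total for k, v in marg5.items()},
    )


def perm_mann_whitney(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every labelling.

    Two-sided p is twice the smaller tail probability, capped at 1.
    Assumes no ties.
    """
    pooled = list(a) + list(b)
    n, na = len(pooled), len(a)

    def u_of(sel):
        asel = [pooled[i] for i in sel]
        bsel = [pooled[i] for i in range(n) if i not in sel]
        return sum(x > y for x in asel for y in bsel)

    obs = sum(x > y for x in a for y in b)
    us = [u_of(set(c)) for c in combinations(range(n), na)]
    le = sum(u <= obs for u in us) / len(us)
    ge = sum(u >= obs for u in us) / len(us)
    return obs, min(1.0, 2.0 * min(le, ge))
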