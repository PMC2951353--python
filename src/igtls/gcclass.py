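"""Classification of called V-lambda mutations into PM / GC / Amb events.

Each clone's mutations are partitioned into diversification events by the
donor-string rule used for Ig gene-conversion analysis in DT40:

* a mutation for which no pseudogene donor contains a contiguous exact string
  of length >= ``min_length`` (default 10 nt, i.e. ">9 bp") matching the clone
  across the mutated position is a non-templated point mutation (PM);
* if such a donor string exists and at least one further mutation of the same
  clone is explained by that donor (the donor base equals the clone base at
  the homologous position), all mutations explained by the donor form a
  single long-tract gene conversion event (GC);
* a mutation with a qualifying donor string but no co-explained further
  mutation is ambiguous (Amb): it could be templated or not.

The donor-string search is offset-free (the matching string may sit anywhere
in the donor), while "explained by the same donor" is read through positional
homology: donors are pre-aligned to the parent once with the same dynamic
program used for mutation calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import DataError
from .mutcall import AlignmentParams, Mutation, align_global
from .seq_io import PseudogeneDB, reverse_complement


@dataclass(frozen=True)
class ClassifierParams:
    """Parameters of the donor-string rule.

    ``min_length`` is the minimum contiguous exact clone-donor match (in
    clone nucleotides) that must cover the mutated position; the default 10
    encodes the ">9 bp" criterion.
    """

    min_length: int = 10
    search_revcomp: bool = False
    tie_break: str = "longest-then-lexicographic-id"

    def __post_init__(self) -> None:
        if self.min_length < 2:
            raise DataError("classifier: min_length must be >= 2")


@dataclass(frozen=True)
class DonorMatch:
    donor_id: str
    interval: tuple[int, int]  # parent coordinates covered by the match, half-open
    length: int  # matched clone nucleotides
    donor_interval: tuple[int, int]
    mutation_index: int
    reverse: bool = False


@dataclass(frozen=True)
class EventCall:
    category: str  # PM | GC | AMB
    members: tuple[Mutation, ...]
    donor_id: str | None = None
    tract: tuple[int, int] | None = None
    qualifying_donors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category in ("PM", "AMB") and len(self.members) != 1:
            raise DataError(f"{self.category} event must contain exactly one mutation")
        if self.category == "GC" and len(self.members) < 2:
            raise DataError("GC event must contain at least two mutations")


# ---------------------------------------------------------------------------
# Parent-coordinate profiles
# ---------------------------------------------------------------------------


class SeqProfile:
    """A sequence laid out on parent coordinates.

    ``base[i]`` is the sequence's character at parent position i ('-' if
    deleted); ``ins[i]`` is the string inserted before parent position i.
    Slots interleave insertions and bases (2i = ins[i], 2i+1 = base[i]) so a
    contiguous equality run between two profiles is well defined even across
    indels.
    """

    def __init__(self, base: list[str], ins: list[str]):
        self.base = base
        self.ins = ins
        self.n = len(base)

    @classmethod
    def from_mutations(cls, parent: str, mutations: Sequence[Mutation]) -> "SeqProfile":
        base = list(parent)
        ins = [""] * (len(parent) + 1)
        for m in mutations:
            if m.kind == "substitution":
                base[m.pos] = m.alt
            elif m.kind == "deletion":
                for k in range(m.pos, m.pos + len(m.ref)):
                    base[k] = "-"
            else:
                ins[m.pos] += m.alt
        return cls(base, ins)

    @classmethod
    def from_alignment(cls, parent: str, seq: str, params: AlignmentParams | None = None) -> "SeqProfile":
        aln = align_global(parent, seq, params)
        base = []
        ins = [""] * (len(parent) + 1)
        p = 0
        for a, b in zip(aln.parent_aligned, aln.clone_aligned):
            if a == "-":
                ins[p] += b
            else:
                base.append(b)
                p += 1
        return cls(base, ins)

    def slot(self, which: str, i: int) -> object:
        return self.ins[i] if which == "ins" else self.base[i]

    def sequence(self) -> str:
        parts = []
        for i in range(self.n):
            parts.append(self.ins[i])
            if self.base[i] != "-":
                parts.append(self.base[i])
        parts.append(self.ins[self.n])
        return "".join(parts)

    def clone_index_map(self) -> list[int]:
        """Parent position (insertion slot index for inserted bases) of every
        character of :meth:`sequence`."""
        out: list[int] = []
        for i in range(self.n):
            out.extend([i] * len(self.ins[i]))
            if self.base[i] != "-":
                out.append(i)
        out.extend([self.n] * len(self.ins[self.n]))
        return out


def _mutation_slots(m: Mutation) -> list[tuple[str, int]]:
    if m.kind == "substitution":
        return [("base", m.pos)]
    if m.kind == "deletion":
        return [("base", k) for k in range(m.pos, m.pos + len(m.ref))]
    return [("ins", m.pos)]


def _profiles_agree(a: SeqProfile, b: SeqProfile, slots: Sequence[tuple[str, int]]) -> bool:
    return all(a.slot(w, i) == b.slot(w, i) for w, i in slots)


# ---------------------------------------------------------------------------
# Donor-string search
# ---------------------------------------------------------------------------


def _clone_anchor(clone_profile: SeqProfile, mutation: Mutation) -> tuple[int, int] | None:
    """Clone-string interval that a qualifying donor string must cover.

    Substitutions and insertions must have all their altered bases inside the
    match; a deletion has no clone bases, so the match must straddle the
    deletion junction (the two clone bases flanking it).
    """
    index_map = clone_profile.clone_index_map()
    seq_len = len(index_map)
    if mutation.kind == "substitution":
        ci = _clone_index_of_base(clone_profile, mutation.pos)
        return (ci, ci + 1)
    if mutation.kind == "insertion":
        start = _clone_index_of_ins(clone_profile, mutation.pos)
        return (start, start + len(clone_profile.ins[mutation.pos]))
    # deletion: junction between the clone bases flanking the deleted tract
    j = _clone_index_of_junction(clone_profile, mutation.pos)
    if j == 0 or j >= seq_len:
        return None  # deletion at a sequence edge: no straddling string exists
    return (j - 1, j + 1)


def _clone_index_of_base(profile: SeqProfile, pos: int) -> int:
    ci = 0
    for i in range(pos):
        ci += len(profile.ins[i])
        if profile.base[i] != "-":
            ci += 1
    ci += len(profile.ins[pos])
    return ci


def _clone_index_of_ins(profile: SeqProfile, pos: int) -> int:
    ci = 0
    for i in range(pos):
        ci += len(profile.ins[i])
        if profile.base[i] != "-":
            ci += 1
    return ci


def _clone_index_of_junction(profile: SeqProfile, pos: int) -> int:
    """Clone index where a deletion starting at parent position ``pos`` sits."""
    return _clone_index_of_base(profile, pos)


def find_donor_matches(
    mutation: Mutation,
    clone_profile: SeqProfile,
    db: PseudogeneDB,
    params: ClassifierParams | None = None,
    mutation_index: int = 0,
) -> list[DonorMatch]:
    """All per-donor maximal exact matches covering ``mutation``.

    For each donor the longest contiguous exact match between the clone and
    any donor substring that covers the mutated position is returned if it
    reaches ``min_length``; results are sorted by length (descending), then
    donor id, so the outcome does not depend on donor file order.
    """
    params = params or ClassifierParams()
    clone_seq = clone_profile.sequence()
    index_map = clone_profile.clone_index_map()
    anchor = _clone_anchor(clone_profile, mutation)
    if anchor is None:
        return []
    a, b = anchor
    matches: list[DonorMatch] = []
    for donor in db:
        candidates = [(donor.sequence, False)]
        if params.search_revcomp:
            candidates.append((reverse_complement(donor.sequence), True))
        best: tuple[int, int, int, bool] | None = None  # (length, clone_start, donor_start, rev)
        for dseq, rev in candidates:
            for t0 in range(len(dseq)):
                # align donor position t0 with clone position a and extend
                s, t = a, t0
                while s > 0 and t > 0 and clone_seq[s - 1] == dseq[t - 1]:
                    s -= 1
                    t -= 1
                e, u = a, t0
                while e < len(clone_seq) and u < len(dseq) and clone_seq[e] == dseq[u]:
                    e += 1
                    u += 1
                if e < b:  # match does not cover the full mutated interval
                    continue
                length = e - s
                if length >= params.min_length and (best is None or length > best[0]):
                    best = (length, s, t, rev)
        if best is not None:
            length, s, t, rev = best
            covered = index_map[s : s + length]
            interval = (min(covered), max(covered) + 1) if covered else (mutation.pos, mutation.pos)
            matches.append(
                DonorMatch(donor.id, interval, length, (t, t + length), mutation_index, rev)
            )
    matches.sort(key=lambda m: (-m.length, m.donor_id))
    return matches


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------


def _donor_profiles(parent: str, db: PseudogeneDB, params: ClassifierParams) -> dict[str, SeqProfile]:
    profiles: dict[str, SeqProfile] = {}
    for donor in db:
        profiles[donor.id] = SeqProfile.from_alignment(parent, donor.sequence)
        if params.search_revcomp:
            profiles[donor.id + "/rc"] = SeqProfile.from_alignment(
                parent, reverse_complement(donor.sequence)
            )
    return profiles


def _extend_tract(
    interval: tuple[int, int], clone: SeqProfile, donor: SeqProfile, parent: str
) -> tuple[int, int]:
    lo, hi = interval
    while lo > 0 and clone.base[lo - 1] == donor.base[lo - 1] == parent[lo - 1] and not clone.ins[lo] and not donor.ins[lo]:
        lo -= 1
    while (
        hi < len(parent)
        and clone.base[hi] == donor.base[hi] == parent[hi]
        and not clone.ins[hi]
        and not donor.ins[hi]
    ):
        hi += 1
    return (lo, hi)


def classify_clone(
    mutations: Sequence[Mutation],
    parent: str,
    db: PseudogeneDB,
    params: ClassifierParams | None = None,
) -> list[EventCall]:
    """Partition one clone's mutations into PM / GC / Amb events.

    Every mutation appears in exactly one event.  When several donors could
    seed a GC event the tie-break is: most mutations explained, then longest
    total matched length, then lexicographic donor id.
    """
    params = params or ClassifierParams()
    mutations = list(mutations)
    for m in mutations:
        if not (0 <= m.pos <= len(parent)) or (m.kind != "insertion" and m.end > len(parent)):
            raise DataError(f"mutation {m} outside parent")
    if not mutations:
        return []

    clone_profile = SeqProfile.from_mutations(parent, mutations)
    donor_profiles = _donor_profiles(parent, db, params)

    matches: dict[int, list[DonorMatch]] = {
        i: find_donor_matches(m, clone_profile, db, params, mutation_index=i)
        for i, m in enumerate(mutations)
    }
    # donor id -> set of mutation indices it explains (positional homology)
    explained: dict[str, set[int]] = {}
    for did, dprof in donor_profiles.items():
        exp = {
            i
            for i, m in enumerate(mutations)
            if _profiles_agree(clone_profile, dprof, _mutation_slots(m))
        }
        if exp:
            explained[did] = exp

    def donor_key(did: str) -> str:
        return did[:-3] if did.endswith("/rc") else did

    events: list[EventCall] = []
    remaining = set(range(len(mutations)))
    while True:
        candidates = []
        for did, exp in explained.items():
            live = exp & remaining
            if len(live) < 2:
                continue
            anchored = [
                mt
                for i in live
                for mt in matches[i]
                if mt.donor_id == donor_key(did) and mt.reverse == did.endswith("/rc")
            ]
            if not anchored:
                continue
            total_len = sum(mt.length for mt in anchored)
            candidates.append((-len(live), -total_len, donor_key(did), did, live))
        if not candidates:
            break
        candidates.sort(key=lambda c: c[:3])
        _, _, _, did, live = candidates[0]
        members = tuple(mutations[i] for i in sorted(live))
        lo = min(m.pos for m in members)
        hi = max(m.end if m.kind != "insertion" else min(m.pos + 1, len(parent)) for m in members)
        tract = _extend_tract((lo, hi), clone_profile, donor_profiles[did], parent)
        events.append(
            EventCall(
                "GC",
                members,
                donor_id=donor_key(did),
                tract=tract,
                qualifying_donors=tuple(
                    sorted({donor_key(d) for d, e in explained.items() if len(e & remaining) >= 2})
                ),
            )
        )
        remaining -= live

    for i in sorted(remaining):
        mlist = matches[i]
        if mlist:
            events.append(
                EventCall(
                    "AMB",
                    (mutations[i],),
                    donor_id=mlist[0].donor_id,
                    qualifying_donors=tuple(sorted({mt.donor_id for mt in mlist})),
                )
            )
        else:
            events.append(EventCall("PM", (mutations[i],)))

    events.sort(key=lambda e: min(m.pos for m in e.members))
    total = sum(len(e.members) for e in events)
    if total != len(mutations):
        raise DataError("event partition does not cover all mutations")  # pragma: no cover
    return events


def classify_clone_set(
    parent: str,
    clone_calls,
    db: PseudogeneDB,
    params: ClassifierParams | None = None,
) -> dict[str, list[EventCall]]:
    """Classify every non-excluded clone of a called clone set."""
    out: dict[str, list[EventCall]] = {}
    for call in clone_calls:
        if call.excluded:
            continue
        out[call.clone_id] = classify_clone(call.mutations, parent, db, params)
    return out
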