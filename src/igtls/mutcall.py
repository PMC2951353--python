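"""Global alignment of clone sequences to the parental locus and mutation calling.

Each sequenced clone is aligned end-to-end to the parental V-lambda segment
with an affine-gap Needleman-Wunsch (Gotoh) dynamic program, and the alignment
is reduced to an ordered list of :class:`Mutation` records (substitutions and
left-normalized indels) in parent coordinates.  Default scores favour isolated
substitutions over compensating indels, which is the right prior for
near-identical V segments.

The DP uses a fixed tie-break (diagonal over up over down-column gap states)
so that equal-scoring optima always yield the same canonical alignment, and
indels are left-normalized afterwards so donor-tract searches downstream are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

NEG_INF = float("-inf")
_EPS = 1e-9


@dataclass(frozen=True)
class AlignmentParams:
    """Scores for the affine-gap global alignment.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend`` (the opening
    position is charged ``gap_open``).
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.match > 0 >= self.mismatch and 0 >= self.gap_open and 0 >= self.gap_extend):
            raise DataError("alignment params: require penalties <= 0 < match")


@dataclass(frozen=True)
class Mutation:
    """A single called change of the clone relative to the parent.

    ``pos`` is 0-based on the parent.  Substitutions have one-base ref/alt;
    deletions have empty alt (ref = deleted parent bases starting at ``pos``);
    insertions have empty ref (alt inserted before parent position ``pos``).
    """

    kind: str  # substitution | insertion | deletion
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if not (len(self.ref) == 1 and len(self.alt) == 1 and self.ref != self.alt):
                raise DataError(f"bad substitution {self!r}")
        elif self.kind == "insertion":
            if self.ref != "" or not self.alt:
                raise DataError(f"bad insertion {self!r}")
        elif self.kind == "deletion":
            if self.alt != "" or not self.ref:
                raise DataError(f"bad deletion {self!r}")
        else:
            raise DataError(f"unknown mutation kind {self.kind!r}")

    @property
    def end(self) -> int:
        """End of the footprint on the parent (half-open)."""
        return self.pos + len(self.ref) if self.kind != "insertion" else self.pos


@dataclass
class Alignment:
    parent_aligned: str
    clone_aligned: str
    score: float
    params: AlignmentParams = field(default_factory=AlignmentParams)


def align_global(parent: str, clone: str, params: AlignmentParams | None = None) -> Alignment:
    """Optimal global alignment of ``clone`` against ``parent``.

    Deterministic: among equal-scoring optima the traceback prefers the
    diagonal (match/mismatch) state, then the vertical gap state (gap in the
    clone), then the horizontal one, giving a unique canonical alignment.
    """
    if not parent or not clone:
        raise DataError("align_global: sequences must be non-empty")
    params = params or AlignmentParams()
    n, m = len(parent), len(clone)
    go, ge = params.gap_open, params.gap_extend

    p_arr = np.frombuffer(parent.encode(), dtype=np.uint8)
    c_arr = np.frombuffer(clone.encode(), dtype=np.uint8)
    sub = np.where(p_arr[:, None] == c_arr[None, :], params.match, params.mismatch)

    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # parent base against clone gap ("up")
    Y = np.full((n + 1, m + 1), NEG_INF)  # clone base against parent gap ("left")
    M[0, 0] = 0.0
    Y[0, 1:] = go + ge * np.arange(m)
    cols = ge * np.arange(m + 1)

    for i in range(1, n + 1):
        M[i, 1:] = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1]) + sub[i - 1]
        X[i] = np.maximum(np.maximum(M[i - 1] + go, X[i - 1] + ge), Y[i - 1] + go)
        # Y row: running-max recurrence Y[j] = max(A[j-1]+go, Y[j-1]+ge)
        A = np.maximum(M[i], X[i])
        cand = np.full(m + 1, NEG_INF)
        cand[1:] = A[:-1] + go - cols[1:]
        Y[i] = np.maximum.accumulate(cand) + cols

    # traceback, preferring M > X > Y on ties
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: ({"M": M, "X": X, "Y": Y}[s][i, j], s == "M", s == "X"))
    score = {"M": M, "X": X, "Y": Y}[state][i, j]
    pa: list[str] = []
    ca: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            pa.append(parent[i - 1])
            ca.append(clone[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
        elif state == "X":
            pa.append(parent[i - 1])
            ca.append("-")
            here = X[i, j]
            i -= 1
            if abs(M[i, j] + go - here) < _EPS:
                state = "M"
            elif abs(X[i, j] + ge - here) < _EPS:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
            continue
        else:  # Y
            pa.append("-")
            ca.append(clone[j - 1])
            here = Y[i, j]
            j -= 1
            if abs(M[i, j] + go - here) < _EPS:
                state = "M"
            elif abs(X[i, j] + go - here) < _EPS:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
            continue
        if i == 0 and j == 0:
            break
        for cand_state in ("M", "X", "Y"):
            if abs({"M": M, "X": X, "Y": Y}[cand_state][i, j] - target) < _EPS:
                state = cand_state
                break
    return Alignment("".join(reversed(pa)), "".join(reversed(ca)), float(score), params)


def call_mutations(alignment: Alignment, parent: str | None = None) -> list[Mutation]:
    """Reduce a pairwise alignment to an ordered list of mutations.

    Adjacent gap columns merge into one indel; substitution columns containing
    N in either sequence are skipped as uncallable; indels are left-normalized
    against the parent so equivalent placements always report the same
    coordinate.
    """
    pa, ca = alignment.parent_aligned, alignment.clone_aligned
    if len(pa) != len(ca):
        raise DataError("alignment rows differ in length")
    muts: list[Mutation] = []
    p = 0  # parent coordinate
    k = 0
    L = len(pa)
    while k < L:
        a, b = pa[k], ca[k]
        if a == "-" and b == "-":
            raise DataError("alignment contains a gap-against-gap column")
        if a != "-" and b != "-":
            if a != b and a != "N" and b != "N":
                muts.append(Mutation("substitution", p, a, b))
            p += 1
            k += 1
        elif b == "-":  # deletion in clone
            start = p
            run = []
            while k < L and pa[k] != "-" and ca[k] == "-":
                run.append(pa[k])
                p += 1
                k += 1
            muts.append(Mutation("deletion", start, "".join(run), ""))
        else:  # insertion relative to parent
            run = []
            while k < L and pa[k] == "-" and ca[k] != "-":
                run.append(ca[k])
                k += 1
            muts.append(Mutation("insertion", p, "", "".join(run)))
    parent_seq = parent if parent is not None else pa.replace("-", "")
    return normalize_left(muts, parent_seq)


def normalize_left(mutations: list[Mutation], parent: str) -> list[Mutation]:
    """Shift each indel to its leftmost equivalent placement on the parent.

    Shifting stops at the footprint of the preceding mutation so calls never
    reorder or collide.
    """
    out: list[Mutation] = []
    floor = 0
    for mut in mutations:
        if mut.kind == "deletion":
            p, r = mut.pos, mut.ref
            while p > floor and parent[p - 1] == r[-1]:
                p -= 1
                r = parent[p] + r[:-1]
            mut = Mutation("deletion", p, r, "")
        elif mut.kind == "insertion":
            p, s = mut.pos, mut.alt
            while p > floor and p <= len(parent) and s[-1] == parent[p - 1]:
                p -= 1
                s = parent[p] + s[:-1]
            mut = Mutation("insertion", p, "", s)
        out.append(mut)
        floor = max(floor, mut.end if mut.kind != "insertion" else mut.pos)
        if mut.kind == "substitution":
            floor = max(floor, mut.pos + 1)
    return out


def reconstruct_clone(parent: str, mutations: list[Mutation]) -> str:
    """Apply mutations to the parent; inverse of calling (round-trip identity)."""
    ins: dict[int, list[str]] = {}
    dels: dict[int, str] = {}
    subs: dict[int, str] = {}
    for mut in mutations:
        if mut.kind == "insertion":
            ins.setdefault(mut.pos, []).append(mut.alt)
        elif mut.kind == "deletion":
            if parent[mut.pos : mut.pos + len(mut.ref)] != mut.ref:
                raise DataError(f"deletion ref mismatch at {mut.pos}")
            dels[mut.pos] = mut.ref
        else:
            if parent[mut.pos] != mut.ref:
                raise DataError(f"substitution ref mismatch at {mut.pos}")
            subs[mut.pos] = mut.alt
    out: list[str] = []
    i = 0
    n = len(parent)
    while i <= n:
        out.extend(ins.get(i, ()))
        if i == n:
            break
        if i in dels:
            i += len(dels[i])
            continue
        out.append(subs.get(i, parent[i]))
        i += 1
    return "".join(out)


@dataclass
class CloneCall:
    clone_id: str
    mutations: list[Mutation]
    divergence: float
    excluded: bool


def call_clone_set(
    parent: str,
    clones: list[tuple[str, str]],
    params: AlignmentParams | None = None,
    max_divergence: float = 0.10,
) -> list[CloneCall]:
    """Align and call every clone; flag clones above the divergence threshold.

    Clones differing from the parent at more than ``max_divergence`` of
    positions are likely mis-tracked sequences and are flagged ``excluded``
    (their calls are still reported for audit).
    """
    calls = []
    for cid, seq in clones:
        aln = align_global(parent, seq, params)
        muts = call_mutations(aln, parent)
        changed = sum(len(m.ref) if m.kind != "insertion" else len(m.alt) for m in muts)
        div = changed / len(parent)
        calls.append(CloneCall(cid, muts, div, div > max_divergence))
    return calls
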