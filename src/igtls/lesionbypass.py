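"""Classification of replicated lesion-plasmid products (pQTs / pQTo style).

The constructs carry a T-T (6-4) photoproduct on each strand.  In the
staggered arrangement the two lesions are 28 nt apart and each sits opposite
a GpC marker mismatch on the other strand, so the sequence of a replicated
copy reveals the bypass route: a copy made by error-free template switching
reads the marker (GC) at both lesion sites, while translesion synthesis (TLS)
past a lesion writes the inserted bases — most often AA opposite the T-T —
or a deletion at that site.  In the opposing arrangement both strands are
damaged at the same position, so replicated copies can only arise by TLS
(full-length site) or lesion-skipping deletion; template switching is
impossible by construction.

All product reads are canonicalized to the reference (marker-form) top-strand
orientation before classification, so calls are invariant to the sequencing
direction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError
from .mutcall import AlignmentParams, align_global
from .seq_io import reverse_complement

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}

POSITIONS = ("3pT", "5pT", "plus1", "plus2")
SYMBOLS = ("A", "C", "G", "T", "del")

TLS_MODES = frozenset({"TLS_top", "TLS_bottom", "TLS"})


@dataclass(frozen=True)
class LesionPlasmidArchitecture:
    """Geometry of a site-specific lesion construct.

    ``reference`` is the marker-form top strand: the sequence a perfectly
    error-free (template-switch) replication product reads.  ``top_site`` is
    the half-open interval of the T-T lesion on the top strand (the bottom
    strand carries the GC marker opposite it); ``bottom_site`` is the
    interval, in top-strand coordinates, of the bottom-strand lesion.  In the
    staggered arrangement the two sites are disjoint and separated by
    ``spacer`` intervening nucleotides (28 in the pQTs construct); in the
    opposing arrangement they coincide.
    """

    id: str
    arrangement: str  # staggered | opposing
    reference: str
    top_site: tuple[int, int]
    bottom_site: tuple[int, int]
    marker: str = "GC"
    accurate: str = "AA"
    spacer: int | None = None

    def __post_init__(self) -> None:
        if self.arrangement not in ("staggered", "opposing"):
            raise DataError(f"unknown arrangement {self.arrangement!r}")
        for name, (s, e) in (("top_site", self.top_site), ("bottom_site", self.bottom_site)):
            if not (0 <= s < e <= len(self.reference)):
                raise DataError(f"{name} {s, e} outside reference of length {len(self.reference)}")
            if e - s != 2:
                raise DataError(f"{name} must be a dinucleotide interval")
        if len(self.marker) != 2 or len(self.accurate) != 2:
            raise DataError("marker and accurate-insertion strings must be dinucleotides")
        if self.arrangement == "staggered":
            if self.top_site[1] > self.bottom_site[0]:
                raise DataError("staggered arrangement requires disjoint lesion sites (top before bottom)")
            gap = self.bottom_site[0] - self.top_site[1]
            if self.spacer is not None and gap != self.spacer:
                raise DataError(f"declared spacer {self.spacer} != inter-lesion distance {gap}")
        else:
            if self.top_site != self.bottom_site:
                raise DataError("opposing arrangement requires coinciding lesion sites")

    @property
    def inter_lesion_distance(self) -> int:
        return self.bottom_site[0] - self.top_site[1]


@dataclass(frozen=True)
class BypassCall:
    """One replicated product's bypass mode and per-position insertions.

    ``bases`` maps the incorporation positions (3' T and 5' T of the lesion,
    then the next two template bases) to the nucleotide inserted opposite
    them, or ``del``.  ``deletion_length`` is the longest deletion run
    touching the called lesion site (0 if none).
    """

    read_id: str
    mode: str  # TLS_top | TLS_bottom | TLS | error_free | deletion | other | unclassifiable
    bases: dict = field(default_factory=dict)
    deletion_length: int = 0
    accurate: bool = False
    identity: float = 1.0


def _product_profile(product: str, arch: LesionPlasmidArchitecture, params: AlignmentParams | None):
    """Canonicalize orientation and lay the product onto reference coordinates."""
    fwd = align_global(arch.reference, product, params)
    rev = align_global(arch.reference, reverse_complement(product), params)
    aln = fwd if fwd.score >= rev.score else rev
    per_pos: list[str] = []
    p = 0
    for a, b in zip(aln.parent_aligned, aln.clone_aligned):
        if a == "-":
            continue  # insertions do not shift reference coordinates
        per_pos.append(b)
        p += 1
    return per_pos


def _lesion_region(arch: LesionPlasmidArchitecture, pad: int = 4) -> tuple[int, int]:
    lo = min(arch.top_site[0], arch.bottom_site[0]) - pad
    hi = max(arch.top_site[1], arch.bottom_site[1]) + pad
    return max(lo, 0), min(hi, len(arch.reference))


def _identity_outside(per_pos: list[str], arch: LesionPlasmidArchitecture) -> float:
    lo, hi = _lesion_region(arch)
    outside = [(r, q) for i, (r, q) in enumerate(zip(arch.reference, per_pos)) if not lo <= i < hi]
    if not outside:
        return 1.0
    return sum(r == q for r, q in outside) / len(outside)


def _deletion_run_over(per_pos: list[str], site: tuple[int, int]) -> int:
    """Length of the longest '-' run overlapping the site interval."""
    best = 0
    i = 0
    n = len(per_pos)
    while i < n:
        if per_pos[i] == "-":
            j = i
            while j < n and per_pos[j] == "-":
                j += 1
            if i < site[1] and j > site[0]:
                best = max(best, j - i)
            i = j
        else:
            i += 1
    return best


def _site_read(per_pos: list[str], site: tuple[int, int]) -> str:
    return "".join(per_pos[site[0] : site[1]])


def _base_or_del(ch: str) -> str:
    return "del" if ch == "-" else ch


def _top_strand_positions(per_pos: list[str], site: tuple[int, int]) -> dict:
    """Insertions opposite a top-strand lesion, read off the canonicalized
    product.  The nascent strand is the bottom strand, so inserted bases are
    the complements of the product's top-strand bases, and synthesis runs
    right-to-left in top coordinates: 3' T at site end, +1/+2 to the left."""
    t = site[0]

    def comp_at(i: int) -> str:
        if not 0 <= i < len(per_pos):
            return "del"
        return _base_or_del(_COMP.get(per_pos[i], "N"))

    return {
        "3pT": comp_at(t + 1),
        "5pT": comp_at(t),
        "plus1": comp_at(t - 1),
        "plus2": comp_at(t - 2),
    }


def _bottom_strand_positions(per_pos: list[str], site: tuple[int, int]) -> dict:
    """Insertions opposite a bottom-strand lesion: the nascent strand is the
    top strand, so inserted bases appear directly, with synthesis running
    left-to-right: 3' T at site start, +1/+2 to the right."""
    s = site[0]

    def at(i: int) -> str:
        if not 0 <= i < len(per_pos):
            return "del"
        return _base_or_del(per_pos[i])

    return {"3pT": at(s), "5pT": at(s + 1), "plus1": at(s + 2), "plus2": at(s + 3)}


def classify_pqts(
    read_id: str,
    product: str,
    arch: LesionPlasmidArchitecture,
    params: AlignmentParams | None = None,
    min_identity: float = 0.90,
) -> BypassCall:
    """Classify one replicated product of a staggered-arrangement construct.

    Decision table on the two lesion-site dinucleotides as read from the
    product: (marker, marker) -> error_free; exactly one non-marker or
    deleted site -> TLS on that site's strand; both non-marker -> other
    (flagged for review rather than forced into a mode).
    """
    if arch.arrangement != "staggered":
        raise DataError("classify_pqts requires a staggered architecture")
    per_pos = _product_profile(product, arch, params)
    identity = _identity_outside(per_pos, arch)
    if identity < min_identity:
        return BypassCall(read_id, "unclassifiable", identity=identity)

    top_del = _deletion_run_over(per_pos, arch.top_site)
    bottom_del = _deletion_run_over(per_pos, arch.bottom_site)
    top_is_marker = top_del == 0 and _site_read(per_pos, arch.top_site) == arch.marker
    bottom_is_marker = bottom_del == 0 and _site_read(per_pos, arch.bottom_site) == arch.marker

    if top_is_marker and bottom_is_marker:
        return BypassCall(read_id, "error_free", identity=identity)
    if not top_is_marker and not bottom_is_marker:
        return BypassCall(
            read_id, "other", deletion_length=max(top_del, bottom_del), identity=identity
        )
    if not top_is_marker:
        bases = _top_strand_positions(per_pos, arch.top_site)
        dlen = top_del
        mode = "TLS_top"
    else:
        bases = _bottom_strand_positions(per_pos, arch.bottom_site)
        dlen = bottom_del
        mode = "TLS_bottom"
    accurate = bases["3pT"] + bases["5pT"] == arch.accurate[0] + arch.accurate[1] and dlen == 0
    return BypassCall(read_id, mode, bases=bases, deletion_length=dlen, accurate=accurate, identity=identity)


def classify_pqto(
    read_id: str,
    product: str,
    arch: LesionPlasmidArchitecture,
    params: AlignmentParams | None = None,
    min_identity: float = 0.90,
    min_deletion: int = 2,
) -> BypassCall:
    """Classify one replicated product of an opposing-arrangement construct.

    A full-length site (or one with a sub-threshold deletion) is TLS; a
    deletion of ``min_deletion`` or more nucleotides covering the site is the
    deletion-associated class.  Error-free bypass cannot occur because both
    templates are damaged at the same position.
    """
    if arch.arrangement != "opposing":
        raise DataError("classify_pqto requires an opposing architecture")
    per_pos = _product_profile(product, arch, params)
    identity = _identity_outside(per_pos, arch)
    if identity < min_identity:
        return BypassCall(read_id, "unclassifiable", identity=identity)
    site = arch.top_site
    dlen = _deletion_run_over(per_pos, site)
    if dlen >= min_deletion:
        return BypassCall(read_id, "deletion", deletion_length=dlen, identity=identity)
    # the observed strand cannot be determined; positions follow the
    # top-strand lesion convention
    bases = _top_strand_positions(per_pos, site)
    site_read = _site_read(per_pos, site)
    accurate = dlen == 0 and site_read == arch.reference[site[0] : site[1]]
    return BypassCall(read_id, "TLS", bases=bases, deletion_length=dlen, accurate=accurate, identity=identity)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeFractions:
    percent_tls: float
    percent_error_free: float
    percent_other: float
    n_classifiable: int
    n_unclassifiable: int


def classifiable(calls: list[BypassCall]) -> list[BypassCall]:
    return [c for c in calls if c.mode != "unclassifiable"]


def tls_fraction(calls: list[BypassCall]) -> ModeFractions:
    """TLS vs error-free (vs other) as percentages of classifiable reads.

    Deletion-associated products count as TLS: every bypass of the damaged
    template that is not a template switch is a TLS outcome.
    """
    ok = classifiable(calls)
    if not ok:
        raise DataError("tls_fraction requires at least one classifiable call")
    n = len(ok)
    n_tls = sum(c.mode in TLS_MODES or c.mode == "deletion" for c in ok)
    n_ef = sum(c.mode == "error_free" for c in ok)
    n_other = n - n_tls - n_ef
    return ModeFractions(
        100.0 * n_tls / n, 100.0 * n_ef / n, 100.0 * n_other / n, n, len(calls) - n
    )


def mode_fractions(calls: list[BypassCall]) -> dict[str, float]:
    ok = classifiable(calls)
    if not ok:
        raise DataError("mode_fractions requires at least one classifiable call")
    counts = Counter(c.mode for c in ok)
    return {mode: 100.0 * cnt / len(ok) for mode, cnt in sorted(counts.items())}


def deletion_fraction(calls: list[BypassCall]) -> float:
    """Percentage of classifiable reads in the deletion-associated class
    (two-or-more-nucleotide deletions covering the opposing-arrangement site)."""
    ok = classifiable(calls)
    if not ok:
        raise DataError("deletion_fraction requires at least one classifiable call")
    return 100.0 * sum(c.mode == "deletion" for c in ok) / len(ok)


@dataclass
class IncorporationProfile:
    """Per-position nucleotide/deletion frequencies over TLS products."""

    frequencies: pd.DataFrame  # index POSITIONS, columns SYMBOLS
    n_calls: int

    def frequency(self, position: str, symbol: str) -> float:
        return float(self.frequencies.loc[position, symbol])


def incorporation_profile(calls: list[BypassCall]) -> IncorporationProfile:
    """Frequencies of each inserted base (or deletion) at the four
    incorporation positions, over TLS calls only; error-free and other reads
    are excluded."""
    tls_calls = [c for c in calls if c.mode in TLS_MODES and c.bases]
    if not tls_calls:
        raise DataError("incorporation_profile requires at least one TLS call")
    counts = pd.DataFrame(0.0, index=list(POSITIONS), columns=list(SYMBOLS))
    for c in tls_calls:
        for pos in POSITIONS:
            sym = c.bases.get(pos, "del")
            if sym not in SYMBOLS:  # an N from sequencing: skipped
                continue
            counts.loc[pos, sym] += 1.0
    freqs = counts.div(counts.sum(axis=1), axis=0)
    return IncorporationProfile(freqs, len(tls_calls))


def classify_products(
    reads: list[tuple[str, str]],
    arch: LesionPlasmidArchitecture,
    params: AlignmentParams | None = None,
    min_identity: float = 0.90,
) -> list[BypassCall]:
    """Route every read through the classifier matching the architecture."""
    fn = classify_pqts if arch.arrangement == "staggered" else classify_pqto
    return [fn(rid, seq, arch, params, min_identity) for rid, seq in reads]
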