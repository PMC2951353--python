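"""Synthetic data with known truth for every pipeline stage.

The study's raw Sanger reads and per-cell counts are not deposited, so this
module generates stand-ins whose generating truth is recorded alongside:

* a pseudogene donor array diverged from a parental V segment
  (substitution-only, co-linear donors, pairwise distinct);
* AID-driven clone sets carrying gene-conversion tracts copied from donors
  and non-templated point mutations with a G/C-biased position model and a
  configurable substitution spectrum;
* replicated lesion-plasmid product mixtures (TLS on either strand,
  error-free template switches, deletion products) with per-position
  incorporation preferences.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError
from .lesionbypass import LesionPlasmidArchitecture
from .seq_io import CloneSet, ProductSet, PseudogeneDB, PseudogeneDonor

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Default PM substitution spectrum: transition-heavy at G/C pairs, the
# signature of abasic-site bypass downstream of AID deamination, with a
# minority of transversions and rare A/T changes.
DEFAULT_PM_SPECTRUM: dict[str, float] = {
    "C>T": 0.30, "G>A": 0.30,
    "C>G": 0.08, "G>C": 0.08,
    "C>A": 0.06, "G>T": 0.06,
    "A>T": 0.03, "T>A": 0.03,
    "A>G": 0.02, "T>C": 0.02,
    "A>C": 0.01, "T>G": 0.01,
}


def simulate_parent(length: int = 400, seed: int = 0, gc: float = 0.5) -> str:
    """A random parental locus with the requested G+C content."""
    if length < 1:
        raise DataError("parent length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=length, p=p))


# ---------------------------------------------------------------------------
# Donor array
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DonorSimParams:
    n_donors: int = 6
    divergence: float = 0.04  # per-base substitution rate from the parent
    min_inter_donor_diff: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.divergence <= 0.2):
            raise DataError("donor divergence must lie in (0, 0.2]")
        if self.n_donors < 1:
            raise DataError("need at least one donor")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def simulate_pseudogene_db(parent: str, params: DonorSimParams) -> PseudogeneDB:
    """Substitution-only donors diverged from the parent, pairwise distinct.

    Each donor differs from the parent at >= 1 position and from every other
    donor at >= ``min_inter_donor_diff`` positions; infeasible constraint
    combinations raise after a bounded number of attempts.
    """
    if len(parent) < 100:
        raise DataError("donor simulation expects a parent of >= 100 nt")
    rng = np.random.default_rng(params.seed)
    donors: list[PseudogeneDonor] = []
    for k in range(params.n_donors):
        for _attempt in range(200):
            n_diff = max(1, int(rng.binomial(len(parent), params.divergence)))
            positions = rng.choice(len(parent), size=n_diff, replace=False)
            seq = list(parent)
            for p in positions:
                alts = [b for b in BASES if b != parent[p]]
                seq[p] = alts[int(rng.integers(3))]
            cand = "".join(seq)
            if all(_hamming(cand, d.sequence) >= params.min_inter_donor_diff for d in donors):
                donors.append(PseudogeneDonor(f"psV{k + 1:02d}", cand))
                break
        else:
            raise DataError(
                f"could not place donor {k + 1}: distinctness constraint infeasible "
                f"for divergence {params.divergence}"
            )
    return PseudogeneDB(donors)


# ---------------------------------------------------------------------------
# Hypermutated clone sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HypermutSimParams:
    """Generating conditions for one clone set.

    Three clones per set mirrors the study design; events per clone are
    Poisson with a mean of a few changes after two weeks of expansion.
    ``gc_position_bias`` is the weight of a G/C position relative to an A/T
    position when drawing PM sites (a deliberately simple hotspot proxy).
    """

    n_clones: int = 3
    event_mean: float = 3.0
    gc_fraction: float = 0.3
    gc_tract_mean: float = 40.0  # geometric mean tract length, nt
    gc_min_tract_len: int = 12  # >= the classifier string bound: every tract is findable
    gc_min_tract_diffs: int = 1
    gc_exclusive_tracts: bool = True  # copied diffs carried by no other donor
    pm_spectrum: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PM_SPECTRUM))
    gc_position_bias: float = 4.0
    pm_avoid_donor_diffs: bool = True
    pm_min_string: int = 10  # reject PMs whose local string coincidentally occurs in a donor
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gc_fraction <= 1):
            raise DataError("gc_fraction must lie in [0, 1]")
        if self.event_mean < 0 or self.gc_tract_mean < 2:
            raise DataError("event_mean >= 0 and gc_tract_mean >= 2 required")
        total = sum(self.pm_spectrum.values())
        if total <= 0:
            raise DataError("pm_spectrum weights must have positive mass")


@dataclass(frozen=True)
class SimEvent:
    clone_id: str
    category: str  # GC | AMB | PM  (a one-diff tract is ambiguous by design)
    mutations: tuple[tuple[int, str, str], ...]  # (pos, ref, alt)
    donor_id: str | None = None
    tract: tuple[int, int] | None = None


@dataclass
class CloneTruth:
    clone_id: str
    events: list[SimEvent]
    errors: list[tuple[int, str, str]]


def _spectrum_matrix(spectrum: Mapping[str, float]) -> dict[str, dict[str, float]]:
    rows: dict[str, dict[str, float]] = {b: {} for b in BASES}
    for key, w in spectrum.items():
        ref, alt = key.split(">")
        if ref not in BASES or alt not in BASES or ref == alt or w < 0:
            raise DataError(f"bad spectrum entry {key!r}")
        rows[ref][alt] = rows[ref].get(alt, 0.0) + float(w)
    return rows


def simulate_clone_set(
    parent: str,
    db: PseudogeneDB,
    params: HypermutSimParams,
    label: str = "synthetic",
) -> tuple[CloneSet, list[CloneTruth]]:
    """Simulate a clone set and its per-event truth.

    GC events copy a contiguous donor tract containing at least
    ``gc_min_tract_diffs`` donor-parent differences (a tract with one copied
    difference is recorded as AMB truth: indistinguishable in principle from
    a point mutation).  PM events draw a G/C-biased position and an alt base
    from the spectrum, at positions where no donor differs from the parent
    when ``pm_avoid_donor_diffs`` is set, so their truth category is
    unambiguous.  Overlapping events are rejected and re-drawn.  Sequencing
    errors are applied last and recorded separately from events.
    """
    rng = np.random.default_rng(params.seed)
    n = len(parent)
    donor_list = list(db)
    donor_diff_positions = {
        d.id: {i for i in range(n) if d.sequence[i] != parent[i]} for d in donor_list
    }
    if any(len(d.sequence) != n for d in donor_list):
        raise DataError("clone simulation requires co-linear, equal-length donors")
    all_diff = set().union(*donor_diff_positions.values()) if donor_list else set()
    rows = _spectrum_matrix(params.pm_spectrum)
    row_mass = {b: sum(rows[b].values()) for b in BASES}

    clones: list[tuple[str, str]] = []
    truths: list[CloneTruth] = []
    for c in range(params.n_clones):
        cid = f"{label}-clone{c + 1:02d}"
        n_events = int(rng.poisson(params.event_mean))
        occupied: set[int] = set()
        events: list[SimEvent] = []
        used_donors: set[str] = set()
        for _ in range(n_events):
            if rng.random() < params.gc_fraction and donor_list:
                ev = _draw_gc_event(rng, cid, parent, donor_list, donor_diff_positions, used_donors, occupied, params)
            else:
                ev = _draw_pm_event(rng, cid, parent, donor_list, all_diff, occupied, rows, row_mass, params)
            if ev is None:
                continue
            events.append(ev)
            # pad the footprint so point-mutation strings never straddle a
            # neighbouring event (keeps truth labels identifiable)
            pad = max(1, params.pm_min_string)
            if ev.tract is not None:
                occupied.update(range(max(0, ev.tract[0] - pad), min(n, ev.tract[1] + pad)))
                used_donors.add(ev.donor_id)
            else:
                p = ev.mutations[0][0]
                occupied.update(range(max(0, p - pad), min(n, p + pad + 1)))
        seq = list(parent)
        for ev in events:
            for pos, _ref, alt in ev.mutations:
                seq[pos] = alt
        errors: list[tuple[int, str, str]] = []
        if params.seq_error_rate > 0:
            hits = np.nonzero(rng.random(n) < params.seq_error_rate)[0]
            for pos in hits:
                ref = seq[pos]
                alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
                errors.append((int(pos), ref, alt))
                seq[pos] = alt
        events.sort(key=lambda e: e.mutations[0][0])
        clones.append((cid, "".join(seq)))
        truths.append(CloneTruth(cid, events, errors))
    return CloneSet(reference_id="parent", clones=clones, label=label), truths


def _draw_gc_event(rng, cid, parent, donor_list, donor_diff_positions, used_donors, occupied, params):
    n = len(parent)
    if params.gc_min_tract_len > n:
        raise DataError("conversion tract longer than parent")
    diff_carriers: dict[tuple[int, str], int] = {}
    for d in donor_list:
        for p in donor_diff_positions[d.id]:
            key = (p, d.sequence[p])
            diff_carriers[key] = diff_carriers.get(key, 0) + 1
    for _try in range(200):
        fresh = [d for d in donor_list if d.id not in used_donors]
        donor = (fresh or donor_list)[int(rng.integers(len(fresh or donor_list)))]
        length = params.gc_min_tract_len + int(
            rng.geometric(1.0 / max(params.gc_tract_mean - params.gc_min_tract_len, 1.0))
        )
        length = min(length, n)
        start = int(rng.integers(0, n - length + 1))
        tract = range(start, start + length)
        diffs = sorted(donor_diff_positions[donor.id] & set(tract))
        if len(diffs) < params.gc_min_tract_diffs:
            continue
        if occupied & set(tract):
            continue
        if params.gc_exclusive_tracts and any(
            diff_carriers[(p, donor.sequence[p])] > 1 for p in diffs
        ):
            continue
        muts = tuple((p, parent[p], donor.sequence[p]) for p in diffs)
        if not muts:
            continue
        category = "GC" if len(muts) >= 2 else "AMB"
        return SimEvent(cid, category, muts, donor_id=donor.id, tract=(start, start + length))
    return None


def _coincidental_donor_string(parent: str, pos: int, alt: str, donors, min_string: int) -> bool:
    """Would this substitution create a >= min_string exact donor string?

    Checks every window of ``min_string`` nucleotides covering the mutated
    position against plain substring containment in each donor.
    """
    if min_string <= 0:
        return False
    window = parent[: pos] + alt + parent[pos + 1 :]
    lo = max(0, pos - min_string + 1)
    hi = min(len(parent) - min_string, pos)
    for s in range(lo, hi + 1):
        sub = window[s : s + min_string]
        if any(sub in d.sequence for d in donors):
            return True
    return False


def _draw_pm_event(rng, cid, parent, donor_list, all_diff, occupied, rows, row_mass, params):
    n = len(parent)
    weights = np.zeros(n)
    for i, b in enumerate(parent):
        if i in occupied:
            continue
        if params.pm_avoid_donor_diffs and i in all_diff:
            continue
        w = params.gc_position_bias if b in "GC" else 1.0
        weights[i] = w * row_mass[b]
    total = weights.sum()
    if total == 0:
        return None
    for _try in range(100):
        pos = int(rng.choice(n, p=weights / total))
        ref = parent[pos]
        alts = sorted(rows[ref])
        alt_w = np.array([rows[ref][a] for a in alts])
        alt = alts[int(rng.choice(len(alts), p=alt_w / alt_w.sum()))]
        if _coincidental_donor_string(parent, pos, alt, donor_list, params.pm_min_string):
            continue
        return SimEvent(cid, "PM", ((pos, ref, alt),))
    return None


# ---------------------------------------------------------------------------
# Lesion-plasmid product mixtures
# ---------------------------------------------------------------------------

DEFAULT_PQTS_MIXTURE: dict[str, float] = {
    "TLS_top": 0.25,
    "TLS_bottom": 0.25,
    "error_free": 0.50,
}
# Nucleotide preference opposite the lesion: mostly accurate A insertion,
# with deletions the main alternative outcome.
DEFAULT_INCORPORATION: dict[str, dict[str, float]] = {
    "3pT": {"A": 0.65, "del": 0.15, "G": 0.10, "T": 0.10},
    "5pT": {"A": 0.60, "del": 0.20, "G": 0.10, "C": 0.10},
}

DEFAULT_PQTO_MIXTURE: dict[str, float] = {"TLS": 0.7, "deletion": 0.3}


@dataclass(frozen=True)
class BypassSimParams:
    mode_weights: Mapping[str, float] | None = None  # None -> arrangement default
    incorporation: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INCORPORATION.items()}
    )
    deletion_mean: float = 3.0  # geometric mean deletion length, support >= 1
    deletion_max: int = 8  # clip: a deletion never reaches the other lesion site
    n_products: int = 100
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_products < 1:
            raise DataError("need at least one product")
        if self.deletion_mean < 1:
            raise DataError("deletion_mean must be >= 1")


@dataclass(frozen=True)
class ProductTruth:
    read_id: str
    mode: str
    bases: Mapping[str, str] = field(default_factory=dict)
    deletion_length: int = 0


def _draw_symbol(rng, weights: Mapping[str, float]) -> str:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=w / w.sum()))]


def _draw_deletion_length(rng, mean: float, minimum: int = 1, maximum: int = 8) -> int:
    length = int(rng.geometric(1.0 / mean))
    return min(max(minimum, length), max(minimum, maximum))


def simulate_bypass_products(
    arch: LesionPlasmidArchitecture,
    params: BypassSimParams,
) -> tuple[ProductSet, list[ProductTruth]]:
    """Simulate a replicated-product mixture for one architecture.

    Staggered constructs draw from {TLS_top, TLS_bottom, error_free, other};
    opposing constructs from {TLS, deletion} (error-free template switching
    is impossible there by construction).  A TLS draw whose inserted bases
    would reproduce the marker at the site is re-drawn: such a product is
    observationally identical to a template switch.
    """
    rng = np.random.default_rng(params.seed)
    weights = dict(
        params.mode_weights
        if params.mode_weights is not None
        else (DEFAULT_PQTS_MIXTURE if arch.arrangement == "staggered" else DEFAULT_PQTO_MIXTURE)
    )
    if arch.arrangement == "opposing" and weights.get("error_free", 0) > 0:
        raise DataError("opposing arrangement admits no error_free products")
    reads: list[tuple[str, str]] = []
    truths: list[ProductTruth] = []
    for k in range(params.n_products):
        rid = f"{arch.id}-read{k + 1:04d}"
        mode = _draw_symbol(rng, weights)
        seq, truth = _build_product(rng, rid, mode, arch, params)
        if params.seq_error_rate > 0:
            chars = list(seq)
            hits = np.nonzero(rng.random(len(chars)) < params.seq_error_rate)[0]
            for pos in hits:
                chars[pos] = BASES[(BASES.index(chars[pos]) + 1 + int(rng.integers(3))) % 4]
            seq = "".join(chars)
        reads.append((rid, seq))
        truths.append(truth)
    return ProductSet(architecture_id=arch.id, reads=reads), truths


def _sample_site_insertion(rng, arch, params, forbidden: str, allow_del: bool = True):
    """Draw (3'T, 5'T) insertions, re-drawing marker-mimicking combinations
    (and, where deletions are disallowed, any combination containing one).

    Returns the two symbols plus a flag for whether either is a deletion.
    """
    for _ in range(1000):
        b3 = _draw_symbol(rng, params.incorporation.get("3pT", {"A": 1.0}))
        b5 = _draw_symbol(rng, params.incorporation.get("5pT", {"A": 1.0}))
        has_del = "del" in (b3, b5)
        if has_del and not allow_del:
            continue
        if not has_del and b3 + b5 == forbidden:
            continue
        return b3, b5, has_del
    raise DataError("incorporation preferences admit no usable insertion draw")


def _build_product(rng, rid, mode, arch, params) -> tuple[str, ProductTruth]:
    ref = list(arch.reference)
    t0, _t1 = arch.top_site
    s0, _s1 = arch.bottom_site
    if mode == "error_free":
        return arch.reference, ProductTruth(rid, mode)
    if mode == "TLS_top":
        # nascent bottom strand: the product's top strand shows complements
        # with the 3'T at the site end, so the draw (b3, b5) mimics the
        # marker exactly when comp(b5)·comp(b3) == marker
        b3, b5, has_del = _sample_site_insertion(
            rng, arch, params, forbidden=_COMP[arch.marker[1]] + _COMP[arch.marker[0]]
        )
        return _apply_site(ref, rid, mode, arch, (t0, t0 + 2), b3, b5, has_del, rng, params, top_convention=True)
    if mode == "TLS_bottom":
        b3, b5, has_del = _sample_site_insertion(rng, arch, params, forbidden=arch.marker)
        return _apply_site(ref, rid, mode, arch, (s0, s0 + 2), b3, b5, has_del, rng, params, top_convention=False)
    if mode == "TLS":
        # opposing arrangement: a TLS product is full length at the site
        # (deletions of >= 2 nt are the separate deletion class)
        b3, b5, _ = _sample_site_insertion(rng, arch, params, forbidden="", allow_del=False)
        return _apply_site(ref, rid, mode, arch, (t0, t0 + 2), b3, b5, False, rng, params, top_convention=True)
    if mode == "deletion":
        length = _draw_deletion_length(rng, params.deletion_mean, minimum=2, maximum=params.deletion_max)
        start = max(0, min(t0, len(ref) - length))
        out = ref[:start] + ref[start + length :]
        return "".join(out), ProductTruth(rid, mode, deletion_length=length)
    if mode == "other":
        for site in (arch.top_site, arch.bottom_site):
            while True:
                pair = "".join(_draw_symbol(rng, {b: 1.0 for b in BASES}) for _ in range(2))
                if pair != arch.marker:
                    break
            ref[site[0]], ref[site[1] - 1] = pair[0], pair[1]
        return "".join(ref), ProductTruth(rid, mode)
    raise DataError(f"unknown product mode {mode!r}")


def _apply_site(ref, rid, mode, arch, site, b3, b5, has_del, rng, params, top_convention):
    t = site[0]
    if has_del:
        # a deletion draw removes the whole site (possibly more), extending
        # away from the +1/+2 template positions so those stay readable
        length = _draw_deletion_length(rng, params.deletion_mean, minimum=2,
                                       maximum=params.deletion_max)
        start = t if top_convention else t + 2 - length
        start = max(0, start)
        out = ref[:start] + ref[start + length :]
        bases = {"3pT": "del", "5pT": "del"}
        return "".join(out), ProductTruth(rid, mode, bases=bases, deletion_length=length)
    bases = {"3pT": b3, "5pT": b5}
    if top_convention:
        ref[t] = _COMP[b5]
        ref[t + 1] = _COMP[b3]
    else:
        ref[t] = b3
        ref[t + 1] = b5
    return "".join(ref), ProductTruth(rid, mode, bases=bases)


# ---------------------------------------------------------------------------
# Truth-vs-call comparison helpers
# ---------------------------------------------------------------------------


def event_recovery(truths: Sequence[CloneTruth], events_by_clone: Mapping[str, Sequence]) -> tuple[int, int]:
    """Count simulated events recovered in the correct category.

    A truth event is recovered when a called event of the same category
    covers its mutation positions (GC additionally requires the same donor
    and allows absorbed extra members, e.g. a sequencing error explained by
    the same donor).
    """
    n_total = 0
    n_correct = 0
    for truth in truths:
        called = events_by_clone.get(truth.clone_id, [])
        for ev in truth.events:
            n_total += 1
            positions = {m[0] for m in ev.mutations}
            for cev in called:
                cpos = {m.pos for m in cev.members}
                if ev.category == "GC":
                    if cev.category == "GC" and cev.donor_id == ev.donor_id and positions <= cpos:
                        n_correct += 1
                        break
                elif positions == cpos and cev.category == ev.category:
                    n_correct += 1
                    break
    return n_correct, n_total
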