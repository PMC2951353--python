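# Methods

## Scope and model

`igtls` implements the sequence-classification and count-statistics analyses
used in DT40 translesion-synthesis (TLS) genetics:

1. **Ig V-lambda hypermutation classification.** The DT40 B-cell line
   diversifies its rearranged V-lambda segment by AID-seeded lesions that are
   resolved either by homologous-recombination-dependent gene conversion from
   an upstream pseudogene donor array, or by mutagenic TLS past the abasic
   site.  Sequenced clone segments are aligned to the parental segment, every
   change is called, and each change is assigned to exactly one event:
   - **PM** (non-templated point mutation): no pseudogene donor contains a
     contiguous exact string of length ≥ 10 nt (the ">9 bp" bound) matching
     the clone across the mutated position;
   - **GC** (long-tract gene conversion): such a donor string exists and at
     least one further mutation of the clone is explained by the same donor
     (donor base equals clone base at the homologous position); all mutations
     explained by that donor form one event;
   - **Amb**: a qualifying donor string exists but no further mutation is
     co-explained — the change could be templated or not.
2. **Lesion-plasmid bypass classification.** Replicated copies of episomal
   constructs carrying T-T (6-4) photoproducts are classified by the sequence
   at the lesion sites.  In the *staggered* arrangement (two lesions 28 nt
   apart, each opposite a GpC marker mismatch) an error-free template switch
   reads the marker at both sites, whereas TLS past a lesion writes the
   inserted bases (most often AA opposite the T-T, read through the strand
   convention below) or a deletion at that site.  In the *opposing*
   arrangement both strands are damaged at one position, so products arise
   only by TLS (full-length site) or by a deletion of ≥ 2 nt covering it.
3. **Count statistics.** Chromosomal aberrations over N metaphase spreads are
   Poisson: rate x/N with SE √x/N.  Sister-chromatid-exchange (SCE)
   distributions are compared by the two-sided Mann-Whitney U test, and
   UV-induced SCE is the post-irradiation mean minus the spontaneous mean
   with SEMs added in quadrature.

## Alignment and mutation calling

Clones are aligned end-to-end with an affine-gap Needleman-Wunsch (Gotoh)
dynamic program (match +1, mismatch −2, gap open −6, gap extend −1; a gap of
length k costs open + (k−1)·extend).  The defaults make an isolated
substitution (−2) cheaper than a compensating indel pair (−12), the right
prior for near-identical V segments.  The DP is numpy row-vectorised (the
horizontal gap state is computed with a running prefix-max recurrence) and
the traceback resolves score ties with a fixed state preference
(match/mismatch, then gap-in-clone, then gap-in-parent), so equal-scoring
optima always produce one canonical alignment.  Indels are merged per run and
left-normalised against the parent, stopping at the previous mutation's
footprint; positions are 0-based half-open everywhere, with 1-based columns
added in reports.  Substitution columns containing N are uncallable and
skipped.  Clones differing from the parent at > 10 % of positions are flagged
and excluded as likely mis-tracked sequences (configurable).

## Donor-string search

The string requirement is **offset-free**: the ≥ 10 nt clone string covering
the mutation may match anywhere in a donor, not only at the homologous
position (the rule as stated is donor *containment* of a string).  For each
donor the maximal exact clone-donor match covering the mutated position is
found by anchoring every donor position against the mutated clone position
and extending; a deletion, having no clone bases, must be straddled by the
match.  "Explained by the same donor" is positional: donors are pre-aligned
to the parent once (same DP) and homology is read through that alignment, so
donors of unequal length are supported.  When several donors qualify for a
GC event the tie-break is: most mutations explained, then longest total
matched length, then lexicographic donor id; results are independent of
donor file order.  The reported GC tract is the minimal interval covering
the member mutations extended outward while clone, donor and parent all
agree (reporting only; category counts are unaffected).  Clone indels are
GC/Amb-eligible like substitutions but never enter substitution spectra.
Reverse-complement donor search exists behind a flag and is off by default.

## Bypass-product reading conventions

Products are canonicalised to the reference (marker-form) top strand by
aligning both orientations and keeping the higher score (ties go forward),
so calls are invariant to sequencing direction.  For a **top-strand lesion**
the nascent strand is the bottom strand: inserted bases are the complements
of the product's top-strand bases, with the 3′ T of the lesion at the site's
right edge and the +1/+2 template positions to its left.  For a
**bottom-strand lesion** insertions appear directly in top-strand
orientation: 3′ T at the site's left edge, +1/+2 to the right.  Hence an
accurate ApA insertion reads TT at the top site but AA at the bottom site.
A deletion run touching a site makes that site "del"; reads below 90 %
identity to the reference outside the lesion region are counted
unclassifiable and excluded from fractions; reads non-marker at both
staggered sites are flagged "other" rather than forced into a mode.
Deletion-associated products count inside the TLS percentage (every bypass
of a damaged template that is not a template switch is a TLS outcome).
Incorporation profiles are tallied over TLS calls only.

Caveat: when a base adjacent to a lesion site equals the site's edge base, a
1-nt deletion at the boundary can legitimately re-align outside the site
(the two placements are score-equivalent).  The packaged fixture references
avoid such flanks; for arbitrary user architectures these boundary products
are inherently ambiguous.

## Count statistics details

`poisson_rate` treats the x aberrations over N cells as a Poisson total:
mean x/N, SE √x/N; presentation values are rounded half-up to 2 decimals
(√12/100 = 0.0346 → 0.03).  `mann_whitney` uses the exact null distribution
of U (counting recurrence) when min(n) ≤ 8 and there are no ties, reporting
the two-sided p as twice the one-sided tail capped at 1; otherwise the
normal approximation with tie and continuity corrections (scipy).  The
classic statistic min(U_a, U_b) is reported alongside U_a.  `induced_sce`
subtracts means and combines sample SEMs in quadrature; a single-observation
sample has SEM 0 by convention.

## Synthetic data generator

The study's raw Sanger reads and per-cell counts are not deposited, so every
stage is exercised on synthetic data with recorded truth.

**Donor array** — substitution-only donors diverged from the parent
(default 6 donors at 4 % divergence, pairwise ≥ 3 differences), emulating a
pseudogene array; co-linear by construction.

**Clone sets** — default 3 clones per set (the study design), events per
clone Poisson with mean 3, 30 % gene conversion.  GC events copy a
contiguous donor tract (geometric length, mean 40 nt) containing at least
one donor difference; a one-difference tract is recorded as Amb truth, since
it is indistinguishable in principle from a point mutation.  PM positions
are drawn with weight 4 at G/C versus 1 at A/T (a deliberately simple AID
hotspot proxy — no mechanistic targeting model) and alt bases from a
12-weight spectrum defaulting to transition-heavy changes at G/C pairs.
Sequencing error is uniform substitution-only, applied last and recorded
separately.  Overlapping events are re-drawn.

Identifiability choices that make exact-recovery tests well-posed (each a
generator design decision, configurable): tracts are at least 12 nt, so
every simulated tract contains a findable ≥ 10 nt string; copied tract
differences must be carried by no other donor, otherwise two same-clone
events can legitimately merge under the rule; PM draws avoid donor-difference
positions and reject positions whose resulting ≥ 10 nt string coincidentally
occurs in a donor (such a change would be genuinely ambiguous).  Under these
conditions plus zero sequencing error, category recovery is exactly 100 %;
with 0.1 % error it stays ≥ 95 % (measured over ≈100 events from 30 clones,
a size chosen for a stable estimate).

**Bypass products** — staggered mixtures draw modes from {TLS_top,
TLS_bottom, error_free, other} (default 25/25/50/0), opposing mixtures from
{TLS, deletion}; insertion draws at the 3′ T and 5′ T positions follow
per-position preferences (default: mostly accurate A, deletions the main
alternative).  Three regularisations keep truth labels observationally
meaningful: an insertion draw that would reproduce the marker is re-drawn
(such a product is identical to a template switch); a deletion draw removes
the whole site and extends away from the +1/+2 positions (lengths geometric,
mean 3, clipped at 8 so a deletion never reaches the other lesion site); and
opposing-arrangement TLS draws exclude deletions (≥ 2 nt deletions are the
separate deletion class; sub-threshold deletions are still classified
correctly when present in real reads).  With zero sequencing error, mode
recovery on generated mixtures is exact.

What the generator does **not** emulate: PCR/sequencing chimeras and
quality-dependent errors, donor indel polymorphism, AID sequence-context
hotspots (WRC motifs), clonal pedigree structure within a set, replication
efficiency differences between constructs.  Passing recovery tests therefore
demonstrates correctness of the classification rules under the stated
identifiability conditions, not robustness to every artefact of real Sanger
data.

## Numerical and reporting choices

Percentages that mirror printed summary tables are rounded half-up to
integers; rates to 2 decimals; all reports carry numerator and denominator,
never percentages alone.  Report writers emit fixed column orders and fixed
float precision, so identical inputs give byte-identical files; every CLI
run writes a provenance header (inputs, parameter hash, seed, version).
Alignment tie-breaks, indel left-normalisation and the donor tie-break
policy make the whole pipeline deterministic for a given input and seed.

## Problem sizes

Default test and acceptance runs use a 400 nt parent, 6 donors, clone sets
of 3-30 clones, and product sets of up to 1000 reads — sizes at which the
vectorised DP classifies a clone in milliseconds and the full acceptance
script completes in seconds.

## Known limitations

The classifier assumes the donor array is provided in sense orientation
unless the reverse-complement flag is set.  The Amb category is reported
as-is and never re-labelled as short-tract conversion.  Significance testing
of spectrum differences and tract-length inference are out of scope; the
Mann-Whitney and Poisson machinery cover the count readouts only.
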