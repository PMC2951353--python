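# igtls

Sequence classification and count statistics for translesion-synthesis (TLS)
genetics in the chicken DT40 B-cell line.

DT40 cells diversify their rearranged immunoglobulin V-lambda segment
continuously in culture: AID deaminates cytosines in the locus, and the
resulting abasic sites are bypassed either by homologous-recombination-driven
**gene conversion** from an upstream array of V-lambda pseudogene donors or
by mutagenic **TLS**, which leaves non-templated point mutations.  Comparing
how knockouts of TLS polymerases (Polη, Polζ, Polκ) shift these outcomes —
together with the replication products of episomal plasmids carrying
site-specific T-T (6-4) UV photoproducts, and cytogenetic counts of
chromosomal aberrations and sister chromatid exchanges (SCEs) — requires a
set of small but fussy analyses that this package implements as a tested,
reusable pipeline:

* **`mutcall`** — global affine-gap alignment of sequenced clone segments to
  the parental V-lambda segment and mutation calling (left-normalised
  indels, deterministic tie-breaks).
* **`gcclass`** — assignment of every mutation to exactly one event by the
  donor-string rule: a mutation with no pseudogene donor containing a
  matching string longer than 9 bp across the mutated position is a
  non-templated point mutation (PM); if such a string exists and further
  mutations are explained by the same donor, all of them form one long-tract
  gene conversion event (GC); an isolated match is ambiguous (Amb).
* **`spectra`** — substitution spectra of PM events and category rates; the
  headline statistic is the proportion of transitions at G/C pairs,
  100·(G→A + C→T)/total.
* **`lesionbypass`** — classification of replicated lesion-plasmid copies.
  In the staggered construct (two T-T lesions 28 nt apart, each opposite a
  GpC marker) a product reading the marker at both sites arose by error-free
  template switching, while a non-marker or deleted site reveals TLS on that
  strand, with the inserted bases (accurate ApA or otherwise) and
  per-position incorporation profiles recovered.  In the opposing construct
  only TLS (full-length site) or ≥2 nt deletions are possible.
* **`countstats`** — Poisson aberration rates x/N ± √x/N over N metaphase
  spreads, exact and asymptotic two-sided Mann-Whitney U tests for SCE
  distributions, and induced-SCE subtraction with errors in quadrature.
* **`synth`** — a synthetic-data generator with recorded truth for every
  stage (donor arrays, hypermutated clone sets, bypass-product mixtures),
  since no raw reads or per-cell counts are deposited for studies of this
  design.

## Worked example

Generate a synthetic hypermutation data set and classify it:

```sh
igtls simulate igv --out sim --seed 4
igtls classify-igv --parent sim/parent.fasta --donors sim/donors.fasta \
    --clones sim/clones.fasta --out igv
```

`igv/events.tsv` (provenance header omitted):

```
clone	event	category	donor	tract_start	tract_end	n_members	positions
synthetic-clone01	0	GC	psV05	72	131	3	93,111,115
synthetic-clone01	1	PM	-	-1	-1	1	158
synthetic-clone01	2	PM	-	-1	-1	1	238
synthetic-clone01	3	PM	-	-1	-1	1	364
synthetic-clone02	0	AMB	psV03	-1	-1	1	248
synthetic-clone03	0	PM	-	-1	-1	1	1
synthetic-clone03	1	PM	-	-1	-1	1	82
synthetic-clone03	2	PM	-	-1	-1	1	143
```

Clone 1 carries a gene-conversion tract copied from donor psV05: three
changes at positions 93-115 are all explained by that donor, and the
reported tract (72-131) is the maximal interval over which clone, donor and
parent agree around them.  The isolated change in clone 2 has a qualifying
donor string in psV03, so it is ambiguous; the remaining six changes match
no donor and are non-templated point mutations.  `igv/summary.json` then
reports the per-category totals and the G/C transition proportion of the PM
set:

```json
{"n_clones": 3, "n_pm": 6, "n_amb": 1, "n_gc": 1,
 "gc_to_at_transition": {"percent": 83, "numerator": 5, "denominator": 6}}
```

Aberration counts work the same way from a TSV of per-line subtype counts
(one packaged with the library):

```sh
igtls stats --counts src/igtls/data/spontaneous_aberrations.tsv --out stats
```

```
line	x	N	per_cell	se	display
wild-type	2	100	0.020000	0.010000	0.02±0.01
polz	12	100	0.120000	0.030000	0.12±0.03
polh	1	100	0.010000	0.010000	0.01±0.01
polh_polz	2	100	0.020000	0.010000	0.02±0.01
polh_polz_wt_Polh	14	100	0.140000	0.040000	0.14±0.04
polh_polz_mut_Polh	4	100	0.040000	0.020000	0.04±0.02
```

Each `display` cell is x/N ± √x/N: the Polζ knockout accumulates six times
the wild-type rate of spontaneous aberrations, the double knockout returns
to wild-type levels, and reconstitution with catalytically active (but not
inactive) Polη restores the instability.

Lesion-plasmid products are classified against a YAML architecture config
(`igtls classify-bypass --products reads.fasta --arch src/igtls/data/pqts.yaml
--out byp`), yielding per-read calls, TLS/error-free fractions and the
incorporation profile at the 3′ T, 5′ T, +1 and +2 positions.

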