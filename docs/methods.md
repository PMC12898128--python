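# Methods

## Coordinates and alphabets

All public coordinates are 1-based inclusive, matching database residue
numbering (an LSmAD annotation of 409–477 means residues 409 through
477). Internal code may use 0-based half-open slices; the conversion is
tested as an identity. Sequences are uppercased on ingestion. Strict mode
(the default) rejects residues outside the 20 amino acids + X (protein)
or ACGT (DNA); lenient mode maps unknown protein residues to X with a
logged warning. FASTA output wraps at 60 columns; parsing accepts any
wrapping and CRLF endings.

## Homopolymer repeat model

A tract for target residue *t* is a chain of maximal pure *t*-runs in
which consecutive runs are separated by at most `max_gap` non-target
residues. A chain is reported when it contains at least one seed run of
length ≥ `seed_min` and ≥ `min_total` target residues in total. Defaults:
targets {Q, A, P, S, G}, `seed_min` 3, `max_gap` 2 (single or double
interrupting residues are the common pattern in real polyQ domains),
`min_total` 6 (tracts are biologically reported from Q > 5 upward).
Conventions that matter:

- **Size counts the target only.** Repeat domains are conventionally
  sized by glutamine count ("73Q" with interruptions), so `count_target`
  excludes interrupting residues; `purity` is reported but no purity
  filter is applied by default — heavily interrupted tracts (e.g. 41Q
  broken at 11 positions) would fail any naive purity cut.
- **Interruption runs are unrestricted in composition** (Pro, His, Ala,
  Met, Arg, Ser, Gly all occur in real orthologs), only bounded in
  length.
- **Flank = the single residue immediately outside the tract**, with
  `^`/`$` sentinels at the termini. Tracts start and end on the target
  residue by construction, so a non-target residue adjacent to the first
  target is a flank, never part of the tract.
- Flank/interruption statistics count *residues* (a "PP" run adds 2 to
  P); ranked tables sort by count descending, alphabetically within
  ties; terminus sentinels are tallied separately.

With `max_gap = 0` the detector provably reduces to maximal pure runs of
length ≥ `min_total`, which is the brute-force oracle used in tests.

## Run-length codon notation

The parser accepts `(XYZ)_n_`, `(XYZ)n`, `(XYZ)` and bare codon runs;
hyphens (line-break artifacts), whitespace and `**` bold markers are
ignored. Bare letter runs are split into consecutive triplets, because
stripping markup from printed strings concatenates adjacent codons
(`CAA**ATG**` → `CAAATG`). Parsing preserves the textual runs so printed
forms can be echoed; canonicalization merges adjacent equal-codon runs,
and `decompose(expand(r)) = canonicalize(r)` is a tested round-trip.
Translation uses the standard nuclear genetic code only (all curated
examples are nuclear genes); internal stops are an error in strict mode.

## Tandem duplications

A reported array is a maximal periodic run (the interval where
`s[i] == s[i+u]` extends no further in either direction) whose primitive
period *u* lies in `[min_unit, max_unit]` (defaults 2–12) and which
contains ≥ 2 full copies. Non-primitive units are suppressed — the run is
reported once under its primitive period — and with `min_unit ≥ 2`
homopolymers are never reported (they belong to the repeat caller).
Among the equivalent phases of one run the **end-aligned (rightmost)
phase** is reported: for the known pathogenic variants this is the phase
in which the duplicated exon segment is conventionally written
(ARPA-**PGCPRPA-PGCPRPA**-CEPV; PARR-**SGR-SGR**-GGGG), and it is
well-defined for every maximal run. `unit_len_nt = 3 × unit_len_aa` is
reported for direct comparison with base-pair phrasing ("21 base
pairs"). The implementation is checked bit-exactly against a brute-force
O(n²·u) scanner on sequences up to 200 residues.

## PAM2 motif scanning

Consensus patterns encode conservation by letter case: uppercase
positions weigh `weight_high` (default 1.0), lowercase `weight_low`
(default 0.25), `.` nothing. A window's score is the weighted fraction of
(case-insensitively) matching positions, in [0, 1]; the default report
threshold is 0.60. The published consensus gives no numeric weights, so
the 4:1 high:low ratio and the threshold are package design choices,
fully configurable; the two-tier scheme follows the two-tier case
encoding of the source consensus. No indels: PAM2 is a fixed-length
linear motif. Shipped presets: `PAM2_FULL_23`
(`pksksKLNPNAKpFsLNiNAKeF`), `PAM2_PLANT_TANDEM`
(`sekstLNPNAKEFkLNPNAKSFtps`, the land-plant tandem variant) and
`PAM2_CORE_10` (`lNPnAtpFvP`), a hand-curated degenerate core distilled
from the five trypanosomatid precursor candidates — a design choice of
this package, not a database consensus (a strict per-column majority
vote over those five strings would give `pNPsAtpFvP`; the shipped form
keeps the Leu seen in the most divergent candidate at position 1).
Mutating *k* lowercase positions of a planted motif yields the exact
score `(W − k·w_low)/W`, which the recovery tests use as a closed-form
threshold.

## Isoform enumeration

Every Met is a candidate internal translation start (no Kozak-like
filtering — no such context is available for the survey data). For each
annotated domain the isoform status is total and exclusive: `full` if
the Met is at or before the domain start (a start codon exactly at the
domain start yields the domain-initial isoform, cf. the MRMVHILTSVV
start at LSm), `truncated` strictly inside, `lost` after the end. Zones
partition the sequence by the annotated core landmarks in canonical
order (pre_LSm, within_LSm, LSm_to_LSmAD, …, post_PAM2); when a landmark
is not annotated its flanking zones merge and the zone name reflects the
nearest annotated landmarks (LSm_to_PAM2 when LSmAD is missing). The
zone census always sums to the number of Met residues.

## Architecture classification

Core labels default to {LSm, LSmAD, PAM2}; anything else annotated on
the protein is an "extra". Verdict rules, invariant to input row order:

- no core domain → `irregular`;
- LSmAD absent → at most `partial` (LSmAD defines the family, so no
  chimerism verdict is issued without it);
- any extra between or overlapping core domains → `irregular` (side
  `internal`; not observed in real data, kept as a guard);
- extras entirely before the first / after the last core domain →
  `chimeric_N` / `chimeric_C` / `chimeric_both`;
- no extras: all three cores in canonical start order → `canonical`,
  otherwise `partial` (out-of-order cores → `irregular`).

`unusual_length` flags proteins above 1000 residues (the screen length
used when hunting fused extra domains); configurable.

Enrichment among chimeric extras uses the two-sided Fisher exact test in
the "sum of tables with probability ≤ observed" convention (scipy's
`fisher_exact`, validated against an independent hypergeometric
enumeration on all 2×2 tables with margins ≤ 30), with
Benjamini–Hochberg q-values across observed categories. No significance
filter is applied at reporting time. Ranking is by p ascending (compared
at 12 significant digits), over-represented before under-represented at
ties — with only two categories the enriched and depleted category have
identical two-sided p, and the tie-break keeps the enriched one first.

## Ortholog tiers and bootstrap

Tier rules use the two printed E-value thresholds (strict 1e-10, loose
5e-7) and the principle that LSmAD defines the family; the exact
tier1/2/3 partition (anchor + support / anchor alone / marginal anchor)
is this package's design, with thresholds, anchor and supporting-label
set all configurable. Supporting hits count regardless of their own
E-value: their role is corroboration, not membership. Taxonomy
include/exclude sets reject subjects before tiering.

The bootstrap loop (search → tier → column-majority consensus of tier-1
sequences → new query) assumes pre-aligned equal-length sequences from
the fetch backend; alignment itself is out of scope. Consensus ties
break alphabetically and `-` wins a column only on strict majority. The
fixpoint is an identical tier-1 subject set in consecutive iterations;
the iteration count reported is the number of productive rounds before
the confirming search. Backends are injected callables (no network
anywhere); by convention they emit hits whose `query_id` is the domain
label the hit supports.

## Synthetic cohorts

Generators are pure functions of their spec; each draws from a stream
derived from the master seed plus a fixed per-generator key, so adding a
generator never perturbs existing outputs. Backgrounds default to
uniform over the 20 amino acids (configurable to IDR-like compositions,
e.g. Q at 2%). Planted features are protected so truth tables are exact:
repeat tracts get a target-free guard band (width ≥ `max_gap`) on both
sides; tandem arrays get boundary characters that break the periodicity
exactly at the planted edges; motif mutations always change the residue
at a lowercase position. What the cohorts do **not** emulate: real IDR
compositional bias beyond single-residue frequencies, homology between
sequences, alignment error in the consensus step, and the long-tailed
length distribution of real orthologs — so passing recovery tests shows
the detectors implement their definitions exactly, not that the
definitions are complete for every real proteome.

Default cohort sizes (100–400 proteins, sequences of 120–300 residues,
30 BLAST subjects across four strata) keep the whole suite and the
analysis drivers in the seconds range while leaving binomial room to
check planted fractions; they are package defaults, not statements about
the original survey's scale.

## Known limitations

- Approximate tandem repeats (mismatches between copies) and DNA-level
  tandem detection are out of scope.
- The repeat caller reports per-sequence calls; genome-scale scanning
  (six-frame translation, intron handling) is not attempted.
- Enrichment assumes a user-supplied background category table; no live
  GO/InterPro lookup exists anywhere in the package.
- The flank/interruption rankings computed on synthetic cohorts reflect
  the planted composition, not any empirical claim about real orthologs.
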