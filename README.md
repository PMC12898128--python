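# atx2kit

Sequence-analysis toolkit for the Ataxin-2 protein family: homopolymer
repeat tracts, codon-level repeat decomposition, tandem duplications,
degenerate PAM2 motifs, Met-start isoforms, domain-architecture chimerism
and offline ortholog-tier classification.

## The problem

Ataxin-2 (ATXN2) carries an N-terminal polyglutamine (polyQ) tract whose
expansion causes spinocerebellar ataxia type 2 and modulates ALS risk. In
the healthy human allele the 22Q tract is encoded by
(CAG)₈-CAA-(CAG)₄-CAA-(CAG)₈ — CAA interruptions stabilize the repeat
during replication, and their loss precedes pathogenic expansion. Across
eukaryotes, Ataxin-2 orthologs share a conserved LSm–LSmAD–PAM2 core
embedded in intrinsically disordered regions (IDRs); LSmAD is the
family-defining domain. Surveying this family requires a set of small,
exact sequence procedures that general-purpose tools do not provide:

- **repeats** — maximal homopolymer tracts (polyQ/A/P/S/G) with bounded
  interruptions, sized by target-residue count (a "73Q" domain means 73
  glutamines, whatever interrupts it), plus flank/interruption residue
  rankings;
- **codons** — parsing of printed run-length codon notation such as
  `(CAA)_3_CAG(CAA)_2_…`, expansion, translation and codon-usage
  summaries of repeat-encoding DNA;
- **tandem** — maximal tandem arrays of primitive units, as in the
  pathogenic dup21 (7-residue unit, 21 bp) and dup9 (SGR, 9 bp) variants;
- **motif** — scanning for the degenerate PAM2 consensus
  `pksksKLNPNAKpFsLNiNAKeF`, where letter case encodes conservation
  strength; a window scores the weighted fraction of matching positions;
- **isoforms** — enumeration of internal Met starts and their zone
  relative to the LSm/LSmAD/PAM2 landmarks;
- **architecture** — classification of domain layouts as canonical,
  partial or N-/C-terminal chimeric, with Fisher-exact/BH enrichment of
  functional categories among chimeric extra domains;
- **tier** — quality-tier classification of BLAST hits anchored on LSmAD
  E-values (strict 1e-10, loose 5e-7) and the iterative
  consensus-bootstrap search loop, with injected offline backends.

Seeded generators (`atx2kit.simulate`) produce IDR-like cohorts with
planted features and exact truth tables, so every detector is testable
with no downloads.

## Worked example

```python
from atx2kit import parse_runlength, expand, summarize_repeat_dna
from atx2kit.worked_examples import SYMBIODINIUM_73Q

summ = summarize_repeat_dna(parse_runlength(SYMBIODINIUM_73Q), target="Q")
print(summ.total_target, len(summ.interruption_events), summ.codon_usage)
```

prints

```
73 3 {'CAG': 50, 'CAA': 23}
```

— the *Symbiodinium necroappetens* repeat region encodes 73 glutamines
from a mix of 50 CAG and 23 CAA codons, broken by 3 interruption events
(each a single Met). The same pipeline gives 22Q for the canonical human
template, 30Q (*Gracilariopsis chorda*), 45Q uninterrupted
(*Condylostylus longicornis*) and 29Q from pure CAA (*Dictyostelium
discoideum*).

The analysis drivers run the full survey on the curated worked inputs
plus synthetic cohorts and write their tables under `results/`:

```sh
python analysis/01_codon_decompositions.py
python analysis/02_repeat_survey.py
python analysis/03_tandem_and_motifs.py
python analysis/04_architecture_enrichment.py
python analysis/05_ortholog_tiers.py
```

A `atx2kit` console script exposes the same operations as subcommands
(`repeats`, `codons`, `tandem`, `motif`, `isoforms`, `architecture`,
`tier`, `simulate`); see `atx2kit --help`.

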