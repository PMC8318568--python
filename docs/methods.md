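# Methods

`gcescan` detects natural genetic code expansion (GCE) — the
co-translational insertion of selenocysteine (Sec, `U`, at opal/UGA
codons) and pyrrolysine (Pyl, `O`, at amber/UAG codons) — in bacterial
genomes and metagenome-assembled genomes (MAGs). This note describes
the models, their assumptions, the default parameters and why they
hold, what the synthetic benchmark does and does not emulate, and the
numerical choices a maintainer would want written down.

## Readthrough-aware gene calling (`seqcore`)

A `TranslationTable` is the bacterial code (NCBI table 11) plus a set
of stop-codon reassignments: amber mode maps `TAG -> O`, opal mode
`TGA -> U`, dual mode both; `TAA` is never reassigned (no natural TAA
recoding is modeled). `find_orfs` enumerates, on both strands and all
three frames, ORFs that begin at a bacterial start codon (`ATG`,
`GTG`, `TTG`), end at a hard (non-readthrough) stop, and pass through
at most `max_readthrough` reassigned codons, each recorded as a
`ReadthroughEvent` with its genomic and protein position. One ORF is
reported per terminal stop: the leftmost qualifying start after the
previous hard stop.

Choices and their reasons:

- **Exhaustive longest-per-stop reporting, not trained scoring.** The
  point of the caller is the translation table, not gene scoring;
  exhaustive enumeration is deterministic and checkable against a
  brute-force six-frame oracle (the test suite does exactly that).
  The cost is overlapping calls in different frames/strands — callers
  downstream must not assume one gene per locus (see "SECIS sharing"
  below).
- **`min_len_codons = 60`** (protein length, stop excluded): well below
  any protein of interest here (the Pyl methyltransferase is 485 aa)
  but long enough to keep the exhaustive call set manageable.
- **`max_readthrough = 2`**: the targets carry one recoded codon each;
  2 tolerates tandem Sec residues. When the budget is exceeded the
  start moves rightward past readthrough codons rather than the stop
  being reinterpreted — an ORF may only end at a hard stop.
- **Starts are translated literally** (`GTG -> V`, `TTG -> L`), not
  forced to Met, so re-translating a gene's genomic span always
  reproduces its `protein` field exactly (a tested invariant).
- Linear contigs only (MAG fragments); codons containing `N` translate
  to `X`; a hard stop inside a supplied span renders `*`.

Edge case: a standard-table ORF ending in `TAG`/`TGA` near the contig
edge may have no dual-mode counterpart, because the merged span never
reaches a downstream in-frame `TAA`. Readthrough merges coding spans
wherever a terminal hard stop exists; at contig edges the merged ORF
can run off the sequence and is then not reported.

## tRNA detection by constrained cloverleaf folding (`trna`)

The Pyl and Sec tRNAs are structurally atypical: the Pyl tRNA has a
CUA (amber-suppressor) anticodon, an anticodon stem with an extra base
pair (6 bp) and a single nucleotide between the acceptor stem and the
D arm; the Sec tRNA has a UCA (opal-suppressor) anticodon and a long
variable *arm* where standard tRNAs have a ~4-nt loop. `gcescan`
recognizes tRNAs with a purely structural model: an exhaustive search
over cloverleaf decompositions within arm-length windows that bracket
canonical dimensions plus exactly those deviations:

| element            | window  | element        | window |
|--------------------|---------|----------------|--------|
| acceptor stem      | 6–9 bp  | anticodon stem | 5–6 bp |
| acceptor–D spacer  | 1–3 nt  | anticodon loop | 7 nt   |
| D stem             | 3–4 bp  | variable region| 3–23 nt|
| D loop             | 4–12 nt | T stem         | 4–5 bp |
| T loop             | 5–9 nt  | total length   | 60–120 nt |

Every stem must be fully paired (Watson–Crick or G·U wobble), with **at
most one G·U pair per stem** by default. The wobble cap is the decisive
specificity lever: with unlimited wobble pairing the admissible pairing
probability per position is 6/16 and random 41%-GC sequence folds as
well as real tRNAs (in calibration, 45 of 100 random 20-kb genomes
contained a fold scoring ≥ 42); with the cap it drops to 3 of 100.
Real tRNA stems do carry wobble pairs, but rarely more than one per
stem; the cap is a relaxable field of `ArmWindows`.

`pair_score` counts the nucleotides engaged in the four cloverleaf
stems (2 per base pair); the variable-arm internal stem (≥ 3 bp within
a ≥ 10-nt region) sets the arm flag used for Sec classification but
does not enter the score. The default reporting threshold is **42**
(the score of a canonical 7/4/5/5-stem tRNA), calibrated as above so
that pure random genomes are nearly always empty. Classification is a
pure function of anticodon and layout: CUA + (6-bp anticodon stem or
1-nt spacer) → `pyl`; UCA + variable arm → `sec`; a reassigned
anticodon without its hallmark → `ambiguous`; anything else →
`standard`.

The genome scan computes, for every position, the best achievable
stem pairing over all legal layouts using layered per-position arm
feasibility tables (run-length tables along anti-diagonals make every
stem query O(1)); this is exactly equivalent to folding every window
at every position — a property the tests assert directly — and then
re-derives the full layout of each above-threshold site with the
per-site exhaustive fold. Ties break toward fewer wobble pairs, then
enumeration order; reported candidates never overlap on the same
strand (greedy by descending score). No CCA tail, intron, or isotype
model: this is not a general tRNA annotator, it recognizes the three
structural classes the pipeline needs.

## SECIS detection (`secis`)

In bacteria the SECIS element is a hairpin of roughly 50 nt starting
just downstream of the recoded UGA. `find_hairpin` scans every
contiguous stem/loop placement in a bounded window and scores

    score = 2·WC + 1·GU − 2·mismatches,

with bulges modeled only as scored mismatches — no free-energy
minimization, no asymmetric internal loops — so the scan stays exact
and oracle-checkable. `scan_secis` extracts, for each U event of a
gene, the strand-aware 75-nt window after the UGA codon (never the
terminal stop, which carries no event), requires the hairpin to start
within 40 nt of the codon, and emits a hit when the best placement
passes the score threshold.

Defaults: `min_stem = 7`, loop 3–14 nt, `max_mismatch = 1`, threshold
**28**. The threshold is the calibrated value: on 20 000 random 75-nt
windows at 41% GC the pass rate is 0.218 at a threshold of 14, 3.5e-4
at 26 and 1.5e-4 at 28. A whole-genome dual-mode scan of 200 kb
produces ~580 candidate windows, so only ~28 keeps a null genome
essentially free of hits while any planted or real hairpin with ≥ 14
well-paired positions passes comfortably. A stricter base-identity
consensus (conserved loop nucleotides) is deliberately not hard-coded;
the structural model plus threshold is the whole detector.

**SECIS sharing.** Hairpins are strand-symmetric and ORF enumeration
is exhaustive, so an ORF on the opposite strand whose own in-frame UGA
happens to sit just upstream of a real SECIS can acquire the same
hairpin and become an extra (novel-group) selenoprotein call.
Benchmark evaluation therefore measures recall against planted truth
and decoy call rates, not raw call counts; consumers of real scans
should deduplicate calls by locus.

## Alignment and recoding calls (`align`, `recoding`)

Global protein alignment uses affine gaps (open 10, extend 1; a gap of
length k costs 10 + k) over BLOSUM62 extended to the non-canonical
letters: `O–O` and `U–U` score 11 (the matrix's maximum diagonal),
`O–K` and `U–C` score 5.5 (pyrrolysine is a lysine derivative,
selenocysteine the selenium analog of cysteine), any other pairing
with `O`/`U` scores −4, and `X` scores 0 against everything. The
engine is Biopython's `PairwiseAligner`; the test suite verifies its
scores against an independent three-matrix dynamic program on hundreds
of random pairs. Tie-breaking between equally optimal alignments is
the engine's deterministic first choice. **Percent identity** is
matches over residue-to-residue columns (gap columns, including
terminal overhangs, never enter the denominator), so one internal
indel between otherwise identical sequences leaves identity at 100.

Consequences of that definition, measured on random proteins: two
unrelated same-length sequences align at 22–25% "identity" (maximum
observed 32%), and a short sequence against a long one at 38–47% with
full coverage of the shorter. Thresholds are set accordingly:

- **Selenoprotein grouping**: a call (gene with a U event *and* a
  passing SECIS hit) is `known_family` when its best reference
  alignment reaches **50% identity** over ≥ 50% of the shorter
  sequence, else `novel`. Thirty percent — a common AAI-style bar —
  does not separate signal from random alignments under this identity
  definition.
- **Pyl verification** (`verify_pyl_site`): the candidate is aligned
  to a Pyl-containing reference; the report carries both 1-based site
  geometries (e.g. candidate 327 of 485 against an archaeal-style
  reference 334 of 483), whether an O column pairs with an O column,
  and the identity of the `window = 20` residues following the site.
  The denominator is the full window — residues missing after the
  site cannot be conserved — and the pipeline requires site alignment
  plus ≥ 60% downstream identity for a call. Both choices are what
  stops short random amber-readthrough ORFs from verifying against
  the reference.

`consensus_sequence` emits, per column, the letter whose frequency
among non-gap letters *strictly* exceeds the threshold (default > 50%),
else `X`; all-gap columns emit `-`; ties at the top frequency resolve
alphabetically (only reachable below 50%). `conserved_columns` applies
the same strict rule (default > 75%) and returns 1-based indices.
`dereplicate` is greedy representative clustering: sequences visited
by descending length (ties by id) join the first representative at
≥ 90% global identity, else found a cluster — the conventional
non-redundant-set construction at a 90% global identity threshold.

## Machinery inventory and neighborhoods (`machinery`)

Functional annotation is an *input* (a TSV of gene id, contig, gene
order index, family accessions) — profile-HMM search is out of scope.
The inventory marks the Sec system (selA Sec synthase, selB
Sec-specific elongation factor, selC Sec-tRNA, selD selenophosphate
synthetase) and the Pyl system (pylB/pylC/pylD biosynthesis, pylS
pyrrolysyl-tRNA synthetase, pylT Pyl-tRNA); a system is complete iff
every component is present. The tRNA components selC and pylT are
taken **only** from structural tRNA classification, never from
annotation labels — annotation of tRNA genes in MAGs is unreliable and
the structural evidence is the point of the scan. `copy_counts`
tallies every mapped occurrence (e.g. a duplicated CysA
sulfate/thiosulfate transporter, the route by which selenium oxyanions
enter the cell, counts 2). The bundled label→component map is an
editable default covering the named components plus the methylamine
neighborhood (TMA/DMA/MMA methyltransferases, cognate corrinoid
protein, ramA activase, metH) and the glycine-betaine
methyltransferase decoy.

`neighborhood` returns genes with index distance **strictly less
than** the radius (default 10 — "within fewer than 10 genes"), same
contig only; `cluster_conservation` reduces that to a per-genome
presence/order matrix around an anchor component, suitable for
rendering locus conservation across genomes.

## Genome comparison (`compare`)

ANI is fragment-based in the Goris-style convention used by the common
web calculators: consecutive 1020-nt fragments of the query; per
fragment the best match in the subject (exact 15-mer seeds vote on
contig/diagonal bands, edlib aligns the fragment into the best bands;
an `exhaustive` flag aligns against whole contigs instead and is
tested to agree with the seeded search on small genomes); a fragment
is used when it aligns at ≥ 70% identity over ≥ 70% of its length;
a direction's value is the mean identity of its used fragments and the
two-way ANI is the fragment-count-weighted mean of the two directions.
AAI computes best hits in both directions by global alignment
(qualifying at ≥ 30% identity over ≥ 70% of the shorter sequence),
keeps reciprocal best hits, and averages their identities. When
nothing qualifies the result is explicitly **undefined** (`None`,
serialized as JSON null) — unrelated DNA has ~25% identity, which is
noise, not an ANI of 0.

On a copy mutated at per-site rate µ (no indels) both metrics recover
100·(1−µ); the acceptance tests check ±0.5 (ANI) and ±1.0 (AAI, as an
average over substitution seeds — one realized draw on a ~25-protein
proteome fluctuates more than the band).

## The synthetic benchmark (`synthetic`)

The generator emulates, at desk scale, the genomic features the
pipeline detects in recoded environmental MAGs. Default `PlantSpec`: one
200-kb genome in 2 contigs at 41% GC carrying 10 selenoprotein genes,
5 Pyl methyltransferase genes with O at residue 327 of 485 (the
references include an archaeal-style homolog with O at 334 of 483,
related by 7 scattered insertions before and 9 deletions well after
the conserved site, plus 8% substitutions outside a protected ±
window), 5 decoy-UGA genes (in-frame TGA, ordinary coding sequence
downstream), 3 glycine-betaine-methyltransferase decoys (the Pyl
template with the amber site reverted to lysine and 25% drift — the
classic Pyl-free mis-annotation), 1 Sec tRNA, 1 Pyl tRNA, 3 standard
tRNAs, and an annotation table whose machinery cassette places
pylB/C/D, pylS and metH directly downstream of the first
methyltransferase and the cognate corrinoid protein at index distance
7 (< 10), with selA/selB and a duplicated cysA elsewhere. Everything
is reproducible from the seed.

Construction rules that make the truth table exact:

- every gene is preceded by an in-frame guard `TAA` immediately before
  its `ATG`, so the exhaustive caller recovers exactly the planted
  boundaries;
- coding sequence is reverse-translated with synonymous codons
  weighted toward the target GC; recoded sites are written literally
  (`O -> TAG`, `U -> TGA`); no other in-frame stops can occur, and the
  SECIS block (planted on a codon boundary, 15-bp perfect stem, 6-nt
  loop, 12–30 nt after the UGA) is redrawn until it is stop-free and
  is recovered by `find_hairpin` at exactly the planted offset;
- tRNA sequences are built from their layouts (stems fully paired,
  ≤ 1 wobble each) and refolded until the fold returns exactly the
  generating layout and class; single non-pairing bases flank each
  planted tRNA so the acceptor stem cannot extend into the background;
- decoys are **not** screened against the detectors — their call rate
  is the statistic being measured (measured: 0.4% of 500 decoy-UGA
  genes across 100 seeds; 0 of the glycine-betaine decoys).

What the benchmark does *not* emulate: real codon usage and
amino-acid composition (backgrounds and proteins are random at the
target GC), sequencing or binning error, operonic structure, homology
between background genes, bulged or consensus-bearing SECIS elements,
and tRNA sequence motifs beyond the cloverleaf. Passing tests
therefore demonstrate that the detectors recover exactly the
signatures they model, with calibrated false-positive behavior on
random sequence — not that those thresholds are optimal for real MAGs.

`mutate_copy` applies seeded per-site substitutions (uniform over the
three other bases, no indels) with an optional interval mask, so
ANI/AAI recovery and "mutate only intergenic regions" experiments are
one-liners.

## Pipeline and configuration (`pipeline`, `cli`)

`run_scan` chains gene calling → tRNA scan → SECIS scan →
selenoprotein calls → Pyl verification → machinery inventory, and
flags a genome **dual GCE** iff the Sec and Pyl machinery are both
complete *and* there is at least one selenoprotein call and one
verified Pyl protein. All thresholds live in `RunConfig` (YAML
round-trippable, validated, embedded in every report); every quantity
in the report equals the length of the underlying call list (schema
checked by `validate_report`). Reports are byte-identical across
reruns on the same inputs. The CLI (`gcescan scan | trna | secis |
compare | simulate`) is a thin click layer; the library is the
interface for anything programmatic.

Problem sizes used by the shipped checks: the benchmark genome is
200 kb (a full scan takes seconds), oracle equivalence runs on ~100
random contigs of 1–10 kb and 200 random protein pairs, the decoy
rate uses 100 seeded 16-kb genomes, and ANI/AAI recovery uses a
100-kb genome and a ~25-protein proteome — sizes chosen so the whole
suite re-runs in about a minute while every statistic is still
well-resolved.

## Known limitations

- The SECIS model is a single contiguous hairpin with mismatch-scored
  bulges; real bacterial SECIS elements with large asymmetric bulges
  or split helices score lower than their biology warrants.
- The tRNA model has no primary-sequence information (no T-loop or
  acceptor-end motifs); its specificity rests entirely on perfect
  stems, the wobble cap and the score threshold.
- Overlapping exhaustive ORFs can share one SECIS (see above).
- Identity-based grouping inherits the gap-free identity definition;
  its thresholds (50% known-family, 60% Pyl downstream) are calibrated
  against random-alignment baselines, not against curated protein
  families.
- ANI seeding assumes ≥ 15-mer exact matches survive between genomes;
  beyond ~20% divergence fragments fail the 70% filter by design.
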