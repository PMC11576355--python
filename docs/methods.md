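# Methods

## Scope and model

`exonact` annotates the exons of one gene at a time from its transcript
models (exon genomic coordinates, GC, plus per-exon coding sub-coordinates,
CGC). It is a deterministic combinatorial procedure, not a statistical
model: given the same transcript set it always produces the same reference
exon set, classifications, identifiers and attributions.

Coordinates are 1-based inclusive everywhere internally (GFF3 convention);
the GTF and TSV readers normalize on input, and only the BED writer
converts (to 0-based half-open). 5' and 3' always refer to transcript
orientation: on the minus strand exon 1 is the exon with the largest
genomic end, and an exon's transcript-5' boundary is its genomic end.

## Reference isoform and RSOEx

The reference isoform is the transcript with the most coding exons, with
ties broken by (1) longest total CDS and (2) lexicographically smallest
transcript id; a gene with no coding transcript falls back to the most
exons. Tie-breaks and the expansion order below are this package's own
convention — the selection rule alone does not make the procedure
deterministic, and identifiers are only meaningful if it is.

Expansion visits non-reference isoforms in descending coding-exon count
(then transcript id), exons 5'→3' within each, adding an exon iff it shares
zero genomic bases with every interval already in the set ("touching" at
adjacent coordinates is allowed; a single shared base disqualifies).
Passes repeat to a fixed point, then intervals are sorted in transcript
orientation and numbered 1..K. Non-overlap of the final set is asserted on
every build.

Relative positions are a property of the transcript set: adding or
removing transcripts can change the reference and renumber positions. The
CLI prints a warning to that effect; nothing in the data model promises
cross-release stability.

## Classification and the EUID codec

An exon overlapping exactly one reference exon with identical boundaries
is canonical; with shifted boundary/boundaries it is a splice-site variant;
overlapping two or more reference exons it is an intron-retention (IR)
event — regardless of whether the intervening intron is covered completely.
Exons overlapping nothing cannot occur after RSOEx construction (they would
have seeded it), and encountering one raises an internal consistency error.

The EUID packs six base-36 characters: cumulative coding status (C/N/M),
two characters of relative position (capacity 1295), one character of
occurrence (number of transcripts carrying exactly this interval,
saturating at 35), and one variant index per side. Distinct alternative
boundaries on a side are numbered 1, 2, … by distance from the canonical
boundary; ties are impossible because boundaries are distinct coordinates.
The per-character layout is this package's documented convention and is
isolated behind `encode_euid`/`decode_euid` so an alternative table can be
swapped without touching the classifier. Occurrence counts exact-interval
transcripts (not all transcripts touching the position); both readings are
defensible and the chosen one keeps occurrence consistent with the
uniqueness rule "one interval, one entity". IR events carry no sixth-column
code of their own; they are written as '+'-joined EUIDs of the canonical
entities they span, ascending by position.

Block I is the *cumulative* status — C if the exon is fully coding in every
transcript containing it, N if coding in none, M otherwise (including
partially coding UTR-edge exons). Per-transcript status (coding / partial /
noncoding) lives in the attribution records, keeping the EUID
transcript-independent so isoforms can share it.

## Residue attribution

Within a transcript the concatenated CDS is walked 5'→3'. Each codon's
residue is attributed to the exon contributing at least two of its three
bases; in the degenerate 1+1+1 split across three exons the middle base's
exon owns the residue. This makes residue→exon a total function, so
attributed ranges partition 1..L exactly. The majority rule is a
convention of this package (the residue genuinely belongs to two exons at a
junction); the independent per-base oracle in the fixture generator applies
the same tie rule, but derives everything from explicit base labels and
Biopython translation rather than interval arithmetic.

Stop-codon handling: the CDS is taken exactly as annotated; GTF
`stop_codon` features are appended to the CDS. Whether the stop is included
is inferred per transcript — from the attached protein length when
available (CDS = 3(L+1) means included), otherwise a frame-complete CDS is
assumed to include it. The stop codon is attributed to no residue but its
bases advance phase bookkeeping. A CDS whose length is not divisible by 3
is flagged `frame_incomplete`; attribution still runs and the trailing
sub-codon is unattributed. Validation reports a CDS/protein length
mismatch as a *warning* when the full codons still yield the protein
length (the frameshift fixtures are exactly this case) and as an *error*
otherwise.

Translated-CDS vs. attached-protein comparison (`verify_translation`,
standard nuclear code) is a warning, not an error: selenoproteins and other
genetic-code exceptions exist.

## Feature mapping and protein back-mapping

Protein features arrive in protein coordinates as a flat TSV (with a
column-mapping option for Pfam-style tables) or as a per-residue H/E/C
secondary-structure string converted to intervals. Mapping intersects each
feature with each exon's attributed residue range; conservation (every
feature residue in exactly one segment) is asserted per feature.
Secondary-structure fractions are emitted per state *and* as the
helix+strand sum, since "fraction structured" is used both ways.

The back-mapper's candidate set is every per-exon attributed peptide of
every coding transcript, minimum length 5 aa by default (shorter peptides
produce spurious hits; junction residues make peptides of the same exon
differ by ±1 terminal residue across transcripts, and all variants are
candidates). Scanning is greedy left-to-right, longest match first; ties
between identical peptide strings resolve to the lowest-position EUID with
the alternatives recorded in a note field. Neither the search order nor
the length floor is canonical; both are documented package choices.

## Synthetic data generator

`exonact.fixtures.generate_fixture` emulates a RefSeq-style multi-isoform
gene: a reference isoform of K exons (default 7) — exon 1 pure 5'UTR, CDS
starting inside exon 2 and ending inside exon K — plus one transcript per
requested event: in-frame exon skip, frameshifting skip (skipped length
≢ 0 mod 3), alternative 5'ss and 3'ss (boundary shifts that are multiples
of 3, 9–21 nt), intron retention (two adjacent exons merged over an intron
whose length is a multiple of 3), cassette-exon gain in the 5'UTR intron,
alternative translation initiation (internal ATG), and alternative
termination (a distinct terminal exon inside the last intron). Exon
lengths default to 60–150 nt, introns 40–180 nt (≥ 30 enforced), all drawn
from a seeded RNG; identical specs generate identical output.

Sequence design: background bases are drawn from {A, C, G}; T enters only
through placed motifs — ATG at translation starts (followed by a forced
non-A base), TAA at stops, GT at splice donors (followed by a forced C),
AG acceptors. Every stop codon requires a T, so no reading frame of any
generated transcript can hit a premature stop, whatever events it
combines. The truth table (positions, classifications, variant indices,
occurrences, coding statuses, residue ranges, proteins) is computed from
the construction itself and from the per-base translation oracle — the
annotator is never consulted — so fixture tests genuinely cross-check two
code paths.

What the generator does **not** emulate: realistic base composition or
codon usage (the no-T background is deliberately artificial), splice-site
strength, overlapping genes, trans-splicing, multi-gene loci, annotation
errors, or genome-assembly idiosyncrasies. Passing the fixture suite
demonstrates the combinatorial machinery is correct under clean
annotations; it says nothing about robustness to inconsistent real-world
gene models beyond what the validator catches.

The worked-example gene (`worked_example_gene`) is a synthetic, hand-built
two-isoform gene reproducing a published isoform relationship (four of six
exons shared; one isoform with a 5'ss-truncated sixth exon and a
non-coding seventh exon); it stands in for a live annotation download and
is labelled synthetic in code and docstrings.

## Problem sizes and numerical choices

The test-suite and the acceptance script use 500 randomized fixtures for
truth-table equivalence, 40–60 for partition/reflection properties, 25 for
back-mapping round trips, and the EUID codec is checked exhaustively over
positions 1–50 × occurrences 1–35 × variant indices 0–10 (635 250 codes);
these sizes exercise every event combination many times over while keeping
a full run in tens of seconds. There is no floating-point numerics
anywhere in the pipeline — all quantities are integers or exact string
codes — so no tolerances apply; secondary-structure fractions are the only
ratios and are reported as exact rational results of integer counts.

## Known limitations

- Mutually-exclusive-exon pairing and event-level statistics (PSI etc.)
  are out of scope; IR detection covers the ≥ 2-overlap rule only.
- Single-chromosome, single-strand genes only; trans-splicing and
  multi-contig genes are rejected by validation.
- EUID capacity: 1295 relative positions, 35 variant indices per side;
  beyond that a capacity error names the gene rather than silently
  wrapping.
- The occurrence character saturates at 35, so `decode(encode(x))` is the
  identity only for occurrences ≤ 35 (codec tests respect this bound).
- Alternative genetic codes and ribosomal frameshifts are not modelled.
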