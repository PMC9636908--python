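# Methods

## Coordinates and orientation

All in-memory positions are 1-based inclusive, matching VCF and `g.`
genomic notation; BED-dialect inputs are shifted (`start + 1`) at the
boundary.  Offsets around a branchpoint (BP) are expressed in
*transcript* orientation: offset 0 is the BP base, negative offsets are
upstream (toward the 5′ss).  On the minus strand a transcript offset
`o` maps to genomic position `pos − o`, and motifs are
reverse-complemented on extraction.  Distance to the 3′ splice site is
defined so the final intron base (the G of the acceptor AG) is −1; a BP
with 20 intron bases between itself and the intron end, inclusive, is
at −20.  This convention makes the distances printed in clinical
reports of BP variants directly reproducible.

## Consensus levels and positional adjustment

The BP consensus YTNAY is matched at five-nucleotide resolution over
offsets [−3, +1]; relaxed levels are nested: 1 = YTNAY, 2 = YTNA,
3 = TNA, 4 = YNA, 0 = none, and the reported level is the most
stringent match.  Any N in the genome yields level 0 — unknown sequence
never matches.

Raw BP calls from lariat-spanning reads are frequently mislocated by a
base or two (the reverse transcriptase stutters across the 2′–5′
junction).  Each raw position is therefore screened at candidate
offsets d ∈ {0, ±1, ±2} in transcript orientation and moved to the
nearest candidate whose centered 5-mer perfectly matches YTNAY; when
+d and −d both match, the transcript-downstream candidate wins, because
BPs closer to the 3′ss are the more likely functional ones.  A record
with no match in the window is left untouched, so datasets whose BPs
are genuinely non-adenine (e.g. cytosine-BP collections) pass through
unchanged.  Records landing on the same (contig, position, strand)
merge, hence the adjustment delta is always ≤ 0.  Adjustment is
idempotent: an adjusted record is a fixed point.

Datasets are adjusted independently and then integrated; a unique
position supported by both evidence classes is an mBP, otherwise eBP or
cBP.  Opposite strands at one coordinate are distinct BPs.  BP names
follow `{m|e|c}BP_{contig}_{pos}_{strand}_{base}` with ASCII `+`/`-`.

## Intron catalog

Introns are the gaps between consecutive exons, deduplicated by
(contig, start, end, strand) with transcript memberships accumulated
and intron numbers counted 5′→3′ per transcript.  Spliceosome type
defaults to a dinucleotide heuristic (AT–AC termini ⇒ minor, all else
major) that an explicit curated list overrides — necessary because most
minor (U12-type) introns actually carry GT–AG termini.  Only BPs at
distances [−3, −100] are retained; distal BPs involve recursive
splicing and long-range structure and are out of scope.  Ranks order a
3′-proximal intron's BPs by ascending |distance| (two BPs cannot tie on
one strand: equal distance would mean equal position).

## BP–snRNA binding-energy estimate

A deliberately simple stand-in, reported for descriptive comparisons
and never used by the prioritization score.  The BP bulges out of the
duplex; the six flanking motif positions (offsets [−5, −1] and +1) pair
antiparallel against a snRNA branch-recognition hexamer, scoring
G:C = 3, A:U = 2, G:U = 1 (wobble), mismatch = 0; the energy is the
negated sum (lower = stronger).  The U2 hexamer is GUAGUA.  The U12
recognition register is not well established; the default GAAGGA is the
antiparallel complement of the minor-intron BP consensus flanks and is
configurable.  A perfect duplex always scores strictly below any
single-mismatch variant of itself.

## Variant typing and detection

VCF rows are split per ALT; a shared suffix then prefix is trimmed, and
one remaining shared leading base of an indel (the VCF anchor) is
stripped.  Left-alignment is *not* performed — inputs are expected to
be normalized; trimming alone suffices for typing.  Types are `snv`
(interval [pos, pos]), `x nt-deletion` (the deleted bases), and
`x nt-insertion` (the breakpoint).  A complex substitution with both
trimmed sides > 1 nt is typed by its REF side (the bases it removes are
what can disrupt the BP window) and flagged.

A variant disrupts a BP when it touches the window [−2, 0]: an SNV hits
its single offset; a deletion hits every window offset whose genomic
site it removes (so partial overlaps report partial hits, and a
deletion spanning the window reports −2|−1|0); an insertion whose
breakpoint falls strictly inside the window reports both flanking
offsets and is flagged low-confidence, since insertion effects on
splicing are hard to predict — they are kept visible rather than
silently dropped.  Output is one row per (variant, BP, transcript
membership), sorted deterministically; variants on contigs absent from
the database are skipped with a warning, and a side report lists
variants with no hit.

## Prioritization score

The score is an additive reconstruction of the published strategy; the
original weight table is not public, so the weights live in
`ScoreWeights` and can be replaced wholesale.  Defaults (maximum 10):

| term | values |
|---|---|
| hit | 3 full-motif deletion or offset 0; 2 offset −2; 1 offset −1 |
| rank | 2 only BP; 1.5 rank 1 of ≤ 3; 1 rank 2 of ≤ 3; else 0 |
| consensus | 2 / 1.5 / 1 / 0.5 / 0 for levels 1 / 2 / 3 / 4 / 0 |
| sources | 1 if ≥ 2 sources; +0.5 if mBP, capped at 1 |
| population | 1 none at BP and BP−2; 0.5 singleton/rare; 0 common |
| conservation | 1 if GERP > 0 or PhyloP > 0 at the BP; 0.5 if unknown |
| penalty | −1 for a T↔C SNV at BP−2 |

The total is clamped to [0, 10]; ≥ 3 is the recommended follow-up
threshold.  Missing conservation scores 0.5 rather than 0 because
splicing elements evolve quickly and low conservation does not imply
low function.  The score is monotone in every single factor.  Exactly
1% MAF classes as common (the cut is MAF ≥ 1%); singleton requires an
AC track value of 1.

## Synthetic data

The generators emulate single-intron genes: two 150 nt exons around an
intron (default 100–200 nt) with transcript-sense GT…AG termini, on
either strand.  Branchpoints are planted as G-padded cassettes — G at
offsets −5, −4, +2, +3 around a 5-mer core built to match exactly the
requested consensus level.  The G padding provably blocks YTNAY at
shifts of ±1 and ±2 whatever the random background, so planted
positions are stable under positional adjustment and off-by-one raw
calls adjust onto their intended neighbors.  Off-by-one records are
planted only next to level-1 cores (adjustment requires a YTNAY
target).  Fixtures carry a manifest of every planted feature; tests
read expectations from the manifest, never from the generator's code.

The 48-locus validation panel reproduces each published pathogenic
variant's *geometry* — variant type, deletion length, distance to the
3′ss, rank/total (co-BPs planted at ±7 and ±14 nt), disrupted offsets,
and the not-detected rows (documented BP placed 10 nt transcript-
upstream of the variant, outside its window) — on one synthetic gene
per variant; real genomic coordinates are deliberately not reproduced,
which avoids any reference-genome dependency while preserving the
validation surface.  Strand per locus is chosen so the printed genomic
REF/ALT alleles are consistent with the transcript-sense consensus
core.  Per-row consensus level, BP class, population, and conservation
attributions are only published as aggregates (24/8/7/1 levels,
19 mBP / 1 eBP / 20 cBP, 38 clean + 2 rare, 33/5/2 conservation); the
panel fixes them arbitrarily but consistently with those totals.

What passing the panel shows — and does not.  The panel exercises the
detection and ranking engine on exact printed geometry; it does not
validate performance on real genomes (no repeats, no alternative
isoform complexity, no real allele-frequency spectra, uniform intron
lengths), nor the genome-scale database counts, which require the ten
original BP datasets.  Those behaviors are covered instead by
property-based suites: adjustment idempotence and non-positive delta on
fuzzed data, merge order-independence, consensus nesting over all 4^5
motifs, brute-force equivalence of mapping and detection (about 1,000
variants against 200+ BPs on both strands), strand-mirror invariance of
distances/ranks/hits, and window fuzzing confirming hits occur exactly
at offsets {−2, −1, 0}.

## Numerical and degenerate-input choices

Empty record sets are errors for composition and occupancy summaries
(an undefined percentage is worse than an exception); an empty track is
a valid 0.0 occupancy.  Missing track values are represented by absence
and rendered `.`, distinct from 0.  Problem sizes in the test suite
(tens of genes, ~1,000 variants, 300-trial adjustment fuzzing) were
chosen so the whole suite runs in a few seconds while still covering
both strands and all rank geometries.
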