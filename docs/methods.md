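# Methods

## The Kozak Similarity Score

Translation initiation in eukaryotes is strongly influenced by the
nucleotides surrounding the start codon: the Kozak context, with its
well-known purine preference three nucleotides 5' of the codon and G
preference immediately 3' of it.  Noncanonical initiation — at ATGs
upstream of the annotated start, or at the nine *near-cognate* codons
that differ from ATG by a single nucleotide — is likewise
context-dependent, and upstream initiation events in long 5'UTRs have
been repeatedly implicated in the translation of oncogenic protein
variants.

The Kozak Similarity Score (KSS) quantifies context quality.  For a
codon with ten fully defined flanking nucleotides on each side,

```
KSS(codon) = (1 / KSS_bits_max) * Σ_{p=1..20} bits(nucleotide_p)
```

where positions 1–10 are the upstream flank and 11–20 the downstream
flank (both 5'→3'), `bits(n_p)` is the height of nucleotide `n` at
position `p` in a sequence-logo-style matrix, and `KSS_bits_max` is the
sum of the per-position maxima.  The codon's own three nucleotides never
enter the sum, so KSS is a pure context score: two codons with identical
flanks score identically regardless of codon identity.  The score lies
in [0, 1] and equals 1 exactly when every flank position carries a
maximal-height letter.

### The default bits matrix

The matrix is a free parameter of the method; any 20×4 table of
non-negative bits can be loaded from TSV.  The packaged default is
constructed by the standard logo convention — `height(p, n) =
freq(p, n) × IC(p)` with `IC(p) = 2 + Σ_n freq log2 freq` bits — from
published vertebrate Kozak-context nucleotide frequencies (the classic
GCCGCCACC|ATG|G compilation) for Kozak coordinates −9..+6, with a mild
GC-skewed background at the distal positions (−10, +7..+13), where real
transcripts show little preference.  Consequences worth knowing:

* flank position 8 is Kozak −3 (purine-dominant, A tallest), position
  10 is Kozak −1 (C tallest), position 11 is Kozak +4 (G tallest);
* a uniformly random context scores ≈ 0.55–0.60 in expectation under
  this matrix — the natural "baseline" level against which candidate
  contexts are judged;
* several distal positions carry very low information (heights near
  zero) and two letters can tie exactly; ties are legitimate and
  propagate to exact KSS ties between codons with identical flanks.

Scores computed with different matrices are not numerically
interchangeable.  Published medians obtained with other groups'
matrices can only be reproduced by loading those matrices; the default
reproduces the *structure* of such analyses (ordering, ranks,
directional tests), not external absolute values.

## Candidate enumeration and ranking

Candidates are ATG plus the nine near-cognate codons, enumerated at
every offset (all three reading frames).  "Upstream" means a codon
*starting* strictly before the main-TIC start, including codons that
overlap the main TIC boundary — a scanning ribosome reaches them first;
a stricter 5'UTR-only region (codon entirely before the CDS) is also
available.  Candidates within 10 nt of either sequence end lack full
flanks; they are flagged, excluded from scoring and ranking by default,
and reported as such (lenient zero-bit scoring of ambiguous characters
exists but is never silent).

Ranks are ordinal within a pool, 1 = highest KSS, so at most one
candidate per transcript is rank 1.  Exact KSS ties (identical flanks)
are broken in favour of the 5'-most codon, again following the scanning
direction; competition ranking ("1-2-2-4") is available behind a flag.
Noncanonical TICs are ranked against all upstream ATG + near-cognate
codons of their transcript; canonical ATGs are ranked against all ATGs
of the full transcript.

## Peptide-evidence inference

N-terminal peptides are matched exactly against the three forward-frame
translations (inputs are mRNA-sense, so reverse frames are meaningless
here; no mismatches are allowed because the operation is overlap
finding, not alignment).  A peptide beginning with Met marks its own
first codon as the TIC.  A peptide without an N-terminal Met whose N
terminus is acetylated is assumed to have lost exactly the initiator
Met, placing the TIC one codon 5' of the match, in frame — but only if
that codon is ATG or near-cognate; otherwise more than Met was likely
cleaved, the position is unreliable, and the evidence is excluded
rather than chased further upstream.  By default the same upstream-codon
logic is applied to non-acetylated Met-less peptides (the inference does
not depend on the acetyl group itself); a strict mode confines it to
acetylated evidence.  Kept TICs are deduplicated on (transcript,
position, codon) so counts refer to unique TICs, and classified as
N-terminal extensions (in frame with the CDS, no intervening in-frame
stop), novel upstream products (out of frame or stop-separated),
downstream products, or the main TIC itself.  An optional flag drops
ATG-initiated TICs to isolate the noncanonical ones.

## Statistical comparisons

All group comparisons are one-sided Mann–Whitney U tests of "first
group stochastically greater".  With pooled sample size ≤ 16 the
p-value is exact, by enumerating all C(n1+n2, n1) labelings of the
pooled midranks (ties handled naturally); the cost is at most
C(16, 8) = 12 870 evaluations.  Larger samples use the normal
approximation with midrank tie correction in the variance and a 0.5
continuity correction — the study-sized groups this tool targets
(tens to thousands per group) are safely in the asymptotic regime, and
the two methods agree within 0.005 absolute p at the 8 + 8 boundary.
Degenerate fully-tied input returns p = 0.5.  U is reported for the
first group with tied pairs counted 1/2, so U(x, y) + U(y, x) = n1·n2.

Outlier handling is never automatic: an explicit flag removes the
single lowest value of the first KSS group and the result records that
it did, so both the trimmed and untrimmed p-values are obtainable.

The random-codon baseline draws a fixed number of fully-flanked codon
positions (default 4) uniformly without replacement per transcript and
scores them; it is seed-deterministic and skips (with a warning)
transcripts shorter than one flanked codon.

## The synthetic cohort generator

The generator produces the study conditions the analyses are validated
under.  Per transcript: a 5'UTR length drawn from a log-normal
parameterised by its median (strictly positive and right-skewed, like
real UTR length distributions), i.i.d. background nucleotides at a
configurable composition (uniform by default), a CDS opened by ATG,
built from non-stop codons and closed by a stop, and a short 3'UTR.
Two UTR regimes are the reference conditions for cohort comparisons: a
long-UTR regime with median 205 nt and a short-UTR regime with median
112 nt, the medians reported for cancer-associated genes bearing
upstream noncanonical TICs versus genes without a cancer link; the
log-scale spread defaults to 0.6.

Context strength is one continuous knob.  A planted codon's flanks are
drawn per position with probability ∝ `exp(c · h / h_max)`, the
softmax of heights normalised by the per-position maximum: `c = 0` is
uniform background, expected KSS increases monotonically in `c`, and
for matrices with well-separated maxima the consensus dominates by
`c ≈ 50`.  Defaults: planted upstream TICs at `c = 12`, the main ATG
context at `c = 8` — both clearly above background, with the
noncanonical context the stronger, mirroring the direction of the
cohort analyses this emulates.  Planted codons sit at uniform random
5'UTR positions at least 10 nt from the UTR start and 23 nt apart and
from the main-TIC context, so no planted context can overwrite another
planted codon; UTR draws too short for the requested plantings are
redrawn, and a spec that cannot be satisfied raises an error naming the
transcript.  The main ATG's downstream flank is rejection-sampled so
the CDS stays stop-free; the single codon straddling the flank boundary
is repaired (third base → C) if a stop arises there.  Everything is
reproducible byte-for-byte from the seed.

Synthetic peptide evidence emits, per planted TIC, the N-terminal
peptide of its product — initiator Met regardless of codon identity,
then the downstream in-frame translation (default 8 residues, truncated
at stops, discarded below 5) — with a configurable fraction of
Met-excised, acetylated peptides, plus optional decoys whose upstream
codon is deliberately not a candidate and which must therefore be
excluded by the filter rules.

### What the generator does not emulate

Background sequence is i.i.d.; real 5'UTRs have GC-rich composition,
secondary structure, uORF conservation and codon-usage signals.  The
planted-context model treats positions independently, exactly as the
KSS itself does, so recovery experiments validate the scoring and
ranking machinery under the model's own assumptions — they do not show
that real noncanonical TICs are recoverable at these rates, nor do they
address IRES-mediated or structure-dependent initiation.

## Numerical and design choices

* Coordinates are 0-based half-open internally, 1-based inclusive in
  every user-facing table.
* Scores are computed in double precision and printed to 3 decimals.
* The annotation report bins KSS at fixed global edges 0.50 / 0.62 /
  0.72 / 0.80 into blue, teal, green, orange, red (low → high);
  right-closed bins, user-overridable.  Fixed edges keep colors
  comparable across transcripts; 0.80 marks the level above which
  roughly half the noncanonical TICs in the motivating analyses score.
  When two candidate codons overlap, only the 5'-most is highlighted
  inline (the rendering must reproduce the sequence on concatenation)
  but both appear in the report's codon list.
* Validation problem sizes: the scoring oracle runs on 1000 random
  matrix/context pairs; enumeration on 100 transcripts of 50–5000 nt;
  ranking on 200 transcripts; null calibration on 2000 Mann–Whitney
  replicates at n = 30 + 30; UTR-regime separation on 20 replicate
  cohort pairs at n = 85 vs 3615 with compact CDS lengths (90–300 nt),
  which leave the UTR comparison untouched while keeping cohorts small.

## Known limitations

* The default matrix is a documented reconstruction from published
  frequency tables, not any specific group's scoring matrix; absolute
  scores are matrix-relative.
* Peptide matching reports all loci of a multi-mapping peptide and
  leaves disambiguation to the caller.
* Exactly one codon of N-terminal cleavage is modelled; evidence
  requiring deeper cleavage is excluded, not searched.
* Transcripts are plain mRNA-sense sequences: no splice-aware genome
  coordinates, no minus strand.
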