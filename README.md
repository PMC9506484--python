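# kozascan

Scanning, scoring and ranking of translation initiation codons (TICs)
in mRNA transcripts by Kozak context similarity.

Eukaryotic ribosomes initiate translation not only at the annotated ATG
of a gene's main protein but also at upstream ATGs and at *near-cognate*
codons (the nine codons one substitution away from ATG: CTG, GTG, TTG,
ACG, AAG, AGG, ATA, ATC, ATT).  Such noncanonical initiation can produce
N-terminally extended or entirely novel proteins and is repeatedly
implicated in cancer biology, where affected genes tend to carry long
5'UTRs.  Whether a codon is used for initiation depends strongly on its
flanking nucleotides' resemblance to the Kozak consensus.

`kozascan` quantifies that resemblance with the **Kozak Similarity
Score (KSS)**: for a codon with ten nucleotides of flank on each side,

KSS(codon) = (1 / KSS_bits_max) · Σ<sub>p=1..20</sub> bits(nucleotide<sub>p</sub>)

where `bits(n_p)` is a sequence-logo height (positions 1–10 = upstream
flank, 11–20 = downstream flank) and `KSS_bits_max` the sum of
per-position maxima, so KSS ∈ [0, 1] and the codon itself contributes
nothing.  Around this score the package provides, for bioinformaticians
studying alternative translation initiation:

* a replaceable 20×4 bits matrix (validated TSV I/O) plus a packaged
  default built from published Kozak-context frequencies;
* exhaustive enumeration of ATG/near-cognate candidates in any
  transcript region, with KSS-based ordinal ranking (rank 1 = best in
  pool, 5'-most wins ties);
* inference of TICs from N-terminal peptide evidence under initiator-Met
  excision rules, with product classification (N-extension / novel
  upstream / downstream / main);
* one-sided Mann–Whitney comparisons (exact for small samples, tie- and
  continuity-corrected normal approximation otherwise) of KSS groups and
  5'UTR length cohorts, plus a random-codon KSS baseline;
* a synthetic cohort generator that plants TICs in contexts of
  controllable Kozak similarity and reproduces two 5'UTR-length regimes
  (median 205 nt vs 112 nt), so the whole pipeline is testable offline;
* a color-coded transcript annotation report (text or HTML) and a CLI.

## Worked example

```python
import numpy as np
from kozascan import (CodonContext, SyntheticCohortSpec, compare_kss_groups,
                      default_kozak_matrix, extract_context, generate_cohort,
                      kss_score, rank_of, rank_upstream)

matrix = default_kozak_matrix()

# score a CTG in the matrix's consensus context, and in a poor one
print(f"{kss_score(CodonContext('CGCCGCCACC', 'CTG', 'GCCCCCCCCC'), matrix):.3f}")
print(f"{kss_score(CodonContext('TTATTTATAA', 'CTG', 'ATTTATATTA'), matrix):.3f}")

# simulate 50 transcripts, each with one strong-context upstream CTG
spec = SyntheticCohortSpec(n_transcripts=50, planted_tic_codons=("CTG",), seed=42)
transcripts, truth = generate_cohort(spec, matrix)
ranks = [rank_of(rec.planted[0].position, rank_upstream(t, matrix))
         for t, rec in zip(transcripts, truth.records)]
print(f"planted CTG ranked 1 in {np.mean(np.array(ranks) == 1):.0%} of {len(ranks)} transcripts")

# do the planted (noncanonical) contexts beat the canonical ATG contexts?
nc = [kss_score(extract_context(t, r.planted[0].position), matrix)
      for t, r in zip(transcripts, truth.records)]
ca = [kss_score(extract_context(t, t.main_tic_start), matrix) for t in transcripts]
res = compare_kss_groups(nc, ca)
print(f"median KSS noncanonical {res.medians[0]:.3f} vs canonical {res.medians[1]:.3f}, "
      f"one-sided p = {res.p_value_one_sided:.2e}")
```

prints

```
1.000
0.421
planted CTG ranked 1 in 100% of 50 transcripts
median KSS noncanonical 0.999 vs canonical 0.985, one-sided p = 1.13e-06
```

The first two lines show the score range: a perfect-consensus context
scores 1.000, an AT-rich one 0.421 (uniform random context averages
≈ 0.55–0.60 under the default matrix).  The planted upstream CTGs sit in
deliberately strong contexts, so ranking every upstream ATG/near-cognate
candidate by KSS puts them first in every transcript, and their score
distribution is detectably shifted above the canonical ATGs'.

The same pipeline is available from the shell:

```sh
kozascan simulate --n-transcripts 50 --plant CTG --seed 42 --out-prefix demo
kozascan rank --fasta demo.fasta --annotation demo.annotation.tsv \
              --pool upstream --out demo.ranks.tsv
kozascan annotate --fasta demo.fasta --annotation demo.annotation.tsv \
                  --format html --out demo.html
```

Real transcripts enter as FASTA plus a sidecar TSV
(`transcript_id  main_tic_start_1based  [cds_end_1based  gene]`) or as
GenBank records with a CDS feature; a custom bits matrix as a TSV with
columns `position A C G T` (rows 1–20).  Note that KSS values are
matrix-relative: reproducing scores published with another group's
matrix requires loading that matrix.

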