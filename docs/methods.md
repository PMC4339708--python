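# Methods

## The annotation problem

bHLH (basic helix-loop-helix) transcription factors are identified in a
predicted proteome not by overall sequence similarity — family members are
highly divergent outside the domain — but by a profile model of the
conserved domain itself.  Once detected, a domain supports several
downstream classifications that this package reproduces as one pipeline:
DNA-binding potential read from basic-region residues, intron/exon
architecture within the domain, subfamily membership, homeologous
(whole-genome-duplication) copy structure, and expression category.

## Canonical coordinates

Every detected domain is projected onto a fixed 57-column scheme: basic
region 1–13, helix 1 at 14–28, a variable loop of 5–14 residues occupying
columns 29–42 (left-aligned, gap-padded), and helix 2 at 43–57.  All
residue rules are expressed in these coordinates (E at 9, L at 23, …).
Loop residues and loop insertions are re-packed left-aligned, so the loop
length is the emitted residue count, not a column count; loops outside
5–14 are flagged atypical but kept.  Canonical positions that the local
alignment trimmed at either end are extended from the flanking protein
residues, never across the loop — atypical HLH proteins score poorly over
the basic region, and without extension their true (non-basic) residues
would be invisible to the rules and the curation span checks.

## Profile HMM

The detector is a Plan-7-style profile HMM without flanking self-loop
states: match/insert/delete states per node, no D↔I edges, local behavior
from free (unscored) entry into and exit from any match state.

* Match columns: gap fraction < 0.5 (configurable).
* Pseudocounts: Laplace +1 on emission counts, +0.1 on transition counts.
  Dirichlet mixtures would sharpen emissions slightly but add opaque
  hyperparameters; the flat scheme keeps every number in a test derivable
  by hand.
* Scores are log2-odds (bits) against a uniform background (configurable).
* Viterbi is exact; its correctness is established against a brute-force
  enumeration of all local state paths on small models (L ≤ 4, sequences
  ≤ 6), which is feasible and entirely independent of the DP code.
* E-values come from an empirical Gumbel fit (`scipy.stats.gumbel_r`,
  maximum likelihood) to the maximal bit scores of seeded i.i.d.
  background sequences (default 200 sequences of length 400).  The
  survival function is computed via `expm1`; the naive `1 − cdf` form
  collapses to zero in the far tail and destroys E-value monotonicity.
  Absolute E-values are calibration-specific and are used only to apply
  thresholds (domain reporting at E ≤ 1e-3, motif corroboration at
  E ≤ 1e-4), not to reproduce any external tool's numbers.

A `*` in a protein never aborts scanning: each stop-free segment is
searched separately and coordinates are shifted back, so curation — not
the scanner — decides the fate of sequences with internal stops.

## Residue rules and curation

Binding classification reads four flags (H/K₅, E₉, R₁₂, R₁₃; a gap never
satisfies a rule) plus the count of {R, K, H} at positions 1–13:

| condition | category |
|---|---|
| E₉ ∧ R₁₂ ∧ (H/K₅ ∧ E₉ ∧ R₁₃) | G-box binder |
| E₉ ∧ R₁₂ | E-box binder |
| otherwise, ≥ 5 basic | non-E-box binder |
| otherwise, ≤ 4 basic | non-binding HLH |

The bare H/K₅-E₉-R₁₃ motif count (`gbox_raw`) is reported separately in
the census because the motif as classically stated does not mention R₁₂,
while a G-box is an E-box subtype; the category therefore additionally
requires R₁₂ so that G-box callers nest inside E-box callers.  The rare
E₉-without-R₁₂ configuration falls through to the basic-count branch and
remains visible through its flags and a dedicated census counter.

Curation flags internal stops (`*` before the final residue) and
incomplete domains (no hit, or an empty basic/helix1/helix2 span after
mapping).  Mismatch counts against a core-11/defined-19 allowed-residue
table are computed and reported; the historical cutoffs (>6/>11) are *not*
enforced by default, because enforcing them removes genuine atypical
members.  The shipped table is a synthetic reconstruction (the cited
residue identities are not published in machine-readable form) and is
plainly labelled as such; it is configuration, not ground truth.

## Families and trees

Subfamily assignment is a distance surrogate for a full phylogenetic
bootstrap: nearest reference exemplar by p-distance over shared non-gap
canonical columns (Poisson correction −ln(1−p) optional), with the margin
to the best other-family exemplar and family-diagnostic motif hits
(Motif 40 → Family X, E ≤ 1e-4) deciding ambiguity (margin threshold
0.05 substitutions/site).  Ties break lexicographically on (family,
reference id).  Neighbor joining (via scikit-bio) serves as the tree
output; it is exact on additive matrices, which the tests exploit both as
a property check and on a closed-form 4-taxon example.

## Gene structure

GFF3 is converted once, at parse time, from 1-based inclusive to 0-based
half-open.  An intron's domain position is the canonical position of the
codon immediately 5′ of it; for phase-1/2 introns that is the interrupted
codon, with the phase recorded separately.  The walk is in transcription
order, so minus-strand genes are handled identically to their plus-strand
mirrors.  Pattern letters are presentation labels over the authoritative
matched-site sets; the defaults place the three conserved sites at
canonical 16/25/48, the alternative (pattern F) site at 5, and the
pattern-G pair at 20/52, each matched within ±2 columns.  These site
coordinates are configuration: the published figures define the patterns
by example genes whose coordinates are not transcribable from text.

## Homeologs, orthologs, expression

Homeolog groups are the union-find closure of evidence pairs with CDS
identity ≥ 90% (inclusive) inside a shared duplication block; both the
threshold and the block requirement are configurable and echoed in output
headers.  Reciprocal best hits use strict filters (E < 1e-25,
identity > 50%) with the tie chain bit score → E-value → subject id.

Expression categories use two invented but explicit thresholds: detection
at ≥ 1.0 normalized units and seed enrichment at ≥ 5× the best non-seed
tissue (boundary inclusive).  "Aerial" for the nodule-preferential rule is
{leaf, pod wall, seed stages}; root is deliberately excluded because root
and nodule expression commonly co-occur.  Precedence: not expressed >
pod-wall-only > nodule-preferential > seed-enriched > ubiquitous
(root ∧ leaf ∧ ≥ 1 seed stage) > tissue-restricted.

## Synthetic data: what it emulates, what it does not

The generator builds the whole input bundle from one seed: proteome with
planted domains and decoys, mutually consistent GFF3 + CDS, homeolog
evidence, expression matrix, and a ground-truth manifest.

* Family structure is a star: one master domain consensus; each family
  diverges from it at rate 0.30 (rule and anchor positions protected) and
  carries its own loop length (uniform 5–14).  Genes mutate from their
  family consensus at rate 0.05 with rule positions protected.
* The master's rule positions are binder-like (H₅, E₉, R₁₂, R₁₃, plus a
  basic-leaning basic region), reflecting that most family members bind
  DNA; the HMM training alignment consists of category-enforced domain
  draws, mirroring the mixed composition of a real curated seed alignment
  (this matters: training on raw consensi makes atypical basic regions
  score so badly that local alignment trims them).
* Binders are planted with 7 basic residues, non-binders with ≤ 3, so a
  single point mutation rarely crosses the 5-vs-4 classification
  boundary; hydrophobic anchors 23/45/52/55 are drawn L (or I/L/V) with
  probability 0.97.
* Homeolog copies keep the founder's domain verbatim (flank drift at 3%
  plus synonymous substitutions tuned to the 96% CDS identity target);
  members therefore share family/binding/intron truth, as recent
  duplicates do.
* Mixture defaults follow the reported family proportions (≈58% G-box
  motif, ≈21% non-binding; intron A 31%, D 43%, intron-free 12%; copy
  spectrum {1,2,3,4,6}; 88% expressed, 47% of those ubiquitous), so
  synthetic censuses resemble the published figures without being fitted
  to them.
* Not emulated: realistic codon usage or splice-site consensus, empirical
  expression distributions, non-uniform background composition, gene
  conversion between homeologs, assembly or annotation errors beyond the
  planted stop/truncation failures.  Passing closed-loop tests therefore
  demonstrates internal correctness of every stage and robustness at the
  stated noise levels — not performance on real proteomes, where domain
  divergence and annotation noise are harsher.

## Problem sizes and numerical choices

The default study conditions are 200 bHLH genes (including 5 planted
internal stops and 5 truncated domains) plus 300 decoys at seed 17; the
full pipeline on this bundle runs in well under a minute on one CPU, and
the test suite keeps oracle enumeration at 200 instances (L ≤ 4, length
≤ 6) and NJ recovery at 50 matrices of 5–8 taxa.  Output formatting is
fixed (scores 2 decimals, distances 4, percentages 1) and record order is
sorted, so repeated runs are byte-identical; every random draw flows
through one `numpy` generator per entry point, seeded from the config.

## Known limitations

* The Viterbi search reports a single best alignment per segment; there
  is no forward/backward posterior decoding or multi-domain splitting.
* Family assignment assumes references are aligned on the same 57-column
  scheme; margins cannot be validated against published trees because
  family labels there are not strict clades.
* The empirical E-value calibration assumes the background length is
  representative (default 400); scores for much longer targets are
  slightly anti-conservative.
* The core-11/defined-19 table is a labelled reconstruction; mismatch
  counts are comparable within a run, not across literatures.
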