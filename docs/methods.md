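# Methods

This note documents the models, parameter choices and known limitations
of the pipeline.  Everything quantitative stated here is computed by the
test suite or the analysis drivers; nothing is asserted that the code
does not check.

## Read processing and classification

Reads are canonicalized to the DNA alphabet (U→T) on input and converted
back to RNA only where folding requires it; the published catalogs mix
both conventions.  Adapter removal scans for the longest 3'-terminal
suffix of the read matching a prefix of the adapter with overlap ≥ 5 and
mismatch fraction ≤ 0.1 (both configurable); 5' adapters are assumed
removed upstream.  The length window defaults to the inclusive 18–30 nt
used throughout the original analysis; the window is what excludes the
32–35 nt piRNA-like population from all downstream stages.

Hierarchical assignment replaces a zero-mismatch short-read aligner with
hash/substring indexes, which is exactly equivalent under zero-mismatch
semantics: a read is assigned to the first matching catalog in the order
known-miRNA → ncRNA → CDS → genome, the genome searched on both strands,
transcript-like catalogs sense-strand only.  Known-miRNA matching
accepts the read if it equals the mature, is a substring of it, or
contains it with at most 3 extra flanking bases in total (isomiR end
variation; set the tolerance to 0 for strict identity).  Multi-mapping
reads count once, toward the lexicographically smallest feature name,
with a warning.

## The folding model and its calibration

Single-strand folding is a Zuker-style dynamic program over a compact
nearest-neighbor model: Watson–Crick and G:U pairs, a Turner-style 6×6
stacking table, size-dependent initiation penalties for hairpin, bulge
and internal loops (log-extrapolated past the tabulated sizes, internal
asymmetry 0.2/nt capped at 1.2), affine multibranch penalties, no
dangling ends, pseudoknots or terminal-mismatch terms, interior loops
capped at 30 nt.  An intermolecular variant of the same table scores
miRNA:target duplexes (stacks plus an affine loop penalty of
3.0 + 0.5/nt, unpaired ends free, no intramolecular pairs).  Both
programs exactly minimize the energy assigned by the explicit structure
scorers `structure_energy` / `duplex_structure_energy`, and the tests
verify equality against exhaustive enumeration of all structures for
single strands up to length 12 and duplexes up to 9+9.

**Calibration.**  The −20 kcal/mol hairpin threshold inherited by this
pipeline was originally applied to AU-rich mosquito precursors whose
energies under modern full Turner parameter sets (with dangles) sit well
above that line; a literal re-implementation would reject most of the
published novel precursors.  The loop-initiation tables are therefore
scaled by a single constant, `LOOP_SCALE = 0.32`, chosen together with
the topology rule below so that (i) all 14 published novel
mature/precursor pairs clear the −20 threshold as single hairpins with a
definite arm, and (ii) shuffled, structure-free 172-nt loci are rejected
at ≥ 95%.  The tightest of the 14 folds at −21.2 kcal/mol, i.e. the
calibration is binding there.  Energies from this model are internally
consistent but not comparable to RNAfold output.

**Hairpin topology rule.**  A candidate passes when, in its MFE
structure: (1) pruning side branches that contain ≤ 5 base pairs leaves
exactly one terminal loop; (2) the whole-window MFE is below the
threshold; (3) at least 15 nt of the mature lie on one side of that loop
and at most 4 nt on the other (the arm is the majority side).  The
15/4-nt arm rule is what separates genuine arm-mounted matures from
random single-loop folds whose "mature" dangles near the loop; the ≤ 5
pair pruning tolerates the small stem decorations present in several of
the published precursors.  Published −5p/−3p suffixes disagree with
mature position in the printed precursor for several loci; the package
always reports the arm computed from position relative to the terminal
loop and keeps the published name as annotation.

## Differential expression

TPM = count / library total × 10⁶.  The libraries are pooled biological
material without replicates, so dispersion cannot be estimated; the
between-stage test is the conditional binomial exact test (condition on
the summed count n of a miRNA in the two libraries; under the null its
count in library A is Binomial(n, Nₐ/(Nₐ+N_b)); the two-sided p sums all
outcomes no likelier than the observed one).  This is a defined
substitute for the dispersion-based count model used originally, not a
reproduction of its p-values.  Fold change is the TPM ratio with a 0.1
pseudocount on both sides; "TPM > 10" is evaluated on the maximum of the
two compared stages so that on/off miRNAs (e.g. TPM 0.5 vs 55.1) remain
callable.  No multiple-testing correction is applied, matching the
stated criteria; a Benjamini–Hochberg helper is provided, off by
default.  Under the null the test's type-I error at α = 0.05 is slightly
conservative (the suite checks 0.035–0.065 over 10,000 simulations), and
the joint three-criterion filter drives false positives at deep
sequencing essentially to zero because a null fold change concentrates
near 1.

## Target prediction

Seed = miRNA positions 2–8, Watson–Crick only.  The duplex energy of a
40-nt window centred on the seed match must be < −20 kcal/mol.
Significance replaces an extreme-value fit with an empirical null:
p = (1 + #{dinucleotide-preserving UTR shuffles whose best duplex energy
anywhere ≤ observed}) / (n_shuffles + 1), Altschul–Erickson shuffling,
seeded; the suite checks approximate uniformity of this p-value under
the null (KS < 0.1 over 500 random miRNA/UTR pairs).  Per-miRNA target
counts against a specific 3'UTR release are not reproducible without
that release and are out of scope.

## Degradome

Tags of 20–25 nt are exact-matched to transcripts; a tag's count
accrues to the 1-based position of its 5' end on every matching
transcript (multi-mapping flagged, not resolved — no rule was stated).
Site scoring: mismatch +1, G:U +0.5, doubled at miRNA positions 2–13,
any non-wobble mismatch at positions 10–11 rejects the site, score
cap 4.0; the cleavage position is the transcript base opposite miRNA
position 10 and must carry ≥ 1 mapped read.  Categories follow the five
stated rules with the median taken over occupied positions only (even
cardinality: mean of the central pair); the suite re-checks the
classifier against a literal reading of the rules on 10,000 random
profiles.  Across injection conditions (PBS / scrambled / antagomir) the
PBS library is the representative category for single-number summaries,
which reproduces the published 29-target tally; "regulated by the
antagomir" is reported both as category change and as presence/absence,
since the source does not define it.

## Synthetic data

The generator is the test bed's ground truth, not a sequencing
simulator.  Genomes are AT-rich (28/22/22/28), as in anopheline
genomes, with features placed without overlap.  Planted novel loci are
perfect stems (default 22 bp with three G:U wobbles on the passenger
arm, 8-nt loop, 75-nt genomic flanks) accepted by rejection sampling:
a locus is redrawn until its extraction window passes the shipped
hairpin criteria, so planted ground truth is a set of true hairpins by
construction (the wobbles also make the mature map uniquely).  Stage
libraries are Poisson draws per unique sequence around per-stage
expected TPMs, normalized so the miRNA mass fills (1 − piRNA fraction)
of the library; TPM being compositional, planting an eight-fold
up-regulation slightly deflates the other miRNAs' realized TPM, as in
real libraries.  Reads carry the 3' adapter (TruSeq small-RNA sequence
by default) truncated at a 50-nt read length; the piRNA-like background
(default 30% of reads, 32–35 nt, 400 unique species) exists only to
reproduce the bimodal length histogram and has no ping-pong structure.
Sequencing error is off by default.  Libraries are generated and
processed in collapsed form (unique sequence + count); FASTQ
materialization expands duplicates on request.  Degradome condition sets
plant one complementary site per requested category with background
sites constructed to realize exactly that category (validated at
generation time), and optionally suppress planted sites in the ANTIMIR
condition.

Because the generator plants clean signals — exact mature sequences, no
sequencing error, hairpins pre-screened to fold — passing its
recovery tests demonstrates the correctness of the pipeline's logic,
not its robustness to real-library artefacts (isomiR spectra, ligation
bias, cross-mapping between paralogs).

## Problem sizes used by the test suite

Oracle equivalences run at the sizes where enumeration is exact
(folding ≤ 12 nt, duplexes ≤ 9 nt, 10,000-iteration simulations for the
count test and category rules).  End-to-end recovery runs the default
configuration: seed 7, six libraries at 10⁶ reads per stage, 30 known
genes, 5 novel loci, 5 planted regulated miRNAs at true fold change 8,
one planted degradome target per category.  Unit tests use a reduced
configuration (10⁵ reads, 8–12 genes) for speed; both configurations
exercise identical code paths.

## Known limitations

* The folding energies are calibrated, not thermodynamic; do not compare
  them to RNAfold values (the calibration rationale is above).
* Zero-mismatch assignment cannot absorb sequencing errors; reads with
  errors fall through to lower catalog tiers or remain unassigned.
* The exact count test treats the two libraries as multinomial draws;
  biological replicate variance is not modeled (none was available).
* Degradome multi-mapping tags are double-counted by design (flagged);
  tallies over paralog-rich transcript sets will overcount evidence.
* Published sequencing-scale numbers (raw read totals, the 36-miRNA
  regulated set, per-miRNA UTR target counts) require the original raw
  data and database releases and are not reproduced.
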