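# Methods

This note documents the models behind `crckit`, the parameters that
matter, what the synthetic genomes do and do not emulate, the numerical
choices, and the known limitations.

## Synthetic genomes

The simulator plants retroelements of known family, age, completeness and
nesting into an i.i.d. random background (default GC 0.38, typical of
plant euchromatin).  The background deliberately has no isochore or gene
structure: it is the simplest model that exercises the detectors, and
users can substitute real flanking sequence.

**Family templates.**  Ten autonomous families are derived from one
ancestral element whose coding region (GAG–PR–RT–RH–INT, ~3.7 kb) is a
reverse translation of the bundled exemplar proteins.  Each family
lineage accumulates 0.343 expected substitutions per site from the
ancestor; under the Jukes–Cantor expectation
identity = ¼ + ¾·e^(−8D/3) two lineages then show ≈ 55% pairwise
nucleotide identity, placing between-family RT identity in the distant
band while copies of one family stay ≥ 80% mutually identical.  After
lineage mutation the functional signals every family must keep are
restored verbatim: TG…CA LTR termini, the PBS (complementary to the
initiator-Met tRNA 3′ end), the polypurine tract, and the CR motif —
these are conserved in real elements because they are required for
replication and targeting.  One family (A) carries a chromodomain
downstream of the integrase instead of a CR motif.  LTR lengths are drawn
per family from 661–781 bp and element lengths span ≈ 5.8–7.4 kb, the
ranges reported for the centromeric families this package models.
TRIM (150-bp LTRs, ~0.9 kb), LARD (~6 kb non-coding) and TR-GAG
(GAG-only) templates model the non-autonomous derivative classes.

**Substitution process.**  Decay is a Kimura two-parameter Markov
process: substitution events arrive as a Poisson process at rate
r = 1.3×10⁻⁸ per site per year (the canonical neutral rate for plant
LTR retrotransposons); each event is a transition with probability
κ/(κ+2).  κ defaults to 2.0 — the literature gives no
transition/transversion ratio for these elements, and every estimator
here is κ-consistent, which the tests exploit.  Multiple hits at one site
are allowed, so observed divergence saturates exactly as the K2P distance
assumes.  Both LTRs of an insertion are mutated independently, giving the
pair an expected divergence of 2rT at age T.  Indels are **not**
simulated inside LTRs; large deletions are modelled instead by the decay
classes (5′/3′ truncation, internal deletion, central fragments of a
stated fraction).  Complete (and internally deleted) insertions carry an
exact 5-bp target-site duplication at age 0 (configurable 4–6 bp); the
duplicated copy decays with age.  Nested insertions are planted strictly
inside their host's realized interval; a nested event's locus is an
offset within the host element, since the host does not exist in the
background coordinate system.

**What passing tests show.**  The planted genomes reproduce the
statistical structure the analyses assume — paired diverging LTRs, TSDs,
ordered coding domains, age-dependent decay, nesting, optional satellite
arrays — but not assembly error, sequencing chimeras, segmental
duplications, or the full repeat-family ecology of a real plant genome.
Passing on them demonstrates correctness of the algorithms under the
stated model, not field performance on arbitrary assemblies.

## Structural detection

Exact k-mer seeds (k = 20) shared by two loci at an element-compatible
spacing are clustered by alignment diagonal (band 30 bp) and chained
(maximum within-chain gap 600 bp, comfortably above the ~20 bp expected
seed spacing at 5% LTR divergence).  Each chained repeat is extended with
a padded global alignment and trimmed to its maximal-scoring segment
(match +1, mismatch −3, gap −4, so extension requires ≈ 75% local
identity), followed by an X-drop extension (drop 12) that carries the
boundary through terminal substitution clusters, and a shave of isolated
terminal matches (< 3 consecutive) that would otherwise extend the repeat
by a chance base.

Boundary polish then scores every shift within ±25 bp by weighted
evidence: an exact 4–6 bp flanking duplication dominates (a duplication
with one mismatch counts half — a single substitution often breaks the
TSD of an old element), TG/CA termini corroborated on *both* LTR copies
rank next, and large shifts are discouraged.  Termini never veto a shift:
a mutated terminal CA must not make a TSD-supported boundary unreachable.
Elements whose interior contains a near-copy of their own LTR are
deferred — such "pairs" are usually two nearby insertions of one family
or a host with a same-family nested insert — and resolved in later passes
after confidently accepted elements are masked (3 passes by default).
Containment of one detected element inside another is allowed (nesting);
partial overlaps are resolved by identity × minimum LTR length.

Orientation comes from the replication signals: PBS = best ≥ 11 bp match
(≤ 1 mismatch) to a bundled tRNA-3′-end set within 20 bp downstream of
the 5′ LTR; PPT = purine run (≥ 10 bp, ≥ 80% A/G) within 30 bp upstream
of the 3′ LTR; if neither is found forward, the reverse complement is
tried and the element marked "−".  Defaults (LTR 100–2,500 bp, element
1–18 kb, detection pair-identity floor 80%) bracket the observed family
ranges with headroom; the 99% pair-identity cutoff used to select
elements for careful annotation is an annotation filter, not a detection
filter.

Measured on the benchmark scenario (2 Mb, 40 complete elements at ages
0–2 Mya, 20 LTR-less decoys), detection recall and precision average
≈ 0.98 over ten seeds with boundary errors ≤ 5 bp; residual misses are
old elements that have lost both the TSD and a terminal dinucleotide, for
which the boundary is genuinely ambiguous at the ±10 bp scale.

## Domain annotation

All six reading frames are aligned locally (BLOSUM62, open −11,
extend −1) against the bundled exemplar set.  Hits require score ≥ 80,
≥ 25 aligned residues and ≥ 40% identity — below which chance local
alignments dominate at these sequence lengths.  Same-domain hits within
two codons are merged across frames (minimal frameshift repair); hits to
different domains never merge.  The RT domain of an element is the
longest RT hit of ≥ 150 residues (ties: identity, then leftmost).  The
bundled reference set is **synthetic**: randomly generated proteins of
realistic lengths and composition, frozen from a fixed seed, standing in
for a curated domain library that cannot be redistributed; it is a
documented, swappable fixture (`DomainConfig.reference_set`).  Likewise
the CR motif is a synthetic 40-bp nucleotide consensus searched within
1 kb upstream of (or extending into) the 3′ LTR at ≤ 30% edit distance —
the motif is defined positionally in the literature, without a published
consensus for this clade, so its detection is only meaningful in
round-trip tests.  When both a chromodomain hit (downstream of INT,
upstream of the 3′ LTR) and a CR-motif match are present, the protein
evidence wins.

## Families and trees

Neighbor joining follows the Saitou–Nei Q-criterion; Q-ties break by the
lexicographically smallest cluster-label pair (a cluster is labelled by
its smallest member taxon), making topology independent of input order;
negative branch lengths are clamped to zero with the deficit moved to the
sister branch.  Bootstrap support resamples alignment columns with
replacement (1,000 replicates by default) and counts bipartitions of the
replicate NJ trees.  The multiple alignment backing the bootstrap is
produced by MAFFT; equal-length inputs (the no-indel model) pass through
unchanged.  A hand-rolled progressive aligner was considered and
rejected: alignment fidelity is not the contract here, group recovery is,
and MAFFT is the tool a practitioner would use.

Groups are maximal clades with support ≥ 70% whose members are all
pairwise ≥ 80% identical at the RT nucleotide level (gap columns count as
mismatches — the stretcher-like convention; identity-matrix reproduction
depends on it, so it is fixed, not configurable).  Singletons are
allowed; every RT lands in exactly one group; the representative is the
member with the highest mean identity to its group.  The 70% / 80%
thresholds are configuration: the source analyses state neither, and
these values produce a clean ten-family partition on the synthetic mimic.
The between-group identity matrix is computed
representative-vs-representative by default with an all-vs-all mean as an
option, since published matrices rarely state which convention they use.

## Census, dating, density, satellites

The census runs `blastn` (representative vs both genome strands), merges
same-strand HSPs separated by ≤ 50 bp on the genome, computes coverage on
the representative's coordinates after merging, and applies the strict
80-80 / 80-10 rules.  Census identity counts gap columns (masking-tool
convention) — deliberately different from the LTR-pair identity
convention (gaps excluded), and both are documented because they are
easy to conflate.  One behavioural note: a truncated copy that retains
one LTR shows query coverage ≈ (true fraction + LTR/element length),
because its single LTR matches both LTR positions of the representative.

K2P distances count substitutions over the ungapped columns of an
**affine-gap** global alignment (match +2, mismatch −3, open −7,
extend −2).  This matters: a unit-cost edit-distance alignment will
explain clusters of substitutions with offsetting indels, deflating K —
and hence ages — by ≈ 8–10% at 3 Mya.  Saturation (non-positive log
argument) is flagged, never clipped.  End-to-end
(simulate → detect → date), median age estimates land within ~4% of the
planted age at 0.5, 1, 2 and 3 Mya.  Per-element ages at young ages are
information-limited: a 700-bp LTR pair at 0.5 Mya carries ~9 expected
substitutions, so the per-element relative error has a Poisson floor
(median ≈ 0.22) that no estimator can beat; recovery statements are
therefore made about the median estimate across elements, which
concentrates as 1/√n.

Density tracks are covered-fraction (overlaps flattened) or hit-midpoint
counts per sliding window; the defaults for the 2-Mb synthetic
chromosomes are 100 kb windows at 20 kb steps (500 kb / 100 kb suit
pseudochromosome-scale plots).  The RT-domain density scan applies the
20% divergence cap used for masking-style annotation.

The satellite scan marks positions whose k-mer (k = 12) last occurred at
a lag within the period range, takes maximal dense runs, estimates the
period as the dominant lag (±2 bp pooling), and requires ≥ min_copies
spanned periods, dense support (≥ 30% of expected), and ≥ 80% identity of
adjacent monomers.  The 170-bp default monomer in the simulator is an
arbitrary stand-in — no satellite monomer is known for the system this
package models, which is precisely the negative finding the element-only
centromere scenario reproduces.

Age histograms call peaks as bins strictly exceeding both neighbours and
reaching ≥ 2× the median bin count.  The median is taken over *all* bins,
not only nonzero ones: on clean multimodal data every nonzero bin belongs
to a cluster, so a nonzero-median floor would sit at peak height and
erase every peak, while the all-bins median estimates the background
level on noisy and clean data alike.

## Problem sizes

The validation experiments are sized for a single desk CPU: a 2-Mb
chromosome with 60 insertions for detection; 50 elements per age point at
four ages for dating; three ~520-kb genomes sharing ten families (three
copies each, ages 0–6 Mya so within-family identity sits near 90%) for
family recovery; an ~800-kb constructed centromere (90% TE, 35% CRC by
construction) for composition and the satellite negative control.

## Limitations

* No indel process inside LTRs; dating is substitution-only by design.
* The reference domain set and CR motif are synthetic fixtures; swapping
  in a curated library is required for biological use.
* Detection is tuned for direct (non-solo) LTR pairs; solo LTRs and
  heavily nested clusters older than ~4 Mya are out of scope of the
  structural detector and are picked up only by the census as fragments.
* The pipeline has no circular/ideogram plotting; tracks are emitted as
  bedGraph for external plotting, with a static helper only.
* `blastn` and `mafft` must be present on PATH; their exact versions
  affect low-level alignment details but not the decision rules built on
  them.
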