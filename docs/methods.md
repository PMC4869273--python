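# Methods

`mhctyper` implements RNA-seq-based MHC class I typing for species with
incomplete allele catalogues, such as cattle (BoLA). The method exploits the
very high expression of class I genes in white blood cells: short paired-end
reads from whole-blood RNA-seq cover every expressed allele deeply enough
that presence/absence can be decided by sequence coverage alone, novel
alleles can be read directly out of the data, and relative allele expression
falls out of the same alignments.

## The typing model

**Complete-coverage calling.** An allele from the catalogue is declared
present in an individual if and only if every base of its cDNA sequence is
covered by at least one read accepted at **zero mismatches**. There is no
likelihood model and no allele-frequency prior: the criterion is
deterministic, which also removes any reference-allele bias — an allele
either survives full-length exact coverage or it does not. The default
minimum depth per base is 1 (`TypingConfig.min_depth`); the knob exists
because deeper data supports stricter settings, but presence of coverage is
the criterion, not depth.

**Relaxed pass and novel-allele candidates.** Catalogues of non-model
species are incomplete, so a second alignment allows up to **3 mismatches
per read, keeping only each read's best stratum** (all placements tied at
the minimal mismatch count). An uncalled catalogue allele whose
relaxed-pass profile is fully covered — or fully covered except a *single*
uncovered interval shorter than 5 bp (i.e. ≤ 4 nt) — is a candidate
"parent" of a novel allele. Classical genes (1–6) are swept before
non-classical genes (NC1–NC5), reflecting their higher variability;
within a class, candidates are ordered by descending mean depth.

Called alleles are swept for variant evidence as well: when an individual
carries two sibling variants of one parent (or a parent plus one variant),
the parent can be completely covered at zero mismatches by the union of the
siblings' reads, yet its relaxed-pass pileup still shows the recurrent
variant nucleotides. Reconstructed alleles are swept before database
alleles so that an incomplete reconstruction is completed before its
residual reads can seed spurious variants on related catalogue entries.

**Variant detection and phasing.** Pileup columns on a candidate parent
yield variant observations; a variant needs `min_support = 3` reads and a
support fraction ≥ `min_fraction = 0.2` of the local pileup. The fraction
threshold is set well below the ~0.5 expected for a heterozygous variant on
a co-dominantly expressed allele because best-stratum multi-mapping against
closely related alleles dilutes support; 0.2 still rejects sequencing error
at the ≤ 0.5 % per-base rates of modern short-read data.

Variants are phased into haplotypes from joint observations: two variants
are linked when ≥ `min_link = 2` sequenced fragments (a read, or the two
mates of one fragment combined) carry both alternate bases, and are held
apart when fragments carry one alternate beside the other's reference base.
Repulsion is judged proportionately — at least `min_link` fragments *and*
at least 10 % of the joint observations — so a handful of error reads
cannot veto a deeply supported linkage, while genuine sibling alleles
(whose cross-variants are seen almost exclusively in repulsion) are never
merged. Contradictory evidence above both thresholds marks the phase sets
ambiguous; ambiguous sets are reported and skipped, never silently merged.

Two situations deserve explicit treatment because 61-nt reads with
~200-nt fragments cannot link variants further apart:

* **Fixation merge.** If the novel allele *replaces* its parent in the
  genotype, every pileup column is nearly 100 % alternate. Components whose
  variants all have support fraction ≥ `hom_fraction = 0.8`, with no
  repulsion between them, are merged into a single haplotype: the absence
  of any reference-carrying reads identifies the single-haplotype
  configuration even though direct linkage is unobservable.
* **Post-closure consolidation.** If partial single-variant
  reconstructions of one parent have been accepted (each fully covered,
  each soaking up the other's variant reads at zero mismatches), the union
  allele is also proposed once the iteration closes, provided no fragment
  shows the variant sets in repulsion. If the union validates, the
  parsimony step (below) removes the partials it makes redundant. This is
  an explicit Occam choice: one allele explaining the data is preferred
  over two otherwise-unevidenced fragments of it.

**Validation of candidates.** A reconstructed or assembled sequence is
accepted only if (a) it differs from every catalogue sequence, (b) a
zero-mismatch re-alignment of the individual's reads covers it completely —
the same criterion used for calling — and (c) its translation shows an
intact open reading frame, or, for non-classical assignments, the
documented non-classical features: an early stop codon or a VPI/IPI/VLIK
transmembrane motif.

**De-novo route.** Alleles too far from every catalogue entry (no 61-nt
window within 3 mismatches) leave reads that align nowhere. Reads sharing a
recurrent k-mer absent from the catalogue (≥ 3 occurrences) seed a greedy
overlap assembly: reads join the layout by exact overlap of ≥ 25 nt, each
extension base must win ≥ 80 % of the spanning reads' votes, and mates of
placed reads may re-anchor at a reduced overlap (≥ 12 nt) when coverage
thins. A supported branch conflict aborts with "ambiguous", a contig
shorter than 200 nt with "fragmentary". Contigs are oriented by their
ATG-led open reading frame (the assembly seed may come from either mate)
and then validated like any candidate. This mirrors reading the allele
sequence directly off the stacked reads rather than running a de Bruijn
assembler.

**Parsimony pruning.** Greedy discovery can leave redundant calls: a
partial reconstruction, or a parent fully covered only by the union of two
sibling alleles' reads. After the iteration closes, the final genotype is
reduced to a minimum explanation: alleles with ≥ `prune_min_unique = 2`
uniquely explained reads are forced; remaining reads are covered greedily
by largest marginal contribution; an allele whose marginal support stays
below the threshold is dropped. The threshold is 2 rather than 1 because a
single sequencing-error revertant read can simultaneously complete a
redundant allele's coverage and fake unique support.

**Iteration.** Calling and discovery alternate until an iteration adds no
allele (cap 20, then a hard error with diagnostics). The catalogue only
grows during iteration; every addition and rejection is recorded in an
audit log. At cohort level, novel alleles accepted in one individual enter
the shared catalogue before the next individual's exact pass (individuals
processed in sorted order, so results are independent of input order); an
isolation mode types each individual against a private catalogue copy.

**Quantification.** After typing, reads are re-aligned at zero mismatches
against *only* the individual's called alleles; multi-mapping reads are
split fractionally (deterministic; a seeded random single-report mode
emulates classic aligner behaviour). Proportions are normalised separately
within the classical and within the non-classical class, as read-count
ratios without length normalisation — class I cDNAs are nearly equal in
length, and a length-normalised mode is available behind a flag. Counts are
real-valued under fractional assignment; reports render 3 decimals.

## The aligner

Bowtie-style ungapped end-to-end alignment is re-implemented so the
pipeline is hermetic and testable: an exhaustive k-mer index (k = 15) over
the catalogue's forward strand, pigeonhole seeding (`max_mismatches + 1`
non-overlapping seeds guarantee that no placement within the budget escapes
when the read is long enough; shorter reads fall back to an exhaustive
scan), and full-length Hamming verification in both orientations. `N`
counts as a mismatch on either side. Coordinates are 0-based half-open;
orientation is recorded on the read. Property tests hold the aligner equal
to an independent brute-force Hamming scan over every allele, offset and
orientation. Gapped alignment is deliberately out of scope: the mismatch
budget model is ungapped, and an allele differing by an indel is reachable
through the de-novo route.

## Pedigree validation

Families provide an internal truth check: every called allele must be
Mendelian-consistent, and the full-sib family's four founder haplotypes
must explain every offspring as (one paternal) ∪ (one maternal) haplotype.

* **SNP quality control** retains markers inside the MHC region of cattle
  chromosome 23 (27,545,231–30,222,836 bp) with call rate > 0.98, minor
  allele frequency > 0.05 and Hardy–Weinberg exact-test p > 0.001. The HWE
  test is the conditional exact test (enumeration of heterozygote counts
  given allele counts), computed on founders only: family structure would
  bias the test, and at family-scale sample sizes the chi-square
  approximation is unreliable.
* **Haplotype derivation** searches 2-partitions of each parent's allele
  set exhaustively, prefiltered by the necessary condition that every
  offspring contains one haplotype of each parent (this kills almost all of
  the 2^(n−1) partitions before the joint sire × dam check, keeping the
  search tractable for parent sets of ~16 alleles; a hard cap of 20 alleles
  guards the worst case). The unique solution up to within-parent label
  swap is returned; co-optimal distinct solutions are flagged
  "unresolvable" (ambiguity from alleles shared between parents is carried,
  never resolved arbitrarily); no solution yields a violation report that
  mentions recombination as a possible benign cause. Haplotypes are allele
  sets, so gene duplications (several alleles of one gene on one haplotype,
  as happens for NC2) are represented naturally.
* **SNP flank tracking** infers, for each marker heterozygous in a parent,
  which parental allele each offspring received (where unambiguous), and
  groups offspring by transmission vector into flank classes. On data
  without recombination inside the short region — the assumption made
  throughout — these classes must partition the full sibs exactly as the
  MHC haplotype classes do.

## The simulator

The generator produces data with the structure the method assumes; it is
first-class, tested code, and every pipeline guarantee is demonstrated on
its output.

* **Catalogue.** A class I family ancestor (codon-level, ATG-led, no
  internal stops) gives rise to gene ancestors at 8 % per-base divergence
  and alleles at 2 % — reproducing the field's awkward reality that alleles
  assigned to different genes can be locally near-identical. Non-classical
  alleles always carry a VPI/IPI/VLIK motif written late in the coding
  sequence (the transmembrane region) and an early stop with probability
  0.5; classical alleles keep an intact ORF and are scrubbed of accidental
  motifs so feature checks stay crisp. Defaults: 4 classical + 4
  non-classical genes × 3 alleles, 1,098 nt (a codon multiple near the
  ~1.1-kb class I cDNA).
* **Novel alleles** are spawned from catalogue parents at 1–3 substitutions
  (configurable; a distant-novel generator at ~20 % divergence exercises
  the de-novo route, and a sibling-pair generator places two alleles'
  variants inside one 52-nt window so that linkage and repulsion are both
  directly observable — the configuration phasing is meant to resolve) and
  are withheld from the public catalogue but recorded in the truth set.
* **Families.** One sire × dam full sibship of 8, plus half sibs through
  the same sire and an unrelated control, mirroring an F2 design. Founder
  chromosomes carry 2–3 classical and 2–5 non-classical gene copies
  (duplications allowed) and are drawn allele-disjoint within a parent and
  between the family's parents: with hundreds of alleles per gene in real
  populations identical alleles on two founder chromosomes are the rare
  case, and distinct haplotypes keep derivation identifiable — the property
  under test. Offspring inherit one haplotype per parent uniformly. Seven
  SNP flank markers segregate with the haplotypes without recombination;
  markers alternate sire-informative and dam-informative (heterozygous in
  one parent, homozygous in the other), emulating the selection of
  family-informative chip markers.
* **Reads.** 61-nt paired-end reads from ~N(200, 20) fragments; mate 2 is
  the reverse complement of the fragment's 3' end. Fragment placement
  models fragmentation of whole transcript molecules: a fragment is
  anchored at the 5' (or 3') transcript end with probability f/L each and
  uniform otherwise — without terminal anchoring the first and last bases
  of a transcript would almost never be read and complete-coverage calling
  would be impossible at realistic depth. Substitution errors at a
  configurable rate (no indels by default — the ungapped aligner defines
  the scope; an indel flag exists to exercise de-novo failure modes);
  constant base qualities (unused downstream, kept for format fidelity).
  Expression weights are symmetric Dirichlet(5) per genotype, shared
  between individuals with identical genotypes to emulate the observed
  cross-individual consistency of allele-level expression.
* **Determinism.** Every generator and the full pipeline are byte-identical
  under a fixed seed.

What the simulator does **not** model — and hence what passing tests do not
show about real data: transcriptome-wide background reads (only optional
random decoys), expression differences between tissues, allele-biased
library artefacts, indel sequencing errors, splice forms, base-quality
structure, and genotyping error in SNP chips.

## Problem sizes and defaults

Simulation-based checks run at sizes chosen to hold the properties they
test with comfortable margins: ~46× mean coverage per allele for discovery
checks (3,000 pairs over 4 alleles), 20,000 error-free pairs per individual
for cohort recovery, 50,000 pairs for quantification recovery (sampling
error ~0.3 %), 50–100 seeds for reconstruction/phasing repetition, and 20
seeds at 0.5 % error for specificity. `scripts/acceptance.py` re-runs the
same battery at moderately reduced counts and prints the measured rates.

## Known limitations

* Variants of one novel allele farther apart than a fragment, in an
  individual that *also* expresses the parent, cannot be phased from the
  data; they surface as partial reconstructions or ambiguous phase sets
  rather than being guessed.
* The consolidation step prefers one merged allele over two unlinked
  partials; if two true sibling alleles never co-occur on any fragment and
  never show repulsion, the merged reconstruction is chosen even though the
  two-allele configuration is equally consistent — parsimony, not evidence,
  decides that tie.
* Indel variants relative to the catalogue are invisible to the variant
  route and reachable only through de-novo assembly.
* Haplotype derivation assumes no recombination within the MHC region and
  reports apparent conflicts as possible recombination rather than
  resolving them.
* Expression proportions are within-individual, within-class read shares;
  no between-individual normalisation is attempted.
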