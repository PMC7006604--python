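# Methods

`retroburst` re-implements, as a verifiable pipeline, the standard workflow
for characterising full-length LTR-retrotransposons in a plant genome
assembly: structural detection, domain-order superfamily classification,
insertion-age dating from LTR-LTR divergence, insertion-polymorphism scoring
across accessions, and gene-proximity annotation. Because the interesting
claims of such an analysis (counts of young elements, polymorphism rates,
promoter-proximal insertions) depend on genome-scale data, every stage here
is validated instead by parameter recovery on a synthetic genome whose
planted elements have known coordinates, superfamily, age, per-accession
presence and gene context.

## The simulator

`simulate_reference` assembles each chromosome as random background sequence
(default GC 0.38, a typical cucurbit value) interleaved with planted
features, each separated by at least 1.5 kb of background. A planted element
is `TSD + 5'LTR + internal + 3'LTR + TSD`:

- **LTR divergence is the age signal.** An ancestral LTR is drawn at random;
  the two copies are evolved independently along branches of length
  d = mu * T (expected substitutions per site) under Kimura's two-parameter
  substitution model with transition/transversion rate ratio kappa
  (default 2), using the exact K80 transition probabilities per site. The
  expected K2P distance between the copies is therefore 2 * mu * T, which is
  exactly the quantity the dating stage inverts. No indels are placed inside
  LTRs: the dating model assumes aligned substitutions only, and keeping the
  generator substitution-only keeps the expected distance analytically tied
  to the drawn age. The default mutation rate is mu = 7e-9
  substitutions/site/year (the Arabidopsis calibration commonly applied to
  other dicots); ages are drawn uniformly on [0.1, 3] Mya. The uniform draw
  is a neutral stand-in, not an inference about any real age distribution.
- **The internal region** carries the five domain consensi back-translated
  into a fixed-codon CDS cassette, in Copia (GAG-PR-INT-RT-RH) or Gypsy
  (GAG-PR-RT-RH-INT) order, in frame 0 with frame-preserving random spacers,
  on a random strand; "Unclassified" elements carry only GAG-PR-RH, i.e.
  they are coding but lack both order-defining domains. The internal region
  is mutated with the same per-site process at branch length d (one lineage
  since insertion).
- **Decoys**: solo LTRs (LTR-like sequence with TSDs, no partner repeat) and
  truncated elements (single LTR plus a non-coding fragment) exercise the
  detector's pairing requirement and the coding filter.
- **Genes** are strand-aware intervals over ordinary background sequence. A
  configured fraction of elements (default 20%) is planted as a composite
  element–gap–gene feature so its strand-aware upstream distance is
  tsd + gap with gap drawn from [20, 920] bp — strictly inside the 1,000 bp
  window with enough margin that a few base pairs of detector boundary
  uncertainty cannot flip the flag, and the 1.5 kb minimum spacing
  guarantees no unpaired element ever qualifies. The planted near-gene set
  is therefore exactly recoverable, which is what the tests assert.
- **Varieties**: each element is excised from each derived accession genome
  independently with probability 0.5 (six accessions by default). Excision
  removes the element plus one TSD copy, reconstructing the pre-insertion
  allele — the standard model of LTR insertion polymorphism.

Everything is driven by one `numpy` `Generator` seeded from `SimConfig.seed`,
so outputs are byte-identical for a fixed config.

What the simulator does *not* emulate: nested or recombined elements,
solo-LTR formation by unequal recombination, indel mutation, sequencing or
assembly error, segmental duplications, and realistic host-gene sequence.
Passing recovery tests therefore demonstrates the correctness of the
decision rules and estimators under their own model assumptions, not
performance on real assemblies, where boundary accuracy and the coding scan
would face degraded and nested copies.

## Structural detection

`find_candidates` seeds exact 20-mer matches on the forward strand (LTRs are
direct repeats whichever strand the element occupies), keeps pairs whose
separation is compatible with the configured element length window, clusters
them by diagonal, and extends each cluster outward with an ungapped X-drop
extension (match +1, mismatch −2, drop 8). Pairs are validated against the
length and identity constraints (defaults: LTR 100–3,500 bp, element
1,000–16,000 bp, ≥ 85% identity, mirroring a widely used structural
detector's defaults with a widened LTR maximum), the flanks are searched for
an identical 4–6 bp TSD, and overlapping candidates are resolved greedily by
score = identity x mean LTR length with a deterministic leftmost/longest
tie-break. Candidates never span an N run; TSDs are optional by default
because they decay in old insertions. LTR identity comes from a global,
end-gap-penalised pairwise alignment (match +2, mismatch −2, gap open −6,
extend −1); the same alignment is reused for dating, which is what a
two-sequence run of a multiple aligner reduces to.

## Classification

Internal regions are translated in all six frames and scanned by local
protein alignment (BLOSUM62, gaps −11/−1) against packaged consensus
peptides; a hit requires at least half the profile's self-alignment score, a
threshold calibrated against the shuffled-sequence null (random 3 kb
sequence scores far below it). Any hit marks the candidate as coding;
candidates without coding potential are filtered out. The superfamily call
reads the domain order along the inferred coding strand: INT before RT is
Copia, RT before INT is Gypsy, and a missing order-defining domain — or hits
on contradictory strands — yields Unclassified. A `strict_five_domains`
option instead requires all five domains in exact canonical order. Users can
supply their own peptide profile FASTA (plus optional per-profile
thresholds) for real genomes.

## Dating

For each coding element the aligned LTR pair gives transition and
transversion proportions P and Q over columns where both bases are
unambiguous; gap and ambiguity columns are excluded from the denominators
(standard K2P practice). The distance K = −1/2 ln((1−2P−Q)√(1−2Q)) is
undefined when either logarithm argument is non-positive; such elements are
flagged saturated rather than clamped and are excluded from age histograms.
Age is T = K / (2 mu), reported in Mya to three decimals; mu is a config
knob defaulting to 7e-9/site/year, with no generation-time rescaling.
Per-element uncertainty is dominated by binomial sampling of K at the LTR
length: sd(K) ≈ sqrt(K/L), i.e. roughly ±0.5 Mya for a 300 bp LTR at 2 Mya.
That is why the slope of the estimated-on-true age regression is assessed
over ≥ 200 simulated LTR pairs (400 by default in the acceptance run),
where its standard error drops to ~0.02; on a 50-element run the slope
estimator itself has SE ≈ 0.06 and is not a sharp diagnostic.

## Polymorphism

The built-in genome-vs-genome detector anchors on 31-mers unique in both the
reference and the accession chromosome, chains them collinearly, and emits a
deletion for every reference-side gap ≥ 50 bp whose accession-side gap is
< 10% of it; boundary uncertainty is at most one anchor length, small
relative to multi-kilobase elements. External BED or VCF deletion calls
(symbolic `<DEL>` or REF/ALT length difference) are read per accession and
flow through the identical scoring path; they are assumed pre-filtered for
mapping quality and read support, since the anchor detector has no analog of
those read-level filters. An element is scored absent in an accession when
some call overlaps it with a reciprocal intersect of at least 90% of both
lengths — inclusive at exactly 0.90, exposed as a flag since inclusivity at
the printed threshold is a convention choice. Fractions are computed on the
LTR-to-LTR element interval, excluding TSDs, because that is the annotated
unit. An element absent in at least one accession is polymorphic.

## Gene context and reporting

Upstream distance is measured strand-aware from the element edge to the gene
feature start (gene start for `+`, gene end for `-`), defined only when the
element lies entirely upstream; the flag uses a strict `< 1000 bp` window.
Ties between equidistant genes break lexicographically by gene id. Reports
comprise superfamily count tables (with a young subset at age < 2 Mya), age
histograms in left-closed 0.5 Mya bins (bin width configurable; saturated
elements excluded, totals conserved), and density tracks over a fixed total
of 6,000 genome windows allocated to chromosomes by largest-remainder
proportional rounding, each feature assigned to the window containing its
midpoint (boundary midpoints go right). All artifacts are plain TSV;
plotting is optional and never load-bearing.

## Problem sizes and numerical choices

The standard benchmark configuration is two 1-Mb chromosomes, 50 elements,
ten solo-LTR and ten truncated decoys, 30 genes and six accession genomes —
small enough to run end-to-end in about a minute while leaving every stage's
decision logic fully exercised; the dating regression uses 400 independent
LTR pairs. Detection/truth matching uses reciprocal element-interval overlap
≥ 0.8. Monte-Carlo assertions use 3–4 standard-error tolerances. Degenerate
inputs are contracts, not crashes: an empty genome yields an empty candidate
list, an element with saturated LTRs stays in the output flagged, a
zero-usable-column alignment raises an error distinct from saturation, and a
configuration whose planted features cannot fit its chromosomes is rejected
with an explicit message.
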