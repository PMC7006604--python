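# retroburst

Structural annotation, dating and polymorphism scoring of LTR-retrotransposons
— with a synthetic-genome simulator that plants elements with known ground
truth, so every stage of the pipeline can be validated by parameter recovery.

LTR-retrotransposons dominate plant genomes and, because the youngest copies
are long, near-identical repeats, they are the hardest features to assemble
and annotate — yet they are exactly the copies most likely to be polymorphic
between accessions and to sit in gene promoters. `retroburst` is aimed at
genome/TE analysts who want the standard characterisation workflow as a
tested, reusable library and CLI:

1. **Detect** full-length elements structurally: two similar direct repeats
   (the LTRs) 1–16 kb apart, ≥ 85% identical, optionally flanked by a 4–6 bp
   target-site duplication (TSD).
2. **Classify** by coding-domain order: six-frame translation, local-alignment
   scan for GAG/PR/INT/RT/RH; integrase 5′ of reverse transcriptase ⇒ *Copia*
   (GAG-PR-INT-RT-RH), 3′ ⇒ *Gypsy* (GAG-PR-RT-RH-INT); non-coding candidates
   filtered, elements missing order-defining domains tagged *Unclassified*.
3. **Date** each element from its aligned LTR pair with the Kimura
   two-parameter distance

   K = −½ · ln((1 − 2P − Q) · √(1 − 2Q)),  T = K / (2μ)

   where P and Q are the transition and transversion proportions and
   μ = 7×10⁻⁹ substitutions/site/year by default; the two LTRs are identical
   at insertion, so their divergence clocks the insertion age T (in Mya).
4. **Score polymorphism** per accession: an element is absent where a deletion
   call shows a reciprocal overlap ≥ 90% of both lengths. Calls come from the
   built-in genome-vs-genome anchor detector or from external BED/VCF.
5. **Annotate gene context**: elements < 1,000 bp upstream of a strand-aware
   gene start are flagged as potential promoter insertions.
6. **Report**: superfamily count tables, insertion-age histograms, and density
   tracks over 6,000 genome-tiling windows.

The simulator (`retroburst.simulate`) generates multi-chromosome genomes with
planted elements whose LTR pairs are evolved so their expected K2P distance is
exactly 2μT for the drawn age T, plus decoy repeats, genes, and derived
"variety" genomes with elements cleanly excised back to the pre-insertion
allele. See `docs/methods.md` for the model and its limits.

## Worked example

Simulate a small study and run every stage:

```bash
retroburst run-all --config sim.yaml --outdir run/
```

with `sim.yaml` setting one 150 kb chromosome, 5 elements, 2 varieties,
seed 5. `run/aged_elements.tsv` then contains (columns abridged):

```
element_id  chrom  start   end     superfamily   aligned_columns  P         Q         K         age_mya
RB0001      chr1   18066   24842   Unclassified  792              0.007576  0.007576  0.015312  1.094
RB0003      chr1   47074   53595   Gypsy         776              0.014175  0.021907  0.036983  2.642
RB0004      chr1   82899   87876   Copia         632              0.000000  0.003165  0.003172  0.227
RB0005      chr1   96075   102518  Copia         1495             0.020736  0.020067  0.041997  3.000
```

RB0004's LTRs differ at 2 of 632 aligned sites (both transversions), giving
K = 0.0032 and an age of 0.23 Mya — a young, recently inserted copy; RB0005
is ten times older. `run/superfamily_counts.tsv` tallies the annotation
(here 1 Gypsy / 2 Copia / 2 Unclassified, of which 2 are younger than
2 Mya), and `run/manifest.json` records the recovery metrics against the
planted truth — for this run detection recall and precision 1.0,
classification accuracy 1.0, polymorphism sensitivity/specificity 1.0, and
an estimated-vs-true age regression slope of 1.04.

The same stages are available separately (`retroburst simulate / detect /
classify / date / polymorph / genes`) and as library functions
(`find_candidates`, `classify_elements`, `kimura2p`, `score_polymorphisms`,
`annotate_context`, ...).

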