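# Methods

## Scope and assumptions

`triovar` implements the desk-scale analysis layer of a family-quartet
recessive discovery study. Upstream read processing (trimming, alignment,
variant calling, quality filtration) and external annotation engines are
out of scope: the package consumes a called multi-sample VCF plus
per-variant `exonic`/`nonsynonymous` flags and predictor scores as
inputs. Downstream wet-lab assays are represented only by their arithmetic
(ΔΔCt, count subtraction, background correction); image segmentation and
signal acquisition are inputs.

The genetic model throughout is a fully penetrant autosomal-recessive
monogenic model with no phenocopies: affected ⇔ homozygous for the causal
allele. A reduced-penetrance mode is deliberately not offered; relaxing
the filter would change the discovery semantics, and the study design
this package mirrors treats discordance as evidence against a candidate
(surfaced in the concordance report, decided by the analyst).

## Coordinates and variant representation

All coordinates are 1-based and inclusive (VCF convention). Variants are
stored anchored (pos/ref/alt). `normalize_variant` trims to the minimal
edit and shifts pure indels through repeat runs. The default is
**3′ (right) alignment**, because protein-level reporting conventions
name an insertion in a repeat after the run's downstream-most base
(`c.4176insC` for the C₇ run at c.4170–4176); `align="left"` produces the
VCF-standard left-aligned spelling for interoperability. Complex
(unequal-length substitution) edits are reduced but not shifted.
Normalization is idempotent, and exhaustive enumeration over homopolymer
runs up to length 10 confirms that all equivalent spellings collapse to
one canonical form.

Genotype calls are diploid alt-allele dosages; any missing allele makes
the whole call missing (conservative for a discovery filter — a variant
with a missing call in the trio is dropped rather than passed; a
permissive flag inverts this). Multiallelic records are split into one
biallelic row per alt with other-alt alleles recoded as reference, which
keeps the segregation filter binary. Phasing is ignored. FORMAT fields
other than GT are carried through for unsplit biallelic records and
dropped on split rows, where per-alt semantics are undefined.

## Segregation cascade

Stages, in order: `total` → (autosome restriction by contig name,
configurable) → `exonic` (input flag) → per-trio AR filter
(offspring hom-alt AND both parents het) → `shared` (intersection across
trios) → `private` (no panel genome homozygous-alternate) →
`candidates` (indels plus nonsynonymous SNVs). The summary enforces
non-increasing counts along the chain in every variant class and raises
on violation. Panel exclusion keys on homozygosity only: a recessive
causal allele may legitimately segregate in panel carriers, so
heterozygous observations never exclude, and a variant absent from a
panel genome's records counts as not homozygous there.

## Consequence calling

Transcript models are exon lists plus CDS start/end (stop codon
included in the CDS; start/end given in transcript orientation, so
`cds_start > cds_end` on the minus strand). Projection maps a normalized
genomic variant into CDS space (reverse-complementing alleles on the
minus strand), re-3′-shifts indels *within the CDS* so naming is
strand-correct, and signals non-coding (`None`) for variants outside or
straddling the CDS — splice-site and UTR effects are not modeled.

The caller applies the edit to the extracted CDS, translates reference
and edited sequences with the standard nuclear code, and classifies by
frame arithmetic plus protein comparison (synonymous, missense,
stop_gained, stop_lost, start_lost, inframe_indel, frameshift). Protein
lengths never count the stop codon. For frameshifts the default name
uses the absolute index of the new termination codon
(`p.F1393Lfs*1395`); `dialect="hgvs"` emits the standard relative count
(`p.F1393Lfs*3`). `residues_lost` is defined as `wt_length − mut_length`
(2,268 − 1,394 = 874 in the flagship example) even though the first one
or two residues of the shifted tail are substituted rather than lost;
the substituted residue is reported separately via `first_changed_residue`
and the p. name. An independent brute-force oracle (codon-by-codon
re-translation with its own codon table) checks kind, mutant length and
stop position over hundreds of random CDS/edit pairs, and a mirrored
minus-strand transcript checks strand symmetry.

## Prioritization

Score bands follow the tools' published conventions, since banded labels
("benign", "probably damaging", "deleterious", "neutral") are reported in
such studies without thresholds: PolyPhen-2 HumDiv 0.446/0.908 band
edges, PROVEAN cutoff −2.5. With both scores present, `damaging` requires
agreement (PROVEAN ≤ −2.5 AND PolyPhen-2 ≥ 0.908) and `neutral` requires
agreement in the other direction; disagreement is `indeterminate`. With
one score, that tool's own call applies. Frameshift/stop-gain/start-loss
variants are damaging by rule (the missense predictors do not score
them). The banding is monotone: making scores more damaging can never
flip a damaging call to neutral. All three thresholds are arguments.

Disease-gene intersection is a case-insensitive, order-preserving set
membership against a local one-symbol-per-line list (e.g. an export of a
retinal-disease gene database); no live queries.

## Quantification formulas

ΔΔCt uses ideal amplification efficiency 2.0 per cycle; the reference
gene's mean Ct per sample normalizes all of that sample's target
amplicons, and the calibrator is the mean ΔCt of the designated group
(default `wild_type`). Group summaries report mean ± SD over technical
replicates; inferential statistics are delegated to standard routines.
`percent_reduction(a, b) = 100·(b−a)/b` and complements
`percent_remaining` to exactly 100.

## Synthetic data

The generator's defaults are the emulated study conditions: a quartet
with two carrier parents and two affected offspring, a 23-genome panel,
a 22-dog cohort (8 affected, 14 unaffected), and the ABCA4-like construct
(2,268 codons + stop, C₇ run at c.4170–4176 with non-C boundary bases,
TTC at codon 1393, first +1-frame stop engineered at codon 1395, no stop
in the reference frame). Values the emulated study does not pin down were
chosen once as field-plausible: a 100 kb single-contig toy genome so
end-to-end runs take seconds; 50 coding exons (the published exon count)
with intron sizes uniform in 200–1,500 bp and boundaries kept out of the
repeat-run neighbourhood; three nuisance variants per violated cascade
condition; nuisance panel allele frequencies uniform on (0.02, 0.3) with
homozygotes demoted to heterozygous except in the designated panel-hom
class; causal panel allele het-only at frequency 0.1; qPCR Ct noise SD
0.2 cycles around GAPDH ≈ 18 and wild-type ΔCt ≈ 6 with planted folds
1.0/0.6/0.25; ONL 100 nuclei per 67 µm field (INL 40, cones 10) with
multiplicative count noise CV 0.10 and a planted 46% ONL reduction;
autofluorescence background 10 AU, wild-type corrected signal 5 AU,
affected contrast 7-fold, additive intensity noise SD 0.5 AU; six
technical-replicate images per genotype group.

Determinism: one master integer seed; each generator draws from a named
substream (`default_rng([seed, k])`), making every emitted file
byte-identical across runs of the same configuration.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium and demography in the
panel, genotyping error and coverage-dependent missingness, realistic
genome-scale variant counts (the cascade's behaviour at scale is covered
structurally by monotonicity and stage-labelled elimination, not by
reproducing published genome-wide counts), sequence fidelity of the
construct to any real gene, and biological replicate structure in the
phenotype tables (technical replicates only, as in the emulated design).

The packaged validation-cohort fixture is a synthetic reconstruction of
the published 22-dog summary (8 affected hom-alt, 14 unaffected
het/hom-ref), since only the summary and a few named individuals are
printed; it is labelled synthetic in its filename and docstring.

## Numerical and edge-case choices

- Degenerate inputs: empty matrices flow through every filter and
  summarize to all-zero tables; an interval with end < start, non-diploid
  genotypes, records without GT, and ref/sequence mismatches raise typed
  errors.
- Insertions at a contig edge re-anchor on the following base (VCF
  convention for position-1 indels).
- A frameshift whose first shifted codon is already a stop is named as a
  plain nonsense substitution (`p.X123*`), with `kind` still
  `frameshift`; a frameshift that never reaches a stop inside the CDS
  reports `fs*?` and `stop_position = None`.
- Start-codon disruption dominates all other classifications (`p.M1?`).
- Trio filtering, intersection and panel privacy preserve input variant
  order; report payloads are sorted-key JSON, and the report hash
  excludes the timestamp, so identical inputs give identical payloads.

## Problem sizes used in the checks

The shipped tests run the oracle equivalences on 64 exhaustive trio
genotype combinations, 200+ random CDS/edit pairs (20–80 codons each),
randomized 23-genome panels, and 100 seeded full-cascade replicates at
the default study dimensions; the whole suite completes in a few seconds
on one CPU.

## Known limitations

Single-transcript annotation (no canonical-transcript selection or
multi-isoform reporting); no compound-heterozygote or de novo models; no
splice/UTR/NMD-escape prediction; no genotype-likelihood modeling; BCF
and structural variants unsupported; inferential statistics (ANOVA etc.)
intentionally delegated.
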