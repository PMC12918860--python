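# somamotif

Motif-centered analysis of somatic mutation catalogues: clonality filtering,
IUPAC-trinucleotide motif enrichment with the enrichment-adjusted minimum
estimate of mutation load (MEML), transcription-strand asymmetry, ID83-style
indel classification, cross-donor structural-variant hotspots with
common-fragile-site association, telomere-based division-normalized mutation
rates, and a fully seeded synthetic-cohort generator for end-to-end testing.

## Method sketch

For a motif such as `nCg>nTg` (pyrimidine representation; purine-strand
records are reverse-complemented before matching) and a catalogue of
*scattered* SNVs (no same-sample neighbor within 10 bp), four counts are
formed: motif-matching class mutations, all class mutations, and the
strand-symmetric motif-eligible / class-base positions inside the ±20 bp
context window of each class mutation. Then

```
enrichment = (mut_motif × ctx_base) / (mut_class × ctx_motif)
MEML       = mut_motif × (enrichment − 1) / enrichment
```

with MEML set to 0 unless enrichment > 1 and the one-sided Fisher's exact
test is significant (q ≤ 0.05 after Benjamini–Hochberg across units).
Clonality gates: SNV allele fraction in [0.45, 0.55] ∪ [0.90, 1.00]; SV
junction fraction in [0.40, 0.60] ∪ [0.90, 1.00] (DEL/INV/INS/TRA) or
[0.20, 0.60] (DUP). Cell divisions are estimated from telomere loss relative
to an ~11 kb newborn TRF (+1 kb assay offset, +2 kb culture add-back,
100 bp/division).

## CLI

```bash
somamotif simulate --preset chondrocyte-like --seed 1 --donors 4 --out cohort/
somamotif filter   --catalogue cohort/catalogue.tsv --af-windows 0.45:0.55,0.90:1.0 --out filtered.tsv
somamotif enrich   --catalogue filtered.tsv --ref cohort/ref.fa --level donor --out enrich.tsv
somamotif indels   --catalogue cohort/catalogue.tsv --ref cohort/ref.fa \
                   --matrix-out id83.tsv --groups-out groups.tsv
somamotif sv       --svs cohort/svs.tsv --cfs cfs.bed --window 1000000 --out svs_flagged.tsv
somamotif rates    --samples cohort/samples.tsv --out rates.tsv
```

Formats: mutation catalogues as MAF-like TSV
(`chrom pos ref alt af depth alt_reads sample_id donor_id var_class`) or
VCF 4.2; blacklist/CFS as BED3; gene footprints as BED6 (strand in column 6);
SV tables as TSV (`sv_type chrom1 pos1 chrom2 pos2 junction_af sample_id
donor_id`). Mutations are 1-based (VCF-anchored indels); interval files are
0-based half-open. The 11-motif registry ships in
`src/somamotif/data/motifs.tsv` and can be replaced via `--motifs`.

## Layout

- `somamotif.catalogue_io` — record/SV types, TSV/VCF/BED/FASTA I/O, clonality
  and blacklist filters, shared-mutation detection
- `somamotif.motif_enrichment` — motif compilation, scattered selection,
  windowed strand-symmetric counting, Fisher/BH, MEML, the per-unit panel
- `somamotif.spectra_strand` — 6-class spectra, transcription-strand
  annotation, exact binomial asymmetry test, 192-channel stranded matrix
- `somamotif.indel_classes` — left-alignment, ID83 channels, homonucleotide
  run and microhomology groupings
- `somamotif.sv_hotspots` — 1 Mb cross-donor hotspot calling, CFS overlap,
  Fisher association
- `somamotif.rates_trends` — division estimates, rate normalizations,
  Spearman (exact for small n) and rank-sum statistics
- `somamotif.synthetic_data` — seeded reference/catalogue/SV/clock simulators
  with ground-truth labels
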