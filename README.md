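# esnvsig

**Mutational-signature analysis of expressed SNVs from RNA-seq, for
identifying POLE-driven hypermutated tumors.**

Tumors with somatic mutations in the exonuclease domain of DNA polymerase
epsilon (*POLE*) are ultramutated, carry a highly characteristic
mutational signature (COSMIC v2 signature 10: TCT>TAT and TCG>TTG
enrichment), respond well to immunotherapy — and can be detected from
RNA-seq alone, without tumor/normal DNA sequencing. `esnvsig` implements
that analysis as a reusable, tested pipeline for bioinformaticians
working with tumor RNA-seq cohorts:

1. **eSNV filtering** — expressed single-nucleotide variants are kept if
   their variant-quality score exceeds 0.10, read depth exceeds 10,
   population allele frequency is below 2% (absent = novel), and the
   site is not a recurrent artifact in a panel of normals. Samples with
   a capture region (positions at ≥ 20× coverage) under five million
   bases are excluded.
2. **96-channel profiles** — each variant is mapped, after
   pyrimidine-strand collapse, to one of the 6 substitution × 16
   trinucleotide-context channels; the cohort becomes a 96 × N count
   matrix V.
3. **De novo signature extraction** — V ≈ W·H by non-negative matrix
   factorization minimizing the generalized Kullback–Leibler divergence
   D(V‖WH) with Lee–Seung multiplicative updates (best of 30 restarts;
   W columns are signatures summing to 1, H keeps the mutation-count
   scale).
4. **Catalog matching** — extracted signatures are compared against a
   reference catalog by cosine similarity; the catalog can be ordered by
   average-linkage hierarchical clustering on 1 − cosine for heatmaps.
5. **POLE calling** — per-signature tumor mutation burden
   TMB(k, s) = H[k, s] / capture_bases(s) × 10⁶ (mut/Mb); samples whose
   POLE-signature TMB lies above the Tukey fence Q3 + 1.5·IQR are called
   hypermutated, and calls are confirmed against expressed POLE hotspot
   mutations (P286R, S297F, V411L, A456P).
6. **Cohort statistics** — two-sided Mann–Whitney (exact by enumeration
   for small tie-free samples) and two-sided Fisher exact
   (point-probability rule), both implemented from first principles with
   enumeration oracles in the test suite.

A first-class synthetic-data generator (`esnvsig.simulate`) produces
reference FASTA, per-sample VCFs with quality/depth/population-AF
annotations, per-base coverage, a panel of normals, spiked hotspots and
a ground-truth manifest, so the entire pipeline is testable end to end
with known truth. The KL-NMF is exposed as a scikit-learn style
estimator (`esnvsig.KLNMF`), as is the fence caller
(`esnvsig.TukeyFenceCaller`).

## Worked example

Run the full pipeline on a synthetic 40-sample cohort with two planted
POLE-like hypermutated samples:

```python
import esnvsig as es

res = es.run_pipeline(es.RunConfig(out_dir="demo", seed=1,
                                   n_samples=40, n_hypermutated=2,
                                   restarts=10))
print(res.match_similarity.round(3))
print(res.calls[res.calls.outlier])
```

Output (abridged):

```
             SBS_POLE_like  SBS_aging_like  SBS_tobacco_like  SBS_flat
Signature_A          0.110           0.966             0.273     0.452
Signature_B          0.245           0.462             0.919     0.593
Signature_C          0.116           0.348             0.619     0.906
Signature_D          0.997           0.191             0.264     0.216

sample_id pole_signature  pole_tmb  threshold  outlier hotspots
      S19    Signature_D  17539.98    1616.18     True    P286R
      S21    Signature_D   9886.57    1616.18     True    S297F
```

Reading this: the four de novo signatures each match one catalog
process, and `Signature_D` is the POLE-like signature (cosine 0.997).
Exactly the two planted samples exceed the data-driven outlier fence
(1616 mut/Mb on the scaled-down synthetic genome), and each carries an
expressed POLE hotspot mutation — outliers and hotspot carriers
coincide, the concordance that makes the RNA-seq call trustworthy. Note
absolute mut/Mb values are large because the synthetic capture region is
~0.05 Mb; TMB arithmetic is scale-free.

The same run is available from the shell, stage by stage or end to end:

```bash
esnvsig run --out demo --seed 1
esnvsig simulate --out sim --seed 1
esnvsig filter --vcf-dir sim/vcf --coverage-dir sim/coverage --pon sim/pon.tsv \
    --min-capture 10000 --out filtered
esnvsig profile --vcf-dir filtered --fasta sim/reference.fasta --out profiles.tsv
esnvsig extract --profiles profiles.tsv --rank 4 --restarts 30 --seed 17 --out nmf
esnvsig match --signatures nmf/signatures.tsv --catalog sim/catalog.tsv --out match.tsv
esnvsig call --contributions nmf/contributions.tsv --capture-sizes filtered/capture_sizes.tsv \
    --match match.tsv --vcf-dir filtered --hotspots sim/hotspots.tsv \
    --pole-name SBS_POLE_like --out calls.tsv
esnvsig stats --calls calls.tsv --annotations sim/annotations.tsv --out stats.json
```

For real data, point `filter`/`profile` at your own VCFs (INFO keys
`QS`, `DP`, `AF1KG`; configurable), coverage TSVs and reference FASTA,
supply a COSMIC v2 catalog TSV (96 channel-label rows × signature
columns) to `match`, set `--min-capture 5000000`, and give `call` a
hotspot table with genomic coordinates on your assembly.

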