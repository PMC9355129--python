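# enhmotif

Motif-enrichment analysis of grouped enhancer sets, built around the
regulatory-genomics question of whether transcription-factor binding motifs
— in particular the TCF/LEF Wnt response element — are over-represented in
enhancers active in quiescent versus actively proliferating neural
stem/progenitor cells (NSPCs), and whether that presence is linked to
differential gene expression. The package also implements the bench-side
arithmetic that accompanies such a study: percent exon retention from gel
densitometry, 2^−ΔΔCt qPCR quantification, dual-fluorophore reporter
normalisation, and protein half-life from cycloheximide-chase time courses.

It is aimed at computational biologists who want a small, fully tested,
self-contained reimplementation of this analysis style that runs on
synthetic data with known ground truth — every statistical claim the
package makes about itself (calibration, power, recovery) is a number its
own benchmark code computes.

## What it does

Enhancers come as BED intervals labelled **Q** (quiescence-specific),
**A** (active-specific) or **PAN** (active in both states), with
soft-masked DNA sequences. The pipeline then:

1. **Scans PWMs.** JASPAR-style count matrices are converted to log₂-odds
   matrices against a background composition,

   `log_odds[b,j] = log2( (c[b,j] + s·bg[b]) / (Σ_b c[b,j] + s) / bg[b] )`,

   and only the maximally scoring placement per sequence is kept. A
   placement touching a masked base is invalid. Presence calls use the
   relative score `(score − min) / (max − min) ≥ 0.8`.
2. **Tests enrichment by bootstrap.** The observed statistic is the
   hit-fraction (or hits-per-kb) difference between enhancers and
   length-matched immediately-flanking controls; the null resamples control
   sequences with replacement, and `p = (1 + #{null ≥ obs}) / (B + 1)`.
   Between-group (Q vs A vs PAN) contrasts use a pooled-resampling null,
   and positional bias within enhancers is checked with an exact binomial
   test against uniform placement.
3. **Discovers co-motifs.** Fixed 15-bp windows flanking each + strand
   anchor occurrence (e.g. the LEF1 word 5′-CTTTGT-3′) are searched for
   exact words of length 4–8, reverse-complement collapsed, ranked by
   one-sided Fisher exact tests with greedy window removal, and mapped
   back to a PWM library by mean per-column Pearson correlation.
4. **Links motifs to expression.** Genes carry up/down/ns differential-
   expression calls (p < 0.01); motif presence at linked (or nearest)
   enhancers is crossed into a 3×2 contingency table and tested with a
   Pearson χ² on 2 df, and group-exclusive / dual-motif gene sets are
   extracted.
5. **Quantifies assays.** PSI = 100·I_FL/(I_FL+I_ΔE6); fold = 2^−ΔΔCt;
   reporter fold = (eGFP/mCherry)/(eGFP_cal/mCherry_cal); half-life from
   log-linear least squares, t½ = ln 2 / k.

A synthetic-data generator produces all inputs with configurable planted
structure (anchor spikes per group, co-motif placement beside anchors,
motif–DE odds ratios, assay noise) plus machine-readable ground truth, so
the whole pipeline is testable without any downloads.

## Worked example

```python
from enhmotif import (SyntheticConfig, counts_to_pwm, demo_motif_library,
                      gen_enhancer_dataset, bootstrap_enrichment,
                      make_flank_controls, percent_exon_retention,
                      fit_half_life, DecaySeries, GelLane)

cfg = SyntheticConfig(seed=7, n_per_group={"Q": 150, "A": 150, "PAN": 150})
data = gen_enhancer_dataset(cfg)
q = sorted(data.by_group()["Q"], key=lambda s: s.name)
controls = make_flank_controls(q, data.contigs)

lef1 = counts_to_pwm(
    [m for m in demo_motif_library() if m.motif_id == "LEF1_syn"][0]
)
res = bootstrap_enrichment(lef1, q, controls, B=999, seed=7, statistic="count")
print(f"LEF1 motif, Q enhancers vs flanks: +{res.statistic:.2f} hits/kb "
      f"(n={res.n_pos} vs {res.n_ctrl} flanks), bootstrap p = {res.bootstrap_p:.3f}")

psi = percent_exon_retention(GelLane("Q_rep1", 610.0, 390.0))
print(f"exon 6 retention: {psi:.0f}%")

fit = fit_half_life(DecaySeries("LEF1-FL", (0, 1, 2, 4, 6, 8),
                                (1.00, 0.83, 0.64, 0.45, 0.27, 0.19)))
print(f"LEF1-FL half-life: {fit.t_half:.1f} h (r^2 = {fit.r_squared:.3f})")
```

prints

```
LEF1 motif, Q enhancers vs flanks: +3.28 hits/kb (n=150 vs 300 flanks), bootstrap p = 0.001
exon 6 retention: 61%
LEF1-FL half-life: 3.3 h (r^2 = 0.997)
```

The enrichment line says the planted LEF1 word occurs about 3.3 more times
per kb in Q enhancers than in their flanks, and that none of 999 null
resamples of the flank pool reached the observed difference. The gel lane
with band intensities 610 (full length) and 390 (exon-skipped) gives 61%
exon retention, and the chase series decays with a 3.3-hour half-life.

The same stages are exposed on the command line (`enhmotif simulate`,
`scan`, `enrich`, `flanks`, `link`, `assays`), and

```sh
enhmotif run --synthetic --seed 7 --outdir out/
```

runs the full demo, writing `report.json` with the enrichment tables,
positional-bias results, discovered words with library matches, the
contingency test and the exclusive/dual gene sets, plus a provenance block
(config hash, seed, version) sufficient to reproduce the run.

## Layout

- `src/enhmotif/io.py` — FASTA / BED / JASPAR / gene-table readers and writers
- `src/enhmotif/pwm.py` — PWM construction, best-hit scanning, IUPAC
  matching, motif–motif comparison
- `src/enhmotif/enrichment.py` — flank controls, bootstrap enrichment,
  positional bias
- `src/enhmotif/cooccur.py` — anchor-flank windows, word discovery,
  word-to-motif mapping
- `src/enhmotif/linkage.py` — nearest enhancers, 3×2 contingency χ²,
  exclusive gene sets
- `src/enhmotif/assays.py` — PSI, ΔΔCt, reporter ratios, half-life fits
- `src/enhmotif/synthetic.py` — the ground-truthed data generators
- `src/enhmotif/benchmarks.py` — calibration/power/recovery measurements
- `src/enhmotif/pipeline.py`, `src/enhmotif/cli.py` — orchestration and CLI

See `docs/methods.md` for the modelling choices, defaults and limitations.
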