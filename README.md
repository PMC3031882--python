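# quadclone

Clonal heterogeneity and treatment-selection analysis of multi-quadrant,
multi-timepoint array-CGH copy-number profiles.

Locally advanced cervical cancers are treated with chemoradiotherapy,
and some fail it. One candidate explanation is intra-tumour genetic
heterogeneity: a tumour that contains several genetically distinct
subpopulations — all descended from one transformed cell — can harbour a
minor, intrinsically resistant clone that survives treatment and seeds
relapse. `quadclone` is a pipeline for testing that hypothesis from
spatially and temporally repeated biopsies: four quadrants of the
cervix, profiled by array CGH before treatment and after weeks 2 and 5
of chemoradiotherapy. It is written for researchers analysing
multi-region copy-number data, and ships both a ground-truthed
clone-mixture simulator and machine-readable transcriptions of a
published 10-case study's per-sample profile flags and per-case
aberration tables, so the whole pipeline is exercisable without any
external download.

## What it computes

Starting from probe-level log2 ratios (tumour/normal), per sample:

1. **Normalise** (median-centre) and **segment** with circular binary
   segmentation — recursively split each chromosome at the arc (i, j)
   maximising the two-sample t statistic
   `|x̄_in − x̄_out| / (s·√(1/n_in + 1/n_out))`, accepted when its
   permutation p-value < α;
2. **Call** segments: amplification iff mean log2 > 1.5, homozygous
   deletion iff < −1.5, gain/loss at ±0.2 by default. A biopsy with
   tumour-cell fraction *c* shows a copy-number-*n* region at
   `log2((c·n + (1−c)·2)/2)`, so stroma-rich biopsies read as normal;
3. **Extract and match events** across the case's samples into a
   catalogue in the clinical dialect ("p tel–13.2 Loss",
   "141.6–q tel Gain", "Whole chr Gain", "Further gain"), then
4. classify events **hom/het** (homogeneous iff present in every
   aberrant sample), cluster samples into **subpopulations**, build a
   neighbour-joining **phylogeny** over samples plus a diploid NORMAL
   outgroup (branch lengths = event counts), infer **trunk events**
   (changes common to all subpopulations — the early events of
   carcinogenesis), and call per-quadrant **trajectories** under
   treatment: clearance, persistence, or replacement.

## Worked example

Analyse one of the packaged published cases at the event level:

```bash
quadclone analyze --fixture-case CE01-13 --out out/
cat out/CE01-13_report.json
```

```json
{
  "case": "CE01-13",
  "labels": {
    "q1_wk0": "A", "q2_wk0": "A", "q2_wk5": "B",
    "q3_wk0": "B", "q4_wk0": "C"
  },
  "heterogeneous": true,
  "n_subpopulations_week0": 3,
  "trunk_events": [
    "3 141.6-q tel Gain",
    "4 167.4-170.1 Loss",
    "9 p tel-13.2 Loss",
    "15 89.3-q tel Loss"
  ],
  "trajectories": {"1": "CLEARANCE", "2": "REPLACEMENT",
                   "3": null, "4": "CLEARANCE"},
  "residual_disease_week5": true
}
```

Reading it: the tumour is genetically heterogeneous — quadrants 1/2
carry one genotype (A) and quadrant 3 another (B), with quadrant 4
holding a third, related variant. The trunk events (3q-terminal gain,
the focal 4q change, 9p loss, 15q-terminal loss) are shared by every
subpopulation and therefore predate their divergence — the early events
of this tumour's carcinogenesis, including the 3q gain classically
placed at the transition to invasive disease. Under treatment, quadrant
2's original genotype was **replaced** by week 5 with genotype B, the
one previously dominant in quadrants 3/4 — selection of an intrinsically
resistant subpopulation — and residual disease persists at the end of
treatment (`out/CE01-13_map.csv` shows the quadrant × week grid; the
Newick tree with the NORMAL outgroup is in `out/CE01-13.nwk`).

Simulated data works the same way end to end:

```bash
quadclone simulate --seed 7 --lineages 2 --trunk 3 --branch 4 --out sim/
quadclone analyze --probe-dir sim/ --out sim_out/
```

which writes per-sample probe tables plus a `truth.json` manifest
(clone genotypes, per-quadrant clone fractions and cellularities) that
the analysis output can be scored against.

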