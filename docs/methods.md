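# Methods

`quadclone` analyses multi-region, multi-timepoint array-CGH copy-number
profiles of one tumour at a time: four quadrantic biopsies of the cervix,
sampled before treatment and after weeks 2 and 5 of chemoradiotherapy,
each yielding probe-level log2 ratios of tumour vs normal DNA abundance.
The pipeline asks three questions. Is the tumour genetically
heterogeneous — does it contain more than one subpopulation descended
from a common malignant ancestor? Which copy-number events are early
(trunk) events, predating subpopulation divergence? And how does
chemoradiotherapy reshape the spatial distribution of subpopulations —
clearance, persistence, or replacement per quadrant?

## Model and assumptions

The underlying model is monoclonal origin with divergent evolution: all
tumour cells descend from a single transformed cell, subpopulations
accumulate private copy-number aberrations after divergence, and events
are neither lost nor gained twice (perfect phylogeny). Under this model

* every aberrant sample of a case shares at least one event (the trunk),
* the set distance between two samples' event catalogues is additive on
  the clone tree, and
* events common to all subpopulations predate divergence.

Real tumours violate perfect phylogeny in places (the published case-13
chromosome-15 ladder is carried by quadrants on *both* sides of the
lineage split), which is why subpopulation assignment is a clustering
decision with an explicit separation threshold rather than a theorem.

A biopsy is a mixture: a fraction *c* (cellularity) of tumour cells —
themselves a mixture of clones with fractions *f_i* — and 1−*c* diploid
stroma. The expected probe log2 ratio over a region of clone copy
number *n_i* is

    log2( (c·Σ f_i·n_i + (1−c)·2) / 2 )

floored at −4 to avoid −∞ at homozygous deletions. Stroma compresses
every aberration towards 0, which is why low-cellularity biopsies read
as normal and why "profile normal" is treated as a statement about
cellularity, not genotype.

## Pipeline stages

**Normalisation.** Median-centring of each profile; valid because the
large majority of probes are copy-number neutral.

**Segmentation (CBS).** Circular binary segmentation: within each
chromosome, the arc (i, j) maximising the pooled-variance two-sample
t statistic between probes inside and outside the arc is tested by
permutation (probes shuffled within the chromosome); if p < alpha
(default 0.01, default 10 000 permutations; tests use a few hundred) the
split is accepted and recursion continues on the pieces. Numerical
choices: ties in the max statistic (complementary arcs are analytically
equal) are broken towards the smallest start index, then smallest width,
with near-equality at relative 1e-10; a zero pooled variance with a
non-zero mean difference scores +inf, so noiseless steps always split;
chromosomes with fewer than 4 probes are returned whole; the permutation
stream is seeded per (chromosome, sub-interval), making results
reproducible and independent of recursion order, and guaranteeing that
decreasing alpha never adds segments. Permutation batches stop early
only when the full-run p-value is already guaranteed to exceed alpha, so
early stopping never changes a decision. Adjacent segments whose means
differ by less than `undo_sd` (default 1.0) × the scaled MAD of probe
residuals are re-merged (DNAcopy-style "undo"). Segments span first to
last probe; they partition the probe sequence, not the base-pair line.

**Calling.** Fixed definitions: amplification iff segment mean log2
> 1.5 and homozygous deletion iff < −1.5. Single-copy gain/loss
thresholds default to ±0.2 log2 — a conventional aCGH choice; the
mixture equation above tells you what they imply (a single-copy gain is
callable at cellularity ≳ 0.3). A profile is *abnormal* iff it has at
least one non-neutral segment of ≥ 10 probes and ≥ 2 Mb.

**Events.** Maximal runs of equally-called segments become typed events
in the clinical reporting dialect: endpoints in Mb (one decimal),
snapped to "p tel" / "cen" / "q tel" when within tolerance or when the
event reaches the first/last probe of the chromosome (the array cannot
see beyond its probes); gains above `further_gain_thr` (default 0.8,
roughly a second gained copy in pure tumour) are reported as "Further
gain" adjacent to the level-1 gain. Sub-threshold gains/losses smaller
than 10 probes or 2 Mb are discarded as noise; amplicons and homozygous
deletions are exempt, being focal by nature. Cross-sample matching:
two events are the same catalogue entry iff same chromosome and kind
(level-aware) and both endpoints agree — token-for-token for landmarks,
within `tol_mb` for numeric endpoints — transitively closed by single
linkage. All matching and snapping tolerances are resolution-aware: at
least the dialect's 1.0 Mb, and at least 3 median probe spacings,
because breakpoints are only localised to the probe grid (on a 180k
array the second bound is ~0.05 Mb and irrelevant; on the 4000-probe
test grid it is the binding one).

**Heterogeneity.** An event is homogeneous (HOM) iff present in every
aberrant sample of the case; normal-profile samples never veto, since
their normality reflects stroma. Subpopulations: average-linkage
hierarchical clustering of aberrant samples under the event distance,
cut at the largest merge-height gap provided the resulting separation is
at least `d_split` (default 3 events) — smaller differences are
subclonal variation within one population. The default distance counts
differing events (symmetric Hamming); a span-weighted variant (Mb of
differing events) is available and is the one that reproduces the
published case-13 lineage split, because arm-level lineage markers then
outweigh recurrent focal jitter. A case is heterogeneous iff it has ≥ 2
subpopulations; by default subpopulations observed only during treatment
count ("inferred pre-existing" mode), because under monoclonal evolution
a genotype cannot arise de novo at detectable levels within two weeks —
a week-0-only mode is available.

**Phylogeny.** Neighbour joining on the pairwise event distance between
samples plus an all-zero diploid NORMAL outgroup, so branch lengths read
as event counts from germline. Negative NJ branch lengths (impossible
under additivity, possible off it) are clamped to zero with the deficit
moved to the sibling branch. Trunk events are the intersection of the
subpopulations' consensus genotypes; a consensus contains the events
present in ≥ `consensus_threshold` of the label's samples (default 0.5,
which tolerates detection dropout in individual low-purity samples). An
empty trunk is flagged, as it would contradict monoclonal origin.

**Dynamics.** The quadrant × week grid holds a subpopulation label,
NORMAL (sample present, profile normal) or MISSING (no sample). Each
quadrant's trajectory compares its first and last observed states:
CLEARANCE (label → NORMAL), PERSISTENCE (same label), REPLACEMENT
(different labels). A quadrant missing at the end of treatment gets no
call — absence of a biopsy is not evidence of clearance. Residual
disease at week 5 = any labelled cell in the final column; the resistant
label is the week-5 label when unique.

## Synthetic data generator

The generator produces the study design the analysis assumes: a trunk
ancestor (default 3 events) with one leaf clone per lineage (default 2
lineages, 4 private events each), each quadrant dominated by one lineage
(quadrants 1–2 vs 3–4 in the two-lineage default), biopsy cellularity
drawn uniformly from 0.4–0.9 (the range in which single-copy events are
callable at the default thresholds), i.i.d. Gaussian probe noise of
sd 0.15 log2 units, and chemoradiotherapy acting multiplicatively on
clone fractions between weeks (sensitive lineages survive at 0.01 —
complete response, below the 10% detection floor for the whole
cellularity range — while the resistant lineage survives at 1.0).
Events are placed uniformly over chromosome arms with log-uniform
lengths from ~2 Mb (and at least 20 probes, the scale at which segment
means are stable at the default noise) up to a whole arm, occasionally a
whole chromosome, all mutually non-overlapping with a few probes'
padding so distinct events can never fuse into one segment in any
genotype — making the simulation perfect-phylogeny by construction and
every downstream stage exactly scorable. Output is byte-deterministic
given the seed.

What the generator does **not** emulate — hence what passing tests do
not show about real arrays: GC/wave artefacts and dye bias, probe-level
quality variation, overlapping rearrangements on one lineage
(gain-within-gain other than the explicit further-gain levels),
homoplasy and event loss, subclonal mixtures within one biopsy
(quadrants are pure single-clone tumour plus stroma), and allele-level
signal. The published tables themselves, shipped as machine-readable
fixtures, are the counterweight: the event-level half of the pipeline is
exercised on real, homoplasy-containing data.

## Problem sizes and verification

Desk-scale runs use a ~4000-probe genome (hg18-era chromosome lengths
and centromeres; X kept diploid for this all-female disease) rather than
the 180k production grid, with CBS at a few hundred permutations. The
test suite verifies: CBS's first split against an independent exhaustive
search on sequences ≤ 30 probes; exact catalogue/trunk/partition/
trajectory recovery in 50/50 noiseless pure-tumour simulations; ≥ 90%
trunk-event recovery and ≥ 90% exact partition recovery over 100 noisy
simulations at the default study conditions; NJ path-length additivity
to 1e-9 on 50 perfect-phylogeny inputs; and, on the packaged published
tables, the event bookkeeping (trunk sets per case, hom/het statuses,
the maximum pairwise difference of 17, heterogeneous-case and
residual-disease counts, and the cohort arithmetic 19 − 6 − 3 = 10).

## Known limitations

Event-count distances treat a whole-chromosome loss and a 2 Mb deletion
as equally informative; span weighting is provided but not default.
Hom/het status and trunk inference inherit the detection limits of the
assay — events private to low-cellularity samples are invisible, so
heterogeneity is a lower bound. Trajectories are endpoint comparisons;
week-2 states are displayed but do not enter the calls. No statistical
test is attached to the heterogeneity verdict (`d_split` is an explicit
operational threshold, not a significance level), and no survival or
outcome statistics are computed from the 10-case clinical table.
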