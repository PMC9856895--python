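# Methods

`riplab` implements the computational arm of a *Drosophila* long-term-memory
study design: identifying the mRNA targets of an RNA-binding protein (the
CPEB-family protein Orb2) from RNA immunoprecipitation sequencing, scoring
conditioned-courtship memory with randomization statistics, counting
cytoplasmic polyadenylation elements (CPEs) in 3′UTR isoforms, and
quantifying proteins and transcripts from dilution-series immunoblots and
qPCR. Every stage can be exercised end to end on synthetic data whose
ground truth is recorded.

## RIP-seq target calling

Input is a gene-level count table for three libraries: **Input** (total
lysate RNA), **IP** (anti-GFP pull-down of the tagged protein) and
**mock IP** (pre-immune IgG, measuring nonspecific capture). Counts are
normalized to counts per million with a pseudocount:

    cpm(g, s) = 1e6 · (count(g, s) + c) / Σ_g' (count(g', s) + c)

so each column sums to exactly 10⁶. The default pseudocount c = 0.5 keeps
both enrichment ratios — IP/Input and IP/mock — finite for genes absent
from one library; c = 0 recovers exact proportions and is supported for
scale-invariance reasoning. A gene is **detected** when its raw count is
≥ 1 in both Input and IP (mock is deliberately not consulted: absence from
the mock is evidence *for* specificity, not against detection). Detection
by raw-count presence is the weakest defensible reading of "detected"; a
CPM floor would be an alternative and can be emulated via `min_count`.

Calling is calibrated on three positive-control transcripts known to be
bound (defaults `orb2`, `act5C`, `tub56D`): the per-ratio threshold is the
**minimum** of that ratio over the three controls, and a gene passes when
it is detected, protein-coding, and **both** ratios are ≥ their thresholds.
Ties pass, so the controls always survive their own calibration. Among the
readings of "discard genes with enrichment lower than the controls'" (min
vs max over controls, per-ratio vs combined score) this is the most
permissive consistent one; the choice is exposed, not hard-coded, since
`calibrate_thresholds` simply consumes a table.

A consequence worth knowing: the min-over-three-controls statistic is an
extreme-value estimate and therefore noisy. When sampling noise drags one
control's ratio toward 1, the threshold collapses and the false-discovery
proportion of a run rises sharply even though average behavior is good.
The acceptance script reports recall/FDP averaged over five replicate
simulations for this reason.

## Courtship memory statistics

The courtship index CI is the percentage of a 300-s observation window a
male spends courting; overlapping bouts are merged before summing so time
is never double-counted. The learning index is

    LI = (CIn − CIexp) / CIn × 100,

with CIn the mean of two independent naive-sample means and CIexp likewise
for trained males. LI is undefined at CIn = 0 and equals 100 when trained
males do not court at all.

Group differences use a sampled randomization test on per-male CIs (the
permutation unit is the male; permuting at the level of replicate samples
is possible by passing sample means instead). α_R is estimated as
(b + 1)/(m + 1) over m label permutations, where b counts statistics as or
more extreme than observed — |·| for two-sided tests (CI comparisons),
signed upper tail for one-sided tests (LI comparisons) — so α_R is never 0
and the test is valid at finite m. Whenever the number of distinct
assignments C(n_a+n_b, n_a) is ≤ the permutation budget the test switches
to exhaustive enumeration and α_R = b/m is exact. For the learning-index
statistic the two samples per arm are pooled and LI is recomputed per
permutation. The default budget is 10,000 permutations and the decision
convention is reject at α_R < 0.05. Floating-point ties at the observed
statistic are counted as extreme (a 10⁻¹² relative tolerance), which is
the conservative direction.

## CPE census

CPEs are U-rich 3′UTR elements, split into canonical A-containing and
noncanonical G-containing classes. Scanning is single-stranded (the mRNA
sense written as DNA), case- and U/T-insensitive, reports every occurrence
at its distinct start (overlaps each count), and N never matches. Patterns
are fixed-length IUPAC strings. The default motif set
(`TTTTAT/TTTTAAT/TTTTTAT` canonical, `TTTTGT/TTTTGAT/TTTTTGT`
noncanonical) is an explicitly non-authoritative stand-in: published
per-isoform CPE counts derive from motif definitions in the primary CPEB
literature, so reproducing a published census requires supplying that motif
set (`--motifs motifs.yaml`). `apply_deletion` removes a 0-based half-open
interval and joins the flanks, mimicking 3′UTR deletion alleles; motifs
spanning a breakpoint are destroyed unless the junction recreates a match,
because the census is taken on the joined sequence. Coordinates are
BED-compatible throughout.

## Immunoblot and qPCR quantification

Dilution-series blots load each sample at several relative loads (the
ladder is always read from the data; 1/2, 1/4, 1/6 is only the simulator
default). Both the chemiluminescent and the total-protein channel are
proportional to load, so each is summarized by a least-squares slope
through the origin (b = Σxy/Σx²) and the normalized level is the ratio of
slopes — invariant to joint rescaling and to the ladder. An intercept is
deliberately not fitted: stain-free total-protein normalization already
removes background, and an intercept would absorb real signal at low
loads. Genotype arms are compared by a two-sample t-test on per-replicate
levels (Welch by default; pooled variance available), and the reported
ratio is the ratio of arm means.

qPCR relative expression uses 2^−ΔΔCt with amplification efficiency fixed
at 2.0 (no standard-curve modeling), ΔCt = Ct_target − Ct_reference and
ΔΔCt taken against a calibrator sample; the calibrator is exactly 1 by
construction. IP yield is reported as percent of input with the input Ct
adjusted by −log₂(input fraction) and the result scaled by the input
fraction (default 0.05, i.e. 100 µL of a 2-mL lysate); both appear in the
definition so the formula matches the conventional worked example
(ct_input 20, ct_ip 22.32, fraction 0.05 → 20%).

## Gene-set statistics

Overlap of a called list with a published set reports counts, the
percentage of the reference set recovered, and an upper-tail
hypergeometric p-value given a user-chosen universe (the percentage is
universe-independent; the p-value is not). Over-representation of
annotation terms reports fold enrichment
(term frequency in targets)/(term frequency in universe), hypergeometric p
and Benjamini–Hochberg q across tested terms (terms with no target member
are skipped). The default universe is the detected protein-coding genes —
the sampling frame of the called list. Annotation is a local term→gene
table or GMT file; no web services are consulted, trading convenience for
reproducibility.

## Synthetic data

The generators emit the statistical structure the analysis assumes, with
ground truth recorded, from a single seeded NumPy generator per call.

**RIP-seq.** Baseline relative abundances are lognormal (log-sd 1.0, a
typical bulk RNA-seq dynamic range); expected counts are abundances
renormalized to the library size (10⁶ per library by default); counts are
negative binomial parameterized by (mean, dispersion) with
variance = mean + dispersion·mean² (dispersion 0.02, the regime of good
technical replicates; 0 gives Poisson). Planted targets (500 of 5000 by
default) have IP abundance multiplied by 4, the three positive controls by
2, before IP renormalization — so observed CPM ratios are diluted by the
enriched mass fraction, exactly as in real data. `28S` is assigned biotype
"other" (rRNA) and `RplP0` is an unenriched protein-coding negative
control. Not modeled: positional/fragment bias, isoform structure,
batch effects between libraries.

**Courtship.** Per-male CI is Beta(μκ, (1−μ)κ) with group means 0.6
(naive) and 0.3 (trained) by default — round placeholders for an
unreported effect size, at concentration κ = 20 (CI sd ≈ 0.10, typical of
courtship assays) — emitted as a single bout at a uniform offset, since CI
depends only on total courtship time. n = 20 males/group and 300-s windows
by default. Bout microstructure, habituation within the window and
between-replicate batch effects are not modeled, so passing tests speak to
the statistics, not to ethogram realism.

**Western.** Per lane, chemi = level·load·ε and total = load·ε′ with ε
unit-mean lognormal of coefficient of variation `cv` (default 0.1);
default true levels put the mutant at 1/3 of wild type, the synaptic-
fraction depletion regime, with the 1/2, 1/4, 1/6 ladder and 5 replicates.

**UTR.** Motifs are planted at uniformly drawn non-overlapping positions
in a GC-0.4 background; the assembled sequence is then screened so that it
contains no unplanted occurrence of any configured motif. Screening is
iterative repair — only background letters inside an offending occurrence
are resampled, since wholesale rejection of a kilobase AT-rich background
essentially never succeeds — with placements redrawn when two adjacent
planted motifs jointly spell a screened motif, all bounded by 10,000
attempts. A planted motif that *contains* another screened motif (e.g.
TTTTTAT contains TTTTAT) is rejected outright, since no layout can repair
it; choose non-nested motif sets when planting.

## Numerical conventions and degenerate inputs

Thresholds use ≥ (ties pass). Called lists sort by descending IP/mock
ratio, gene id as tie-break, so output order is total and reproducible.
Empty count tables, all-zero columns with pseudocount 0, bouts outside the
observation window, fewer than two distinct loads, missing reference Cts,
non-positive input fractions and out-of-bounds deletion intervals all fail
fast with named errors; the CLI maps validation errors to exit code 2 and
computation errors to 3. Randomization α_R is bounded below by
1/(m + 1) in sampled mode and by 1/m in exhaustive mode.

## Problem sizes

Default test and acceptance runs use 5000-gene / 500-target RIP
simulations, 1000-repetition null calibrations at 10,000 permutations
each (vectorized over permutations), 200-run power simulations for the
dilution-series comparison, and 5.8-kb UTR censuses — sizes chosen to make
Monte-Carlo error small relative to the tolerances being checked while a
full run of suite plus acceptance script stays comfortably under a minute.

## Known limitations

- The default CPE motif set is a stand-in; published per-isoform counts
  are not reproducible without the original motif definitions.
- The calibrated-threshold caller inherits the fragility of min-over-three
  controls (see above); it reports no per-gene uncertainty.
- `percent_of_input` follows the stated worked-example convention in which
  the input-fraction adjustment and the input-fraction multiplier cancel
  algebraically; supplying a fraction therefore documents the protocol but
  does not change the value.
- Randomization tests assume exchangeability of males across groups under
  the null; block structure (testing day, replicate chamber) is not
  modeled.
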