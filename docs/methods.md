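# Methods

## Input model and conventions

The central record is one tested cytosine in one sample: transcript,
position, 9-mer context, coverage, stoichiometry, prediction
probability. Positions are **0-based on the spliced transcript and
point at the C itself**; callers that index the start of the 9-mer
window are normalized at parse time with `position_offset=4` and a
configurable column map. Parsing is strict by default — any invariant
violation (center base not C, stoichiometry or probability outside
[0, 1], duplicate site keys) raises with row-numbered diagnostics;
lenient mode drops and reports offending rows instead, and always
satisfies accepted + rejected = input rows. Silent coercion is never
performed: a malformed table is a caller bug, not data.

Annotation is GTF (Ensembl/GENCODE dialect), parsed with `gffutils`
and converted from 1-based closed to internal 0-based half-open
intervals. Exons are stored in transcription order (reversed for the
minus strand) and the CDS is projected into transcript coordinates by
mapping the genomic endpoints of every CDS interval through the exon
structure; a CDS not contained in the exons is an error for that
transcript. Transcripts without a CDS are treated as non-coding, never
guessed.

## Site selection

A site is high-confidence iff coverage ≥ 8 reads **and** probability
strictly greater than 0.9999 — the strict inequality matters at the
boundary and is tested. The funnel's middle "called" tier uses a
softer probability bound (default 0.5, configurable; clamped to the
high-confidence bound so the tiers always nest). Replicate consensus
keeps sites present in both replicates with |Δstoichiometry| ≤ 0.1
(the consistency requirement is otherwise unquantified, so the
tolerance is an exposed parameter); the merged record carries the
coverage-weighted mean stoichiometry/probability and the summed
coverage.

Gene-level pooling ("sites per gene") deduplicates sites shared by
splice variants **by genomic base**, which requires the strand-aware
transcript→genome projection; a transcript-keyed mode is available by
flag. The shared-site (Venn) computation likewise offers both
site-level `(transcript, position)` keys and gene-level keys, since
either view is meaningful and published figures are not always
explicit about which they use.

## Transcript geometry

The metatranscript axis maps 5′UTR → [0, 1), CDS → [1, 2), 3′UTR →
[2, 3), each region scaled linearly to unit length; the first CDS base
sits exactly at 1.0 and the first 3′UTR base at 2.0. Default 90 bins
(30 per region) keep region boundaries on bin edges. Non-coding
transcripts are excluded and tallied, not force-mapped.

Splice junctions live at cumulative exon lengths (excluding the
total); a junction coordinate names the first base of the downstream
exon, so distance 0 identifies exactly the first base of a non-first
exon — an off-by-one here silently shifts every distance histogram,
which is why the convention is pinned by tests against exhaustive
enumeration. Zone classification uses a closed proximal window
[0, 100] nt and a half-open flank (100, 400] nt; endpoint inclusion is
a documented choice, not a published constraint. Both absolute and
signed (upstream/downstream) distances are available.

Genomic window densities tile each chromosome half-open — [0, W),
[W, 2W), … with W = 27 Mb by default — and count distinct genomic
bases, so variant-shared sites increment one window once.

## Statistics

**Motif-conditioned stoichiometry comparison.** Sites are selected by
an IUPAC 5-mer pattern anchored at the modified C (the 5-mer is the C
plus four downstream bases — the published predominant contexts CCAGC,
CCCAG, CCTGC and the Type I CNGGG all start at the C). The default
test is the two-sided unpaired Wilcoxon rank-sum: exact enumeration
when n_A + n_B ≤ 12 without ties, normal approximation with tie
correction otherwise. A paired signed-rank mode joins sites observed
in both conditions, for designs where the same sites are measured
twice. Fewer than 3 sites on either side flags the result underpowered
(p undefined) rather than returning a misleading number.

**Per-site differential test.** Read counts are reconstructed as
modified = round(stoichiometry × coverage) with round-half-to-even
(bias-free at .5 boundaries) and tested with Fisher's exact test on
[[mod_A, unmod_A], [mod_B, unmod_B]]. A read-level rank-sum test as
performed by callers with access to per-read probabilities is not
reproducible from per-site summaries; the count-based exact test is
this package's defined per-site test, with a two-proportion z-test
option for large counts. The adjustment procedure is
Benjamini–Hochberg by default (Bonferroni selectable). The labeling
fold change is stoichiometry-based (ε = 0.01 pseudocount, exposed); a
counts-based variant is computed alongside. Labels: hyper when A > B
with |log2FC| ≥ 1 and adjusted p < 0.001, hypo for the mirror image.
Top-k extraction ranks by adjusted p, then |log2FC|, then
(transcript, position) for full determinism.

**Expression association.** Stoichiometry strata are left-closed
right-open with the last bin closed ([0.8, 1.0]), so every value in
[0, 1] maps to exactly one of the five bins. Mann–Whitney U per
stratum is exact for ≤ 8 tie-free observations per side. The global
correlation uses x = methylation log2FC and y = log2((tpm_A + ε)/(tpm_B
+ ε)) with ε = 0.01; points with x = 0 or y = 0 sit on a quadrant axis
and are counted separately rather than assigned arbitrarily.
Site-level points are the default; a transcript-aggregated mode (mean
log2FC per transcript) exists because multiple sites can share a
transcript.

**Decay kinetics.** RQ = 2^−[(Ct_target,t − Ct_ref,t) − (Ct_target,0 −
Ct_ref,0)], with replicates averaged on the Ct scale for display
series; for regression, replicates are pooled as individual points
(averaging first would understate residual variance), each normalized
against the common t = 0 calibrator. The fit is OLS of ln(fraction) on
time with a free intercept (absorbing plating offsets; a pinned-at-zero
mode exists); k = −slope, half-life = ln 2 / k for k > 0, and k ≤ 0 is
flagged "stable" with an undefined half-life. The condition comparison
is a pooled regression with condition, time and condition × time
terms; the two-sided t-test on the interaction is the headline test,
with per-timepoint Welch t-tests as a descriptive companion.
Degenerate zero-residual designs (noiseless inputs) return p = 1 for
identical slopes and p = 0 otherwise instead of a 0/0 artifact.

## Synthetic-data generator

The generator emulates the statistical structure of a writer-knockout
m⁵C profiling experiment at desk scale, with every parameter surfaced
in `SimConfig`:

- **Transcriptome** — 150 genes over 4 toy chromosomes, ~4 exons per
  transcript (Poisson), exon lengths 80–400 nt, 30% of eligible genes
  carrying a second exon-skipping splice variant (so variants share
  genomic sequence and exercise genomic deduplication), 90% coding
  with the 3′UTR longer than the 5′UTR. CNGGG motifs are planted at
  ~3 per kb of exon so Type I contexts are well represented.
- **Site universe** — 20,000 tested cytosines shared by both
  conditions, placed with a 4× weight on 3′UTR cytosines. 1% are real
  m⁵C sites (probability planted strictly above 0.9999); selection of
  real sites up-weights CNGGG contexts 8×. Background probabilities
  follow a right-skewed Beta scaled below 0.9999, chosen so that
  together with the real sites roughly 7–8% of tested cytosines exceed
  a 0.5 "called" bound — under 10%, as in the emulated funnel.
- **Stoichiometry** — Beta distributions (natural [0, 1] support) with
  concentration 10: Type I mean 0.60 in WT and 0.25 in KO (the planted
  writer-dependent depletion), background mean 0.40 in both
  conditions, noise sites Beta(1, 3). Replicates share the per-site
  base value, jittered with σ = 0.02 — well inside the 0.1 consensus
  tolerance. Coverage is negative binomial (mean 30, dispersion 5).
- **Expression** — per-transcript baseline log2 TPM ~ N(4, 1.5); the
  knockout-vs-WT expression log2FC is β·x + N(0, 0.5) where x is the
  transcript's methylation log2FC and β is solved so the population
  Pearson correlation equals the configured target (0.263 by default).
  TPMs renormalize to 10⁶ per condition (a within-sample constant, so
  the correlation is unaffected).
- **Ct series** — Ct_target(t) = Ct₀ + k·t/ln 2 + N(0, 0.05) (one Ct
  cycle per transcript halving), flat reference gene, timepoints 0, 3,
  6, 9 h, 3 replicates. The default rate map includes two genes with
  equal WT/KO rates, two with mild stabilization and two with clear
  knockout stabilization (half-life doubling).

Randomness flows from one master seed through named `SeedSequence`
child streams — one per output — so regenerating one artifact never
perturbs another and identical configurations produce byte-identical
files.

**What the generator does not emulate**, hence what passing tests do
not show about real data: per-read signal artifacts and coverage
biases along transcripts, junction-proximal site depletion (placement
is motif- and region-weighted only, so the junction-zone histogram
exercises the machinery, not the biological pattern), transcript
families/paralogy, batch effects between replicates beyond the
stoichiometry jitter, and amplification-efficiency differences in
qPCR. The end-to-end measured methylation–expression correlation on a
default bundle (~0.18–0.21 at ~190 shared sites) sits below the
planted population value of 0.263 because the coupling is planted at
the transcript level while measurement is per-site on jittered
replicate-consensus stoichiometries — the same attenuation a real
experiment exhibits.

## Numerical choices and problem sizes

Exact tests (Fisher, rank-sum, Mann–Whitney) come from scipy;
independent enumeration oracles in the test suite verify them — the
Fisher test exhaustively over all 2×2 tables with N ≤ 24 plus 1,500
random tables up to N = 60, the rank-sum and Mann–Whitney tests by
full arrangement enumeration on small samples. Benjamini–Hochberg is
statsmodels', checked against the step-up formula on random vectors.
Geometry is verified against per-base brute-force walks on 1,000
randomized transcript models. Simulation-recovery checks use 100
seeded runs each (300 sites per arm for the motif contrast, 2,000
sites for the expression coupling, 12-point Ct series for decay);
these sizes give the power the checks assert while keeping the whole
suite under half a minute.

## Known limitations

- GTF is the only annotation dialect (no GFF3); BAM/FAST5/POD5 and
  caller internals are out of scope — the per-site table is the
  contract.
- The per-site differential test treats reconstructed counts as
  independent Bernoulli reads; overdispersion across reads within a
  site is not modeled.
- No amplification-efficiency correction in 2^−ΔΔCt.
- No motif discovery — only fixed-window k-mer statistics anchored at
  the called C.
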