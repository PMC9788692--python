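# Methods

This note records the models, conventions and numerical choices behind
varmotif, and what the synthetic-data generator does and does not emulate.

## Alignment model and Stockholm dialect

The unit of analysis is a single-alignment Stockholm 1.0 file with a
`#=GC SS_cons` line. Structure characters follow WUSS conventions: any of
`<> () [] {}` forms the nested layer, matched letter pairs (`A…a`, `B…b`)
form pseudoknot layers, and `.,_-:~` are unpaired. Nested pairs must be
non-crossing among themselves; pseudoknot pairs may cross them. Because no
standard Stockholm tags exist for the per-sequence labels this analysis
needs, a documented dialect is used: `#=GS <id> GENE <domain>`,
`#=GS <id> PHYLUM <name>`, `#=GS <id> ENV <gut|non_gut|unknown>`. Unknown
`#=GS` tags survive read/write round trips verbatim.

Sequences are normalised to uppercase RNA (T→U). IUPAC degeneracy codes are
treated as gaps and counted in a warning, rather than being fractionally
assigned: they are rare in curated alignments and must not silently skew
column frequencies. Columns and sequence positions are 1-based throughout.

Deduplication keys on the ungapped sequence string and keeps first
occurrences; removal of rows claimed by a homologous motif's alignment takes
an explicit id list, since overlap criteria (coordinate overlap vs identical
hit) vary between curation workflows.

## Consensus conservation model

Column profiles count residues and gaps exactly; identity fractions are
computed among non-gap residues only, so a column's identity and its
presence are separated. Tier thresholds (identity 97/90/75 %, presence
97/90/75/50 %) follow the convention of standard consensus-diagram software,
so varmotif's tabular output can be read like the familiar diagrams.

Covariation is scored as mutual information (base 2) of the joint residue
distribution over rows where both columns are non-gap (pairwise, not
listwise, deletion — this maximises usable rows per pair). The average
product correction is computed over the background of **all** column pairs:
APC(i,j) = MI̅(i)·MI̅(j)/MI̅, with column means over pairs having at least
5 jointly present rows (fewer rows give unstable marginals; such pairs also
carry a low-support flag and are never called covarying). The covarying call
additionally requires ≥ 90 % canonical (WC or G:U) pairing and ≥ 2 canonical
pair types at ≥ 5 % frequency, so a perfectly conserved pair — zero MI by
construction — is *consistent* with pairing but never *evidence* of
covariation. The MI threshold τ_MI defaults to 0.3 bits; with ~2 bits the
theoretical maximum, 0.3 rejects the sampling noise floor of a few hundred
rows by a wide margin while keeping genuinely covarying stems (empirically
≥ 1.3 bits under the generator's canonical pair distribution). This MI+APC
score is a deliberately self-contained replacement for null-simulation
covariation tests; it is not calibrated to a significance level.

No phylogenetic sequence weighting is applied; frequencies are unweighted
row counts. This is a known limitation for clade-skewed alignments.

## Column mapping and discriminating features

Two consensus models are aligned column-to-column by global dynamic
programming with affine gaps (open −1.0, extend −0.2). The match score is
the residue-frequency dot product Σₓ f_A(x)·f_B(x) plus a 0.5 bonus when
both columns agree in paired/unpaired status; ties break toward the
diagonal, making the mapping deterministic. A user-supplied anchor map
(two-column TSV) can replace the automatic mapping when a curated
correspondence exists.

Identity contrasts are graded strict at ≥ 97 %/≤ 3 % and high at
≥ 90 %/≤ 10 % — an explicit operationalisation of "close to 100 % conserved
in one motif, never or rarely the same in the other"; both thresholds are
configuration values. A column present in fewer than half the rows of either
motif is excluded from identity testing, because absence must not be
confounded with identity change; such regions are instead handled by the
element detector. Elements are maximal runs of ≥ 4 unmatched columns, scored
by gap occupancy: the fraction of rows with ≥ 6 non-gap residues in the span
(6 = the minimal hairpin, 2 bp stem + 2 nt loop). Occupancy-based detection
deliberately avoids any thermodynamic folding dependency: an element that
exists only in one motif manifests in comparative data precisely as columns
absent from the other motif.

## Context and enrichment

Gene-context tables count RNAs per downstream-domain label (semicolon-
separated multi-labels count once per label); percentages are relative to
the full row count of each motif including unlabelled RNAs, so columns sum
to less than 100 %. Enrichment questions are formalised as 2×2 tables and
tested with Fisher's exact test; the two-sided p-value follows the "sum of
tables with probability ≤ observed" convention (stated explicitly because
two-sided exact conventions differ between packages). The odds ratio is the
sample estimate ad/bc, infinite when only bc = 0 and undefined when both
products vanish; zero-margin tables return p = 1 with a degenerate flag. A
chi-square with Yates correction is available behind a flag. The gut
enrichment formulation (motif rows vs a user-supplied background of sampled
metagenomes, unknown environments excluded) is one reasonable formalisation
of an enrichment the source data only supports qualitatively; the background
counts are the user's responsibility.

## Classification

Each motif model defines a per-column log-odds score against a uniform 0.25
background with pseudocount α = 0.01: residues contribute
log₂((f_c(x)·present_c + α)/(0.25 + α)), gap columns contribute
log₂((gap_c + α)/(ḡ + α)) with ḡ the model-wide mean gap frequency (chosen
so that a model's typical gappiness is score-neutral). A sequence is aligned
to the model by a dynamic programme that maximises exactly this column
score; residues not assignable to any column pay an affine insert penalty
(−1.0/−0.2 bits) that is charged to the returned total. Making the aligner
maximise the same quantity the classifier scores is essential: with a
frequency-dot-product alignment objective, the alignment to the *wrong*
model can silently re-register around its contrast columns and collect
log-odds it never paid for, which measurably degrades discrimination.

The label is argmax of the two totals when the margin reaches δ_min
(default 2 bits — a guard against alignment noise); below that, the
discriminating features vote. Identity features are read symmetrically:
each model's own register advocates with the frequency of the residue it
placed at the contrast column (0 for a gap); element features vote by
occupancy of the span in the carrier's register. A tied or empty vote yields
"ambiguous" — the honest output for sequences near the boundary between two
homologous motifs, where no crisp delineation exists. Swapping the two
models provably mirrors labels and negates the margin.

## Assay quantification

*In-line probing.* Per lane, the modulated band is divided by the constant
band; relative intensity change is that ratio minus the no-ligand lane's
ratio. Binding curves are fitted by nonlinear least squares to
f(c) = f_max·cⁿ/(K_Dⁿ + cⁿ) with the Hill coefficient free in [0.5, 3]
(start 1): fixing n = 1 would presume single-site binding the data may not
support, while unbounded n overfits sparse series. Saturation is declared
only when the fitted K_D is ≤ max(conc)/5 **and** the fitted values at the
two highest concentrations are within 10 % of f_max; otherwise no K_D is
reported and the series is normalised to the highest tested concentration.
This operationalises the weak-binder outcome in which a modulation trend is
real but an apparent K_D cannot be claimed. Non-monotone series (a drop
exceeding 25 % of the peak magnitude) are flagged but still fitted; flat
series are flagged degenerate. Under 5 % multiplicative noise on the series,
the median relative K_D error over the tested range is below 10 %, and
beyond-range dissociation constants (≥ 10× the top concentration) are never
called saturated.

*Transcription termination.* Body labelling with [α-³²P]-ATP makes band
intensity proportional to each product's adenosine count, so intensities
are divided by the respective A counts before forming
terminated/(terminated + full-length); the correction can be disabled for
end-labelled data. An absent full-length band gives fraction 1.0.

*Acetylation.* The DTNB/CoA calibration is an ordinary least-squares line
(≥ 3 points, non-degenerate concentrations); released CoA is
(A₄₂₀ − intercept)/slope, clipped at zero with a warning. Reporter
normalisation is fluorescence/OD₆₀₀.

## Synthetic-data generator

The generator's defaults encode the study conditions the package is tested
under: a 51-column base model of two hairpins connected by a pseudoknot and
a U-rich tail; three planted identity contrasts at frequency 1.0 vs 0.0;
one 8-column hairpin element (3 bp stem + 2 nt loop) carried by motif A,
inserted in the terminator loop; gene context dominated by a transaminase
domain (0.55) in motif A and an exporter domain (0.41) in motif B with two
shared domain classes; three phyla; and gut probability 5/6 for motif A
against 1/2 for the background-like motif B (odds ratio 5). Study-scale
runs use 395 and 1,262 rows with 12 planted overlaps/duplicates. Where the
source conditions gave only qualitative statements ("over 50 %",
"striking enrichment"), a single concrete value was fixed here and is not
revisited.

Rows are sampled independently (no phylogeny); within a row, unpaired
columns draw independently from per-column distributions with per-column
presence probabilities, while stem and pseudoknot partner columns draw
jointly from a canonical pair distribution (GC 0.35, CG 0.25, AU 0.15,
UA 0.10, GU 0.10, UG 0.05) so that complementarity and a genuine
covariation signal exist; per-column marginals remain fixed and are tested
for convergence. An optional star-tree mode (per-row mutation away from a
shared ancestor) is available for classifier stress tests and is off by
default. Probing tables apply independent multiplicative lognormal noise to
modulated and constant bands around a baseline of 1000; note that band-level
noise compounds (two noisy bands per lane plus a noisy reference lane) to a
harsher effective noise on the derived series than the same σ applied to
the series directly.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: phylogenetic correlation between rows, alignment
errors and ambiguous columns, covariation-preserving evolution beyond
i.i.d. pair sampling, multi-label or missing-at-random metadata biases, and
gel artefacts beyond lognormal intensity noise.

## Problem sizes and determinism

Default test and acceptance sizes are 200 rows/motif for feature recovery
(20 replicates) and classification (200 held-out per motif), 500-2,000 rows
for convergence checks, 50 replicates for K_D recovery, and exhaustive 2×2
tables to N = 40 for the exact-test cross-check — sizes at which every
planted effect is far outside sampling error while a full run stays
comfortably fast on one CPU. All generators and pipelines are pure
functions of their seed; identical config + seed reproduces artifacts
bit-for-bit.

## Known limitations

- Unweighted frequencies; clade redundancy can inflate apparent
  conservation.
- The covariation score is a heuristic, not a calibrated significance test.
- Element detection is occupancy-based and will not see an element that is
  present but aligned into shared columns.
- The classifier is a profile log-odds model, not a full covariance model:
  it ignores base-pair complementarity in the query sequence.
- The 2×2 environment formulation compresses a metagenome-provenance
  curation problem into two counts supplied by the user.
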