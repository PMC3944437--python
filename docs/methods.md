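# Methods

## The analysis model

The pipeline treats a xenograft proteomics experiment as a two-compartment
mixture observed through tryptic peptides. Each protein is an ortholog pair
(one human, one mouse entry). A peptide whose sequence occurs in only one
species' database — after collapsing isobaric residues (I ≡ L by default,
optionally N ≡ D for deamidation ambiguity) — is *species-specific* and
attributes signal to that compartment; a peptide occurring in both digests is
*shared* and is informative for identification but not for origin.

Identification follows the two-step target-decoy scheme of ion-trap search
pipelines. Spectral level: for each LC-MS/MS run and precursor charge state
z ∈ {2, 3, 4} (charge 1 and > 4 precursors are excluded), the retained-score
threshold is the smallest observed score t with

    FDR(t) = #decoys(score ≥ t) / #targets(score ≥ t) ≤ α,   α = 0.016.

No π₀ correction is applied — the estimator is the plain decoy/target ratio.
Protein level: PSMs collapse to distinct peptides (maximum score per bare
sequence; charge states, fractions, and modification variants of one
sequence are one distinct peptide), proteins sharing a detected peptide
longer than 8 residues form groups, members with unique evidence spawn
subgroups, and a subgroup's protein score is the sum of its distinct peptide
scores (peptide scores are capped at 25, so score ≥ 20 effectively demands
two peptides or one near-perfect match). Subgroups below score 20 are
dropped; if any decoy subgroup survives, the cutoff rises just above the
best surviving decoy (protein-level FDR 0).

Membership and quantification use the same two-replicate rule: present in
both biological replicates, with ≥ 2 distinct peptides in one of them.
Abundance per compartment is the summed XIC of species-specific quantifiable
peptide precursor ions — one XIC per (peptide, modification variant, charge)
per run, summed over fractions and replicates of a tumor type; peptides
shared across subgroups of a group and precursors with poor isotope quality
are not quantifiable. With H and M the two sums, the origin call is
tumor-only / stroma-only when one side is zero, tumor- or stroma-dominant at
a fivefold imbalance (H ≥ 5·M, boundary included), similar otherwise, and
undetermined without species-specific evidence. No normalization is applied
between human and mouse ionization efficiencies — such label-free ratios are
generally reliable only to within about twofold, which is why the fivefold
threshold is deliberately conservative.

Signatures compare per-type matrisomes as case-insensitive gene-symbol sets
(the human and mouse forms of one protein are one biological entity), and
compare origins over the shared set. Shift detection defaults to the coarse
three-class scale (tumor / stroma / both) because dominance and similarity
both mean "both compartments secrete it"; the exact six-class comparison is
available via `coarse=False`. No multiple-testing correction is involved
anywhere: the comparisons are set-based presence/absence, not hypothesis
tests.

## Key parameters

| parameter | default | role |
|---|---|---|
| `max_missed_cleavages` | 2 | tryptic digestion depth |
| `min/max_peptide_length` | 6 / 50 residues | typical tryptic search window |
| `spectral_fdr` | 0.016 | decoy/target ratio per (run, charge) |
| `charges` | {2, 3, 4} | analyzable precursor charge states |
| `grouping_min_length` | 8 (strictly >) | shared-peptide grouping rule |
| `min_protein_score` | 20 (scores ≤ 25) | protein reporting floor |
| `max_protein_fdr` | 0 | no decoy subgroup may be reported |
| `fold_threshold` | 5 | origin dominance rule |

All are fields of `PipelineParams`; the same values appear as defaults in
the CLI and the run-config schema.

## The simulator

`SimulationConfig` defaults define the study conditions: 150 ortholog pairs
(uniform random sequences of 150–450 residues over the 20 standard amino
acids), two tumor types × two biological replicates, 60% of proteins common
to both types, 10% annotated non-matrisome (to exercise annotation
filtering), and a 35/25/40 origin mixture of tumor-only / stroma-only /
mixed with log-uniform human:mouse ratios up to 20-fold either way.
Mouse orthologs derive from their human partners by independent substitution
at rate 0.10 per substitutable residue — comparable to typical human–mouse
protein divergence. Substitutions never touch K/R/P, so both orthologs share
one tryptic cleavage map and every peptide exists as an aligned
conserved-or-diverged pair; substitutions also never produce I or L, so
divergence is never erased by the isobaric-residue collapse. Both are
deliberate simplifications that make ground truth exactly bookkeepable.

Abundance is log-normal (ln-scale location 16 ≈ 8.9 × 10⁶ ion-current units,
σ = 1.5). Peptide detection probability saturates in the *protein's* total
abundance, p = p_max · A / (A + k_half) with p_max = 0.9 and k_half = 2 × 10⁶:
tying detection to the protein rather than to each species' share keeps the
minor species' ions sampled at the same rate as the major's, so summed
intensity ratios are unbiased estimates of the configured mixing ratio (a
detection model tied to per-ion intensity would systematically inflate
ratios away from 1). Per-ion intensity is the species' abundance share times
log-normal noise (σ = 0.5). Scores are truncated normals on [0, 25]: targets
centred at 12/13/14 for charges 2/3/4 (sd 4), decoys at 5 (sd 2.5); decoy
rows are 10% of each table and carry peptides drawn from reversed-sequence
digests (collisions with target peptides are rejected). 2% of precursors are
flagged poor-isotope-quality; 5% of methionine-containing detections emit an
additional oxidized-variant PSM row to exercise distinct-peptide collapsing.

`GroundTruth` records, per protein, the design (type membership,
annotation), the drawn origin and ratio per type, and the *realized* peptide
bookkeeping (aligned pairs in bounds, species-specific counts under the
global digest), so expected downstream answers account for proteins whose
orthologs happen to produce no species-specific peptides.
`ground_truth_signature(config)` restates the config arithmetic alone
(expected membership Venn); it pins the expected origin-shift count to 0
only when the config makes origins deterministic.

What the simulator does not emulate: retention time, m/z, spectra,
chromatographic interference, protein-level correlation structure, real
amino-acid composition, contaminant proteins, and between-type abundance
changes for shared proteins. Passing tests therefore demonstrate the
correctness of the analysis logic under the stated statistical model, not
robustness to every artifact of real LC-MS/MS data.

## Numerical and design choices

- **FDR threshold search** scans the observed score grid ascending and
  returns the smallest qualifying score, so the retained set is the largest
  one meeting the target; +∞ (filter everything) when no grid point
  qualifies. Lowering the target can only raise the threshold.
- **Fivefold comparisons** use products (H ≥ 5·M), not ratios, so the
  tumor↔stroma mirror symmetry is exact in floating point; the boundary
  ratio 5.0 classifies as dominant.
- **Grouping determinism**: groups are numbered by descending total group
  score, subgroups by descending subgroup score, ties broken by
  lexicographic accession. A peptide short enough to escape the grouping
  rule but matching entries in several groups is counted toward exactly one
  — the highest-scoring group. Members without unique evidence join the
  highest-scoring subgroup whose spawning member's peptide set covers
  theirs, falling back to the highest-scoring subgroup when none does.
- **Mixed-species subgroups**: when one ortholog lacks unique evidence, its
  entry joins the other's subgroup, which is labelled `mixed`. Origin
  determinability is decided by the presence of species-specific
  quantifiable peptides (the "?" rule), not by the member-species label —
  a tumor-only protein grouped with its undetected mouse ortholog through
  conserved peptides is still confidently tumor-derived.
- **Grouping uses detected peptides only** (the shared-peptide graph is
  built over identified distinct peptides, not over all theoretical
  peptides), tying groups to the evidence in the data set at hand.
- **Membership counts use total peptides** (species-specific + common),
  matching how per-replicate evidence is displayed in per-protein reports.
- **Origin calls pool the two replicates** of a tumor type before the ratio
  is taken (one call per protein per type); per-replicate intensities remain
  available for QC through the retained PSM tables.
- Semi-tryptic peptides are not modelled; full tryptic specificity is
  assumed. Initiator-methionine removal is off by default.

## Known limitations

- The spectral-FDR model assumes decoy scores are exchangeable with
  false-target scores; the simulator draws them from a separate distribution
  by construction, so calibration tests verify the thresholding rule, not
  the decoy assumption itself.
- Gene-symbol keying collapses paralogs that share a symbol
  case-insensitively and requires the mouse annotation to use the human
  symbol's letters; a real UniProt-derived workflow should normalize symbols
  upstream.
- Problem sizes in tests and the acceptance script (150 ortholog pairs,
  ~7,000 PSM rows per run) were chosen as the smallest sizes at which the
  membership, Venn, and origin statistics are stable; the pipeline itself
  streams plain DataFrames and handles full-scale tables.
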