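# Methods

## Scope and model

`sumoscape` operates downstream of a search engine: its inputs are
protein-level evidence (protein-group tables with per-run peptide
counts and raw intensities, plus a per-row FDR produced upstream),
proteome FASTA files, pairwise homology-search tabular output, and
experimental target lists. It does not perform peptide-spectrum
matching, label-free quantification or its normalisation, and it does
not run BLASTP itself — hit tables are consumed as files.

## Target calling

A protein group is called a SUMO target when all four rules pass:

1. **Support** — detected (raw intensity present and non-zero) in at
   least `min_experiments` (default 3) distinct non-control experiment
   groups. Experiment groups are declared in the run design; they are
   not inferred from run identifiers.
2. **Peptides** — maximum peptide count across detecting runs at least
   `min_peptides` (default 2). The per-protein peptide requirement is
   not tied to a single run.
3. **FDR** — the row-level FDR (an input column, thresholded, never
   recomputed) at most `fdr_max` (default 0.01).
4. **Control** — absent from every control purification, or the
   *median* raw intensity over detecting non-control runs exceeds
   `control_intensity_ratio` (default 10) times the *maximum* control
   intensity. Median-versus-maximum is deliberately conservative on
   both sides; an aggregate comparison was chosen over per-run ratios
   because replicate intensities are noisy and a single low control
   observation should not rescue a contaminant.

Zero and missing intensity are both "not detected" (protein-group
tables use both conventions interchangeably). A protein detected
nowhere is excluded silently; a design without control runs is a hard
error because rule 4 is undecidable.

Differential presence between two conditions is qualitative: a protein
is condition-A-specific when detected in at least `min_present` of
`of_replicates` replicates of A (default 2 of 3) and in at most
`required_absent` (default 0) replicates of B. With more replicates
than the nominal design the presence threshold scales as
`ceil(min_present/of_replicates × n)`; the absence threshold stays
absolute, keeping "in none" strict. The two output lists are disjoint
by construction.

## Strict orthology

For each (query, subject) protein pair only the single best HSP is
evaluated: lowest e-value, ties broken by larger summed coverage, then
first encountered. No HSP chaining or coverage summation is performed —
the simplest defensible reading of a per-pair criterion. Coverage is
span coverage, `(end − start + 1)/length` per sequence, computable from
the 12-column tabular dialect; gap columns are not subtracted. The pair
is accepted iff `evalue < 1e-10` and both coverages are `> 0.80`, with
strict inequalities; `OrthologyCriteria(strict=False)` switches to
`<=`/`>=` for sensitivity analysis. Calling is one-directional
(query → subject); a reciprocal-best-hit requirement is intentionally
not part of the default criterion. A protein is "conserved" when it has
at least one accepted ortholog pair.

## Motif scanning

Patterns are position classes over the 20 standard residues with one
bounded-window construct. `5[ED]K` is ambiguous as printed; the default
reading is a lysine preceded by at least one E or D within the five
immediately N-terminal positions, because the literal reading (five
consecutive acidic residues then K) would make the motif far rarer than
its observed prevalence in target sets suggests. The literal reading
ships behind `literal_window=True`; no result in this package depends
on the choice. Ambiguity codes X/B/Z and selenocysteine U never match
any pattern position, including window gap positions — a conservative
choice that avoids spurious hits in sloppily annotated proteomes.
Scanning is position-wise, so overlapping matches are all reported;
set summaries collapse to presence/absence per sequence, which makes
them additive over partitions of a set.

## Transfer prediction

Status assignment per query protein: `experimental` if in the query
species' own evidence set (own evidence always wins over transfer);
else `predicted` if any accepted ortholog pair lands on a donor
species' experimental target, with provenance recording every
supporting (donor, target, e-value, coverages) tuple across all
donors; else `none`. A protein supported by several donors is counted
once. Donor evidence identifiers that never appear in the ortholog
map's subject side are ignored with a logged warning — published
target lists and proteome releases drift apart, and silently dropping
them is the only behaviour that keeps heterogeneous lists usable.

## Enrichment statistics

The 2×2 Pearson chi-squared with Yates' continuity correction, in
closed form with the correction clamped to zero when |ad − bc| ≤ N/2
(so a table at independence cannot yield a negative corrected
statistic). The p-value is the chi-squared survival function at df = 1
(scipy), inherently two-sided; no directional variant is offered. A
zero margin is an error. Human-readable output floors p at 2.2e-16
("< 2.2e-16", the conventional double-precision reporting floor) while
the raw value — possibly denormal or exactly 0 — stays available
machine-readably.

The conservation builder uses proteome-minus-targets as the background
so the four cells are disjoint; a whole-proteome-background variant is
exposed because published tables do not always state which was used.
For the printed counts both satisfy the same p < 2.2e-16 bound.

## Synthetic data

The generator exists so every rule is testable against planted truth
without downloads:

- **Species pair** (`simulate_species_pair`): donor proteins are
  uniform random sequences, length uniform on [80, 400] residues;
  a fraction (default 0.5) of query proteins are per-site-substituted
  copies (default divergence 0.1) of distinct donor proteins; e-values
  for planted full-length alignments come from a documented monotone
  map from percent identity (log-linear, 100% → 1e-180 down to
  35% → 1e-8), so no aligner binary is ever invoked; spurious
  background rows carry e-values ≥ 1e-5 and partial coverage and can
  never pass the strict criterion. A fifth of donor proteins are marked
  as known targets.
- **Protein groups** (`simulate_protein_groups`): three stress
  conditions × three replicate purifications of the tagged strain,
  each an independent experiment group, plus six wild-type control
  runs (untreated and heat-shock) — a scaled-down image of a
  31-plus-6-purification design. True targets (a fifth of the nominal
  proteome size) carry ≥ 2 peptides and log-uniform intensities around
  10⁷; a quarter of them leak into controls at 1/100 of their typical
  intensity (so the 10× rule still accepts them); contaminants bind
  the affinity column equally in control and sample runs and are
  always rejected by the control rule; a handful of decoys carry FDR
  above 1%. Per-run dropout (default 0) is applied to true targets but
  never erases one below the support threshold, so planted truth stays
  recoverable.
- **Motifs** (`plant_motifs`): base sequences are drawn from a
  lysine-free alphabet — every consensus pattern requires a lysine, so
  planted occurrences are provably the only matches of the planted
  motif. Exactly one realization is written per selected sequence at a
  recorded position.

All generators run off a single `numpy` Generator per simulation; a
fixed seed yields byte-identical output files. What the synthetic data
deliberately does *not* emulate: realistic residue composition, indels
and rate heterogeneity in ortholog divergence, spectrum-level MS noise,
and correlated dropout. Passing recovery tests therefore demonstrates
the correctness of the rule logic, not the field performance of the
criteria on real proteomes.

## Problem sizes and numerics

Property suites run 1000 randomized instances per operation (hit sets
≤ 50 rows, tables ≤ 20 proteins × 12 runs, sequences ≤ 30 residues,
2×2 tables with cells ≤ 500) against independently coded comparators,
plus zero-noise recovery across 20 seeds at 40–200 proteins; these
sizes exercise every branch while keeping the full suite in seconds.
Chi-squared agreement with the library oracle is asserted to 1e-9
relative tolerance. Floating-point intensities are compared with
strict inequalities exactly as the rules state; no epsilon is applied,
so boundary cases (e.g. coverage exactly 0.80) are rejected under the
strict criterion by construction.

## Known limitations

- Published species-level counts (target-list sizes, homologue counts,
  predicted totals) depend on proteome releases and deposited raw data
  and are treated as inputs, not reproduced from external downloads.
- Isoform collapsing is the caller's responsibility; one sequence per
  identifier is enforced, never inferred.
- The ortholog criterion is sequence-only; no synteny or tree-aware
  orthology.
- Site-level SUMOylation scoring (machine-learned predictors) is out
  of scope; motif presence is reported at sequence level only.
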