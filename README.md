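# sumoscape

Tools for identifying SUMOylated proteins from replicate
affinity-purification mass-spectrometry (AP-MS) experiments and for
predicting SUMOylation in any proteome by transferring experimentally
known targets across species through strict orthology.

SUMO (small ubiquitin-related modifier) is reversibly attached to
lysines of target proteins and regulates protein–protein and
protein–DNA interactions; SUMO targets turn out to be strongly
conserved across eukaryotes, which makes orthology transfer a useful
predictor. `sumoscape` is aimed at proteomics groups who have
protein-group tables from an AP-MS screen (e.g. MaxQuant output) and
want to (a) call targets with reproducible rules, (b) compare stress
conditions qualitatively, (c) scan for SUMO consensus motifs, and (d)
extrapolate target lists to other species.

## What it computes

**Target calling.** A protein group is called a SUMO target when all
four rules hold: detected in ≥ 3 independent experiments; supported by
≥ 2 peptides; identification FDR ≤ 1%; and absent from every wild-type
control purification *or* present at > 10× the control raw intensity.
Differential presence between conditions is qualitative: detected in
≥ 2 of 3 replicates of one condition and in none of the other.

**Strict orthology.** Proteins q (query species) and s (subject
species) are orthologs when the best BLASTP HSP satisfies

    E(q, s) < 10⁻¹⁰   and   cov_q > 0.80   and   cov_s > 0.80

where cov is the fraction of a sequence's residues inside the aligned
span. Prediction by transfer: a query protein not experimentally known
is *predicted* SUMOylated if it has an accepted ortholog in any donor
species' experimental target list.

**Motif scanning.** The four consensus patterns `[IV]KE`,
`[VF]K[QTEP][ED]`, `[PKE]KE[ED]` and `5[ED]K` (a lysine with an acidic
residue within the five preceding positions; a literal reading is also
available) are matched position-wise; summaries count sequences with at
least one match.

**Enrichment.** 2×2 contingency tables (conserved × target, or
motif × set) are tested with Pearson's chi-squared with Yates'
continuity correction,

    χ² = N (|ad − bc| − N/2)² / ((a+b)(c+d)(a+c)(b+d)),   df = 1,

with p-values below 2.2 × 10⁻¹⁶ reported as "< 2.2e-16".

A seeded synthetic-data module generates proteome pairs with planted
orthologs, replicate protein-group tables with planted targets and
contaminants, and proteomes with planted motifs, so the whole pipeline
is testable without any external data.

## Worked example

Simulate a 100-protein species pair, call strict orthologs from the
synthetic hit table, and predict SUMOylation in the query species from
the donor's target list:

```
$ sumoscape simulate --preset pair --seed 7 --n 100 --out demo
$ sumoscape orthologs --hits demo/hits.tsv --out demo/orthomap.tsv
50 ortholog pairs -> demo/orthomap.tsv
$ sumoscape predict --query-fasta demo/query.fasta \
    --donor donor_sp:demo/donor_targets.txt:demo/orthomap.tsv \
    --out demo/sumobase.tsv
proteome	100
experimental	0
predicted	9
total_sumoylatable	9
proteome_fraction	0.0900
```

Half of the query proteins have a planted donor ortholog (all 50 are
recovered by the strict criterion), 20 of the 100 donor proteins are
marked as known targets, and the 9 query proteins predicted are exactly
those whose planted ortholog partner is a donor target
(`demo/truth.json` holds the ground truth). `demo/sumobase.tsv` is the
exportable known/predicted table with per-protein donor provenance.

Enrichment of conservation among a target set, from counts (874
targets of which 570 conserved, against a 26 723-protein proteome with
6 010 conserved):

```
$ sumoscape enrich-conservation --targets-total 874 --targets-conserved 570 \
    --proteome-total 26723 --proteome-conserved 6010
statistic	df	p_value	p_display
943.746	1	3.03559e-207	< 2.2e-16
```

i.e. 65% of targets are conserved versus ~21% of the rest of the
proteome — far beyond chance.

## Layout

- `src/sumoscape/proteome.py` — FASTA proteome I/O and validation
- `src/sumoscape/orthology.py` — BLAST tabular parsing, strict ortholog calling
- `src/sumoscape/target_calling.py` — AP-MS replicate rules, differential presence
- `src/sumoscape/motifs.py` — consensus-motif scanner and set summaries
- `src/sumoscape/predict.py` — orthology transfer, sumobase-style export
- `src/sumoscape/stats.py` — Yates-corrected chi-squared and table builders
- `src/sumoscape/simulate.py` — seeded synthetic fixtures with ground truth
- `docs/methods.md` — models, rules, parameter defaults and limitations
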