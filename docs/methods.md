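# Methods

This note documents the models, rules and numerical choices behind `neovax`,
and what the synthetic cohort does and does not emulate.

## Epitope prioritization

A candidate is a minimal 8–11-mer mutant peptide paired with one patient HLA
class I allele. Binding is summarized as the **median IC50 (nM) across the
predictor ensemble** (default 4 algorithms); medians are insensitive to a
single outlying algorithm and well defined for any ensemble size. The filter
is a conjunction:

- median mutant IC50 < `ic50_max` (default 500 nM, the conventional binder
  threshold);
- expression: transcript TPM > 0 **and** mutant-allele RNA support
  ≥ `min_rna_alt_reads` (default 1). No numeric TPM cutoff is imposed beyond
  positivity, since expression calls are platform-dependent;
- anchor logic: if the substituted residue occupies an anchor position
  (position 2 or the C-terminus by default, overridable per allele), the
  wild-type/mutant fold change must exceed 1. An anchor mutation changes
  binding rather than the T-cell-facing surface, so an anchor mutant that
  binds no better than its wild type is likely tolerized or not novel;
- no exact match of the mutant peptide in the wild-type proteome;
- optionally a minimum sequencing-coverage filter (off by default; no
  defensible universal cutoff exists).

Ranking is a **lexicographic total order**, not a weighted score: passing
first, then known driver genes, clonal before subclonal variants (clonal ≡
VAF ≥ 0.5 × the patient's maximum VAF — a simple, monotone clonality proxy),
ascending median mutant IC50, descending fold change, id as the final
tie-break. A human tumor board performed the final arbitration in the
original workflow; a deterministic order is the minimal reproducible
substitute, and the board's judgment is explicitly out of scope. Vaccines
take the top 4–20 windows (the smallest and largest real vaccines carried 4
and 20 epitopes). When fewer than 4 windows pass, thresholds are relaxed
stepwise — IC50 cutoff ×2, then the mutant-RNA requirement dropped — and the
relaxation step is recorded in the output; the precise relaxation used per
patient in the original trial is unpublished, so this schedule is a
documented design decision.

## Construct assembly

The insert is Ub(G76V) — ubiquitin whose C-terminal glycine is replaced by
valine, a non-cleavable fusion that routes the polyprotein into proteasomal
processing — fused N-terminally to the selected windows concatenated in rank
order. No linkers are inserted by default (a configurable linker string is
available); epitope order within the manufactured inserts is unpublished, so
rank order is the documented default. Junction-spanning 8–11-mers are novel
sequence absent from the tumor; they are enumerated and flagged when
predicted to bind a patient allele, but windows are never reordered
automatically — the report is informational. Reverse translation maps each
residue to its most frequent human codon (ties to the alphabetically first),
so the emitted DNA deterministically translates back to the protein; codon
optimization beyond this, RNA structure and vector assembly are out of
scope. One stop codon is appended.

Monitoring panels tile each window with 15–16-mers overlapping by 11
residues, 16-mers placed last so the final peptide ends at the window end; a
25-mer yields exactly three peptides. Window lengths 17, 18 and 22 are not
exactly tileable at overlap 11 with 15/16-mers; there the last peptide is
shifted to end at the window end and overlaps by more than 11, preserving
full coverage.

## Response calling

ELISpot counts are SFC per 10⁶ cells, 2–3 replicate wells per condition.
Background (no-peptide wells) is mean-subtracted, floored at zero for
reported means but unfloored inside the test statistic (a pure shift leaves
the t-test invariant). **Screening** (post ≥ 50 SFC and ≥ 2× pre) is an
invented numeric stand-in for a screening step whose criteria were not
published; both knobs are exposed in config. **Confirmation** is a one-sided
Welch t-test (post > pre) at α = 0.05; Welch is the default because no
equal-variance assumption is justified for count data, and the pooled
variant is available. Per-neoantigen calls are not multiplicity-adjusted
(matching the per-neoantigen testing convention); Benjamini–Hochberg
q-values are reported alongside. Zero-variance degenerate arms resolve by
the sign of the mean difference.

ICS positivity per T-cell subset: strict = post ≥ 2× pre and post ≥ 1%
IFN-γ⁺; relaxed drops the 1% floor, so strict ⊆ relaxed always.
Deconvolution labels a response *focused* when one overlapping peptide
carries ≥ 60% of the summed adjusted OP signal, else *mixed*; mutant
specificity requires the minimal mutant peptide to outscore the wild-type
minimal peptide ≥ 2-fold.

TCR expansion uses the one-sided exact 2×2 test (hypergeometric tail with
fixed margins) on pre/post counts per CDR3β clonotype, BH-corrected within a
repertoire pair, plus a pseudocounted fold floor (default 4, pseudocount
0.5 to keep de novo clones finite). The original analysis showed frequency
plots without naming a statistic; this test is the standard defensible
surrogate and is fully config-exposed. Fold *ranking* is stable across
pseudocounts in the realistic 0.1–1.0 range for clonotypes observed in both
samples, but is not pseudocount-invariant in the mathematical limit of large
pseudocounts.

## Survival

Kaplan–Meier product-limit per arm; ties between events and censorings at
one time follow the events-first convention (censored subjects remain at
risk at that time). Confidence bands use Greenwood's variance on the
log(−log S) scale, which respects the [0, 1] range. The log-rank statistic
is the usual (O−E)²/V with hypergeometric variance, p from χ²(1df).
Vaccinated time zero is the first injection; control times enter on a clock
reset 4 months after surgery to absorb vaccine design/manufacture time.
Times are months, fractional permitted.

## The synthetic cohort

The generator emulates the study conditions: 18 patients; protein-altering
mutation counts Poisson around a median of 21.5, ~90% of non-engineered
variants expressed; 97% missense / 3% frameshift; 4–20 vaccinated epitopes
per patient; ~23% of vaccinated epitopes truly immunogenic; no-peptide
ELISpot background means uniform in 10–120 SFC/10⁶; ~2/18 recurrences; a
historical control arm with exponential hazard 0.01925/month (~50% 3-year
RFS) and uniform censoring.

The **toy binding predictor** is a per-allele 9×20 positional weight table
derived from a stable hash of the allele name (baseline weights
U(0.02, 0.2), one non-alanine consensus residue per column at weight 1.0,
alanine at 0.05 throughout); 8/10/11-mers map onto the 9 columns
anchor-aligned. The mean weight s maps to IC50 = 50000^(1−s), so the
consensus 9-mer scores ~1 nM, a random peptide needs ≥4 consensus matches to
cross 500 nM (giving a realistic minority of "natural" binders), and poly-A
is a reliable non-binder. Each ensemble algorithm applies a fixed ±0.05
perturbation. The predictor is deterministic, monotone and spans the 500 nM
decision boundary; it has no biological calibration and stands in only for
the *interface* of trained predictors.

**Planted binders**: for 30% of variants the generator embeds the chosen
allele's consensus 9-mer, with position 5 (non-anchor) replaced, into the
reference protein, and the somatic variant restores the consensus. The
mutant peptide then scores far below 500 nM while its wild-type partner
remains in the proteome — a known set of recoverable epitopes for
parameter-recovery tests. Planted variants are always missense and always
expressed.

**Assays**: truly immunogenic epitopes receive a post-vaccination ELISpot
effect log-uniform in 250–5000 SFC/10⁶ over background; everything else
shares the background law pre and post. Well counts are negative-binomial
with size 50 (~15% replicate CV at high counts, typical of ELISpot
duplicate/triplicate wells; much larger dispersion would make a 3-well
t-test insensitive to any effect size, unlike the assay being emulated).
OP signal is focused on one peptide (80%) with probability 0.6, else
balanced. ICS signal for immunogenic epitopes is ~2.5% ± 0.3 in CD8 (CD4
with probability 0.5), satisfying the strict rule with probability > 0.9.
Repertoires are Zipf(1.1) over 1000 clonotypes sampled at depth 10⁴; 1–2
mid-frequency clones are spiked ×20 post-vaccination for each immunogenic
epitope.

**What passing tests do not show**: the generator has no HLA biology, no
sequencing error, no shared clonal structure between assays, no correlation
between binding strength and immunogenicity, and its survival model is
exponential with independent censoring. Recovery and calibration results
therefore validate the *pipeline logic and statistics*, not predictive
performance on real tumors.

## Problem sizes

Defaults are chosen so a full simulate + analyze cycle runs in well under a
minute on one core: 60 proteins of 200–500 residues, ~21.5 variants × 18
patients (~80k candidate rows), 1000-clonotype repertoires at depth 10⁴.
Calibration and recovery checks use 200 simulated patients (2000
epitope-level null calls) and 40 planted-effect patients respectively.
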