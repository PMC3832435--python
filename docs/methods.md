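# Methods

## Scoring model

The statistic answers a relative question: is this gene under *stronger*
purifying selection than the average gene? It is therefore built entirely
from ranks — no metric enters on its natural scale, and no per-gene variance
or test statistic is used, so gene length cannot confound the ordering (a
longer gene gives a more precise mean, not a more extreme one).

**Scoring units.** A unit is a spliced CDS: at gene level, the longest
transcript of the gene (ties broken by lexicographically smallest transcript
ID, for determinism); at transcript level, every transcript. Units need a
spliced CDS of at least 100 nt as annotated (`min_cds_length`, default 100).
Trailing partial codons are trimmed from the 3′ end with a warning, as is a
terminal stop codon if the annotation includes one (CDS features in the
GenCODE dialect exclude it); internal stops are reported but do not abort
site building. The default chromosome whitelist is chr1–chr22 with and
without the `chr` prefix; chromosome naming across inputs is reconciled
automatically for the chr-prefix case only.

**ndCDS.** Metrics are computed only over 0-fold (non-degenerate) positions:
sites where all three single-nucleotide substitutions change the encoded
amino acid, with substitutions creating a stop counted as amino-acid-changing.
Restricting to 0-fold sites removes the synonymous-capable positions whose
evolution is largely neutral and would dilute all four signals. Degeneracy is
classified per codon position under the standard genetic code (pluggable);
codons containing ambiguous bases are excluded from the ndCDS.

**CpG stratification.** Each unit's ndCDS is split into CpG and non-CpG
sites, and every metric is ranked *within* stratum before the strata are
combined. CpG dinucleotides are roughly an order of magnitude more mutable
than other sites, so a CpG-rich gene would otherwise look polymorphic (weakly
selected) for purely mutational reasons. A site is CpG iff it is the C or
the G of a CG dinucleotide on the plus strand of the reference, regardless
of transcript strand — the mutational mechanism (deamination of methylated
C) is strand-symmetric. This is a reference-context definition; variant-level
mutational context is a defensible alternative that was not adopted because
the stratification's job here is to partition *sites*, not variants.

**The four metrics.** Per unit and stratum:

* mean conservation: arithmetic mean of the per-position track score over
  ndCDS positions with a score; coverage is reported, unscored positions are
  skipped (an unscored site is missing evidence, not evidence of zero).
* mean functional score: mean over all *possible* substitutions at ndCDS
  positions (up to 3 per site) that the table scores, pooled across
  substitutions rather than averaged per site — a site with one scored
  substitution should not weigh as much as a fully scored one.
* SNV density: 1000 × (observed SNVs at ndCDS positions) / (ndCDS sites).
  Variants count as segregating sites (occurrences after splitting
  multi-allelic records), not allele copies; a record whose REF disagrees
  with the genome is skipped with a warning.
* %RARE: the fraction of observed SNVs with MAF ≤ 0.5%. "Common" is
  strictly MAF > 0.5%, so the boundary value counts as rare. MAF per record
  comes from INFO/AF, else AC/AN, else genotypes, in that priority.

Missing slots (no sites in a stratum, no score coverage, no observed SNVs)
stay missing and are excluded from combination — never imputed.

**Rank → z.** For each ranked collection, units are ordered so rank 1 =
strongest selection, ties take average ranks, and z = Φ⁻¹((r − ½)/N) over
the N non-missing units. The half-offset grid keeps z finite at the extremes.
The inverse CDF is evaluated on the lower tail and mirrored so that
Φ⁻¹(1 − q) = −Φ⁻¹(q) holds *exactly* in floating point; without this,
analytically tied symmetric combinations (rank swaps between two inputs)
acquire sign-arbitrary 1e-16 residues and tie-breaking becomes
implementation noise rather than the average-rank rule.

**Hierarchy.** (1) per metric: within-stratum rank-z, per-unit Stouffer
across strata weighted by √(stratum site count) — more sites, more reliable
stratum mean — then re-quantile-normalise across units; (2) conservation +
functional → functional-genomic branch (unweighted Stouffer, renormalise);
(3) density + %RARE → population-genetic branch (same); (4) the two branch
z-scores → final z (same); the GIMS/TIMS quantile is the (r − ½)/N rank
quantile of the final z. Branch and stratum weights are overridable. A unit
missing an entire branch is scored from the surviving branch alone
(single-entry Stouffer) and flagged incomplete in the output.

**Enrichment.** Gene sets are summarised by median and quartiles
(linear-interpolation convention) of member quantiles and tested with the
two-sided Wilcoxon rank-sum test: exact enumeration of all C(n, n₁)
assignments when the pooled sample has ≤ 20 observations (average ranks, so
ties are handled), otherwise the normal approximation with tie and
continuity corrections. The default comparison is the set versus its
complement; `vs_all` (members kept in the reference) is available because
"all genes as reference" conventions differ — results record the mode. No
multiple-testing correction is applied across sets.

**Two-score combination.** Two per-gene quantile tables are merged by
rank-z-transforming each (lower quantile = stronger), unweighted Stouffer,
and re-expressing the combined z as a quantile over the shared genes. Genes
missing either score are dropped; the operation is symmetric in its inputs.

## Synthetic data

The simulator exists to make every stage testable without external
downloads, and to validate the central premise that the final quantile
orders genes by selection strength. Each gene carries a latent strength
s ∈ [0, 1] (an even gradient by default) that moves all four observables in
the directions selection does:

* conservation ~ Normal(0 + 4s, 1.5) per coding position — a unit-scale
  stand-in for a rejected-substitutions score;
* functional score ~ Beta(1 + 4s, 5 − 4s) per substitution (mean 1/6 → 5/6);
* SNV presence ~ Bernoulli(0.12 × (1 − 0.8s)) per ndCDS site;
* MAF ~ log-uniform (density ∝ 1/x) on a rare band (10⁻⁴, 0.005] or a
  common band (0.005, 0.5], with P(common) = 0.6 × (1 − 0.85s).

Default geometry: 200 genes on one contig, CDS 150–300 nt in 1–3 exons,
GC 0.45, about half the genes on the minus strand, and a truncated 5′-prefix
second isoform for a subset of genes (so transcript-level scoring has real
isoform structure). Defaults were chosen once to give per-gene metric
uncertainties small enough that the gradient is recoverable at 200 genes —
i.e. a clearly powered regime, with the null variant (all four effect slopes
zero) as the contrast. Randomness is one NumPy `SeedSequence` per run with
an independent child stream per gene, consumed in a documented order, so
extending a configuration never perturbs already-generated genes and outputs
are byte-identical given the seed.

What the simulator does *not* emulate: linkage, demography, realistic
GERP/PolyPhen score distributions, annotation errors, multi-chromosome
structure, or correlated metrics. Passing the recovery test therefore shows
the pipeline's plumbing and ordering behaviour are correct under the assumed
monotone structure — not that the score has any particular power on real
cohorts.

## Numerical choices and edge cases

* Quantile convention (r − ½)/N everywhere; ties always average ranks.
* Coordinates: GTF 1-based inclusive on disk, 0-based half-open internally,
  1-based in all outputs.
* The CDS-length filter applies to the spliced length *as annotated*; the
  partial-codon trim happens afterwards (an annotated 100 nt CDS is kept and
  trimmed to 99 for analysis).
* Fewer than 2 non-missing values cannot be ranked → error; a stratum with
  fewer than 2 scored units contributes no signal for that metric.
* Functional scores are clamped to [0, 1] on load with a warning; ref==alt
  entries are rejected.
* Output tables are written atomically (temp file + rename): a failed run
  leaves no partial output.

## Known limitations

* **The final quantile is not strictly monotone in a single metric.**
  Because every combination level is re-quantile-normalised, demoting an
  intermediate unit in one ranking can hand an untouched third unit a
  one-rank gain that cascades to the final ranking and occasionally
  overtakes the improved unit. Measured on random 40-unit tables, roughly
  1–3% of random single-metric perturbations shift the perturbed unit's
  final quantile up by one grid step (`scripts/acceptance.py` reports the
  rate). Monotonicity does hold exactly one level down: a unit's own
  combined per-metric z never worsens when that metric improves. A variant
  that skips intermediate renormalisation would be strictly monotone but
  would no longer match the stated level-wise quantile-normalisation
  procedure, so it was not adopted.
* Stouffer combination treats the branches as independent evidence; the
  four metrics are only approximately independent (they are derived from
  disjoint resources, but all respond to the same underlying selection).
* The CDS model trusts transcription-order concatenation of CDS features
  (no phase/frame attributes), and does not handle selenocysteine recoding
  or non-standard genetic codes beyond a pluggable codon table.
* Enrichment p-values are raw; with many sets, correct externally.
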