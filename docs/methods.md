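# Methods

## Read-level assignment model

The unit of analysis is the sequenced fragment (a read pair is one
fragment). Alignment hit tables carry, per hit, a score (higher is better),
a mismatch count and the fragment length. Two rules define the surviving
hit set per fragment:

1. **Mismatch cap.** Hits with mismatches > 10 % of the fragment length are
   discarded. The cap is applied *before* the best-hit comparison, so an
   inadmissible high-scoring hit cannot mask admissible ones.
2. **Equal-best retention.** Among admissible hits, only those whose score
   equals the per-fragment maximum are kept. Score ties are exact (scores
   are integral in the supported dialects); no epsilon is used.

Taxon assignment takes the full reference lineage for single-hit fragments
and the lowest common taxon for multi-hit fragments. The taxonomy is a
fixed six-rank hierarchy (kingdom, phylum, class, order, family, genus; no
species — deeper Greengenes payloads are discarded with a warning). Lineage
labels may be empty from some rank downward; an empty label never agrees
with anything, including another empty label, so unannotated ranks
terminate agreement rather than inflating depth. Label comparison is exact
and case-sensitive after whitespace trimming, for determinism. Fragments
whose equal-best hits span both kingdoms are unassignable (rank "none").

KO assignment mirrors this: hits without a KO annotation are set aside,
and a fragment is assigned a KO only when its remaining equal-best hits map
to exactly one; fragments resolving to zero or several KOs are ignored.
Assigned + ignored always equals surviving fragments (a tested invariant).

**Denominators.** Counts at a rank are over fragments annotated at that
rank, and percentages are normalised to that per-rank total, so every
rank's percentages sum to 100. Archaeal genera are *additionally*
re-expressed against the bacterial kingdom-level count (the convention for
reporting methanogen load), and tables carry an explicit denominator label
so the two conventions cannot be confused. The A:B ratio is
100 × archaea/bacteria on either read counts or qPCR copies/ng.

Multi-mapped fragments count once per fragment, never once per hit.
Unknown reference ids raise in strict mode (default) or are dropped and
counted in lenient mode.

## Diversity

Shannon index in natural log units; Chao1 in its classic form
S_obs + F1²/(2 F2), with the standard bias-corrected fallback
S_obs + F1(F1−1)/(2(F2+1)) when there are no doubletons (the classic form
would divide by zero; the fallback reduces to S_obs when F1 ≤ 1). Both
require raw counts — Chao1 is undefined on percentages.

## Paired comparisons

The design is matched pairs: one high and one low emitter per pair, same
breed and diet. Summaries use pairwise deletion — a flagged (invalid)
measurement in either member removes the whole pair from that feature. The
H/L ratio is the ratio of class means over the remaining pairs, reported
as undefined (never infinity) when the low mean is zero. Inference is a
two-sided paired t-test on (high − low) differences with df = pairs − 1;
zero-variance differences yield a flagged degenerate result rather than a
P value. P values are unadjusted by design — the analysis is an exploratory
screen, and family-wise correction at these feature counts would inflate
false negatives; a Benjamini–Hochberg column can be added but never alters
the unadjusted output.

## Gene selection

**Stage 1 — GLM screen.** For each KO separately, OLS of methane yield
(g CH4/kg DMI) on an intercept, a diet indicator and that KO's abundance;
the KO passes at two-sided P < 0.1 on its coefficient. Diet is included
unconditionally (it is a design variable of the experiment). Breed is
checked once, up front, by regressing methane yield on breed alone, and
enters the screen models only at P ≤ 0.1 — a logged pre-step, not a
hard-coded omission. Constant KO columns and KOs collinear with the base
design (e.g. an indicator equal to diet) are flagged and excluded.

**Stage 2 — PLS/VIP.** All passers plus two complementary diet indicator
columns enter a PLS1 model with predictors and response centred and scaled
to unit SD (ddof = 1). The complementary diet columns are exact negatives
after centring, which yields the symmetric ± standardized estimates
conventional for a two-level effect; NIPALS handles the collinearity
without inversion. Predictors with VIP < 0.8 are removed and the model is
refit once on the survivors. There is exactly one pruning pass: the refit's
VIPs are reported but not acted on, even if a few effects drift below 0.8
again. The retained set is the KO survivors of the first prune.

**PLS numerical details.** NIPALS with X- and y-deflation; unit-norm weight
vectors; successive score vectors orthogonal to < 1e−8 (tested). The factor
count defaults to the minimiser of the leave-one-out PRESS (ties broken
toward fewer factors, capped at rank(X) and at `max_factors`, default 10);
it can be fixed explicitly and is always recorded. Requesting more factors
than rank(X) or including a zero-variance column raises, naming the column.
Coefficients are reported on the standardized scale, with back-transformed
original-unit coefficients and intercept provided secondarily. With A =
rank(X) factors the fit reproduces OLS predictions; an independent PLS
implementation is used in the test suite to confirm coefficient agreement
to 1e−6. VIP uses SSY_a = q_a²·(t_a·t_a) as factor-wise explained response
variance; mean VIP² = 1 is an algebraic identity and is asserted on every
fitted model.

## Novelty screen

Candidates per KO group are predicted proteins whose ordered Pfam-accession
sequence equals the group profile's (an unordered-multiset comparison is
available) and whose length is ≥ the group's shortest member (inclusive).
Each candidate's best database match is chosen by highest percent identity,
ties by highest percent positives. A candidate is "identical at θ" when
best-match identity ≥ θ and "conserved at θ" when positives ≥ θ, for
θ ∈ {100, 90}. Full query coverage (alignment length ≥ query length) is
required by default for both bands — an exact match claimed from a partial
alignment is meaningless — with the 90 % band's rule independently
switchable, since reasonable analyses differ there.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions: a panel of matched pairs
cycling over two breeds × two diets (defaults: 4 pairs); methane yields
centred at 13.43/25.26 g/kg DMI for low/high emitters with a ±5 g/kg diet
offset (Med above Conc, matching the observed spread) and Gaussian noise
(SD 2.0); a 14-genus rumen-like community (Firmicutes ≈ 44 %,
Bacteroidetes ≈ 40 %, Proteobacteria ≈ 11 %, archaea ≈ 1.5 % in low
emitters) with planted high/low multipliers — archaea ×2.5,
Proteobacteria ×0.24, *Megasphaera* ×0.08; and KO abundances in which eight
methanogenesis-pathway orthologues (mcrA/B, fwdA/B, hdrA, mvhA, V-type
ATPase A/B) carry per-KO multipliers drawn from N(2.82, 0.27) against a
default background of 100 null KOs.

Abundance noise is multiplicative mean-one lognormal (σ = 0.3): abundances
are positive and effects are reported as fold ratios, so multiplicative
noise leaves planted folds unbiased. Methane couples to *total archaeal
abundance* (coefficient 100 g CH4/kg DMI per unit relative abundance), not
to each KO independently — archaeal biomass yield is proportional to
methane formed, which is the mechanistic rationale for expecting gene
abundance to track emissions. Methanogenesis KOs therefore correlate with
methane through the emitter class, as in the real system.

Hit-table simulation draws each fragment's genus from the sample
composition and emits one hit, or several equal-score hits forced to share
a lowest common taxon at a chosen rank (the generated taxonomy carries
multiple references per genus and decoy sibling genera per family to make
this possible at every rank). A controllable fraction of fragments exceeds
the 10 % mismatch cap and must vanish downstream. An optional Dirichlet
layer adds compositional sampling noise.

What passing tests on these data do **not** show: real hit tables have
correlated, non-multinomial coverage, chimeric and contaminant reads,
reference-database bias and incomplete annotation; real KO matrices are
compositional and heavy-tailed far beyond a lognormal; and the real
community has hundreds of genera, not 14. Recovery of planted effects here
validates the machinery, not field performance.

## Problem sizes and determinism

Desk-scale defaults are used throughout: 10³–10⁵ fragments per sample for
read-level checks, 20-pair panels with 108 KO columns for selection
recovery (50 seeded runs), 100 seeded panels for fold-recovery averages,
1000 null KOs / 2000 null replicates for calibration. Every stochastic
routine takes an explicit seed and is bit-reproducible given it; the
pipeline report records seed, thresholds and a config hash, and rerunning
the same configuration reproduces byte-identical tables.

## Known limitations

- Six ranks only; species-level information is discarded by design.
- No alignment, FASTQ or SAM/BAM handling: the pipeline starts at tabular
  hit files (the dialect is documented in the readers).
- The qPCR-style and read-count A:B ratios share one code path; units are
  the caller's responsibility.
- Published mid-table anchor values that depend on unreleased per-sample
  matrices (full KO tables, genus count tables) cannot be recomputed here;
  the worked examples cover the per-pair summary tables, and everything
  else is validated by property suites and synthetic recovery.
- The GLM screen assumes homoscedastic Gaussian errors; with 8–40 animals,
  P values are approximate for heavy-tailed abundance data.
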