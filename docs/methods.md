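# Methods

## Signature scoring and classification

The unit of evidence is a homology hit of one of the 66 sporulation-predictive
proteins against a genome. Detection is binary: a gene is present iff at least
one hit satisfies e-value ≤ 1e−5 **and** percent identity ≥ 30 (both
inclusive). Hit multiplicity is deliberately discarded — the signature score is
defined on presence only — and duplicated rows from concatenated search
outputs collapse to a single presence. The score is 100 × (genes present)/66,
so it is always a multiple of 100/66 in [0, 100].

Classification is family-structured. For a family with at least `min_n = 5`
genomes we compute the exhaustive two-group 1-D partition of its scores that
minimizes the summed within-group sum of squares (all n−1 sorted cut points
are tried; ties resolve to the smaller low group). The family is **bimodal**
iff the two group means differ by at least `min_gap = 20` score points and
each group has ≥ 2 members; the cluster boundary is the midpoint between the
adjacent extreme members across the split. Families that fail these checks —
including all families below `min_n` — are called **high** or **low** by
their *spo0A* majority, with ties going to low. These two thresholds are this
package's operationalization of a clustering that is visually obvious on
well-separated score modes but was never specified as an algorithm; both are
exposed in `PipelineConfig`.

Within a bimodal family a genome joins the high cluster iff its score is
strictly above the boundary; a score exactly on the boundary goes to the low
cluster (conservative toward FSF). A genome is SF iff its cluster is high.
*spo0A* never overrides cluster membership: low-cluster genomes retaining
*spo0A* stay FSF and are reported as discordant. Concordance = fraction of
genomes that are (high ∧ spo0A) or (low ∧ ¬spo0A), displayed with half-up
rounding to one decimal.

## Stage-wise retention

Each signature gene maps to a developmental stage (0, I–V, germination, or
unknown; bin sizes 3, 2, 7, 12, 12, 9, 2, 19). Per stage and group we pool
gene × genome presence events into a single 2 × 2 table (presences/absences ×
SF/FSF) and use a two-sided Fisher's exact test, with Benjamini–Hochberg
q-values across the seven tested stages (the unknown bin is profiled but not
tested). Pooling treats cells as exchangeable, which overstates the effective
sample size when genes within a stage co-occur — a pseudo-replication caveat
that applies to the per-stage q-values, not to the retention percentages
themselves.

## Enrichment, paralogs, CAZymes, substrates

Domain enrichment works on genome-level presence of each protein domain:
one-sided Fisher's exact per direction (SF-enriched, FSF-enriched), Hochberg
(FWER) adjustment across all domains within a direction, and a flag at
adjusted p < α = 0.05 (α is conventional, configurable). Functional-class
comparison builds, per class, the 2 × 2 table of class members vs non-members
across the two enriched sets; it uses a two-sided Fisher test (sidedness was
an open choice; two-sided is the conservative default and matches the 4-vs-4
worked example p = 1/35).

Paralogy is the percentage of excess domain copies: Σ max(0, c−1) over
domains divided by Σ c, where c is the copy count. The alternative reading —
the fraction of distinct domains that are multi-copy — is available as
`paralog_mode="multicopy_domains"`.

CAZyme hits are kept iff alignment > 80 aa and (E < 1e−5, or E < 1e−3 with
HMM coverage > 0.30); hits lacking coverage fail the relaxed clause with a
warning. The family label is the leading catalog prefix of the HMM name
(`GH13_31.hmm` → GH13); families AA\* (auxiliary activities), GT\*
(glycosyltransferases) and CE10 are excluded after filtering. Per-genome
totals and distinct-family counts are compared with two-sided Welch's t.
Substrate growth calls are pooled per isolate by majority vote (ties → not
grown, flagged as an open choice) and compared per substrate with two-sided
Fisher.

## Metagenomic presence, abundance, permutations, beta-diversity

Coverage summaries are computed from dense per-position depth vectors:
breadth = fraction of positions with depth ≥ 1; mean depth and the
coefficient of variation (population sd / mean, ddof = 0) are taken over
covered positions only. "Depth variation" is not pinned down by its source,
so the CV is this package's declared stand-in: the simplest scale-free
statistic consistent with the idea.

Presence calibration bins breadth into width-0.01 bins over [0.60, 1.00];
each bin's cap is the empirical 99th percentile of its members' CV
(numpy linear-interpolation percentile), and empty bins inherit the nearest
populated bin (ties to the lower). A species is present in a sample iff
breadth ≥ 0.60 and CV ≤ the bin cap. Abundance is
RPKM = RS/(GL × TRC/10⁶) with GL in kilobases. Species-level abundance is
the **median** RPKM over the samples where the species is present (robust to
the heavy right tail; the summary statistic was an open choice), restricted
to species present in strictly more than 10 samples.

The equal-n permutation analysis repeatedly draws n_FSF spore-former species
without replacement and compares the subsample's **median** prevalence to
the FSF median (strictly greater counts); the returned fraction is exact in
expectation and is checked against exhaustive subset enumeration on small
inputs. All permutation draws come from one `numpy` Generator seeded from
the config, so a fixed seed gives bit-identical fractions.

Beta-diversity contributions CLR-transform each sample after replacing zeros
with half its smallest nonzero value (standard multiplicative replacement;
configurable). The squared Aitchison distance between two samples decomposes
exactly as a sum over species of squared CLR differences; a species'
contribution is its mean share over all sample pairs with nonzero distance,
so shares are non-negative and sum to 1.

## Statistics

Fisher's exact test is computed by direct integer enumeration of the
hypergeometric support, which makes it exact at double precision for every
table the pipeline produces and makes two-sided tie handling unambiguous
(a table is included iff its integer weight ≤ the observed weight); it is
cross-checked against `scipy.stats.fisher_exact` in the tests. Hochberg and
Benjamini–Hochberg adjustments go through
`statsmodels.stats.multitest.multipletests`. The Wilcoxon rank-sum /
Mann–Whitney test (the two names denote the same test here) uses the exact
null when both groups have ≤ 20 observations and no ties, otherwise the
tie-corrected normal approximation; the two paths agree within 0.01 at
n = 20/20. Welch's t with constant groups (zero variance on both sides) is
defined as t = 0, p = 1 when means agree and p = 0 otherwise.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of a real genome collection, not
its content. Defaults: seven families (five bimodal, one high, one low),
40 genomes each; SF scores ~ N(80, 8²) truncated to [50, 100], FSF ~
N(20, 6²) truncated to [0, 35] (as presence counts), a score/spo0A
concordance rate of 0.989, germination genes fully lost in FSF; SF genome
sizes ~ N(3.5, 0.5²) Mbp with FSF means 36% smaller and gene counts tightly
tracking size; CAZyme totals around 112 (SF) vs 57.5 (FSF) with ~37 vs ~24
families; 200 domains with 30 planted enriched per group at presence 0.9 vs
0.1; metagenome panels of 200 samples with SF prevalence ~ Beta(7, 3) vs FSF
~ Beta(3, 7) and FSF per-base depth rates 2× SF (lognormal around 8 vs 4,
so expected breadth 1 − e^(−λ) ≫ 0.60 when present; absent species carry
noise with breadth < 0.3). Reads are tied to depth through a fixed 100-bp
read length; TRC multiplies each sample's mapped reads by 20.

Simulated genomes for metagenome coverage are 1–2 kb — three orders of
magnitude below real bacterial genomes — which keeps whole runs in seconds
while leaving every statistic scale-free (breadth, CV, RPKM ratios and all
rank tests are unchanged by genome length up to sampling noise). Passing
tests therefore demonstrate that the *procedures* are correct and recover
planted effects at realistic effect sizes; they say nothing about homology
search quality, real coverage biases (GC, mappability, strain mixtures), or
the taxonomy of any real collection.

## Known limitations

- The bimodality rule is a deterministic stand-in for an unspecified
  clustering; families with genuinely trimodal scores would be forced into
  two clusters.
- Stage-wise Fisher tests pool gene × genome events (see above).
- The depth-variation statistic and its binning scheme are declared choices,
  not reconstructions of the original tooling.
- `hmm_tab` input expects `genome|protein` query identifiers; other naming
  schemes need pre-processing.
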