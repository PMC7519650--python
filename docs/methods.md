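# Methods

This note documents the models implemented in `chemomics`, the defaults and
why they were chosen, the numerical decisions, and what a passing test suite
does and does not establish.

## Mutational signatures

A sample's SNVs are binned into the 96 trinucleotide channels (six
pyrimidine-strand substitution classes x 4 x 4 flanking bases; purine-ref
substitutions are reverse-complemented onto the pyrimidine strand). The
channel order is fixed package-wide and documented in
`chemomics/channels.py` and in the header of the shipped signature TSV.

Exposures are obtained by non-negative least squares: minimize
`||M w - p||_2` over `w >= 0`, where `M` is the 96 x 4 column-stochastic
signature matrix and `p` the observed channel counts. NNLS is a convex
problem with a unique-objective global optimum; the test suite checks the
objective against a fine-grid simplex-by-scale search. Two gates follow the
refitting conventions for this tumor type: samples with <= 100 SNVs are not
eligible, and fits whose reconstruction has cosine similarity <= 0.9 to the
observed profile are not assessable; either failure leaves the sample
unassigned. Both thresholds are strict inequalities on purpose ("more than
100", "above 0.9").

**Signature matrix.** The shipped matrix
(`data/sbs_signatures_synthetic.tsv`) is a *stylized synthetic stand-in*,
constructed deterministically in
`signatures.build_synthetic_signature_matrix`: SBS1 peaks at NpCpG C>T,
SBS2 at TpCpN C>T, SBS13 at TpCpN C>G, and SBS5 is broad and nearly flat.
It reproduces the qualitative channel structure of the four signatures but
is **not** a COSMIC release; users with access to the COSMIC v3 TSV can pass
it to `load_signature_matrix(path)` unchanged. Every test in this package is
a recovery test against structure planted with the shipped matrix, so no
result here depends on the literal COSMIC probabilities.

**Per-signature mutation counts** use proportional attribution,
`total_snvs * w_s / sum(w)` (SBS2 and SBS13 summed for the APOBEC group).
A per-channel posterior attribution mode (`method="posterior"`) exists as a
sensitivity check; proportional is the default because the downstream
analyses are phrased in terms of relative signature contributions.

## Burden-controlled permutation test

Mutation burden confounds any per-sample count outcome: heavily mutated
samples are more likely to carry a mutation in *any* gene and also have
larger context counts. The test controls this by randomizing the binary
genes x samples matrix with the Curveball algorithm — repeated "trades" of
discordant columns between random row pairs — which preserves every row and
column sum exactly. Defaults: `n_trades = 5 * (number of 1-entries)` per
permutation (a mixing heuristic, configurable), `n_perm = 100,000` in
production (overridable; tests use hundreds to thousands), and a gene
frequency filter of strictly more than 5% mutated samples, applied after
the HIGH/MODERATE impact filter.

The observed statistic per gene is the two-sided Wilcoxon rank-sum p of
mutant vs wild-type counts. Inside the permutation loop both `p_obs` and
`p_perm` use the same midrank normal approximation with tie correction and
0.5 continuity correction, vectorized as `W = matrix @ ranks` (the ranks and
tie term never change under permutation, and row sums are margin-preserved,
so the whole per-permutation computation is a matrix product). The
standalone `gene_observed_stat` offers exact enumeration for tie-free
groups of <= 25; exactness is deliberately *not* used inside the loop, where
what matters is that `p_obs` and `p_perm` live on an identical scale.

`p_final` defaults to the add-one smoothed estimator
`(1 + #{p_perm <= p_obs}) / (n_perm + 1)`, which is never 0; the literal
"fraction of p_perm strictly below p_obs" is available (`mode="literal"`)
but is anti-conservative under ties (it returns 0 when no permutation beats
the observation). The null is per-gene — each gene's `p_obs` is compared to
that gene's own permuted p-values; a pooled mode (all genes' permuted
p-values) is available behind `null_scope="pooled"` since the construction
admits both readings.

## Allelic imbalance

Only segmented BAF is used (absolute copy-number/purity estimation is
deliberately out of scope). The imbalance-relevant quantity is the mirrored
deviation `|BAF - 0.5|`, in [0, 0.5]; the "maximum BAF segmented value" in
the thresholding rule is interpreted as the maximum *deviation* (a raw-BAF
maximum would saturate near 1 for any LOH segment). "Removing outliers" is
operationalized as dropping segments supported by fewer than `min_snps`
SNPs (default 10) before taking the maximum, because short noisy segments
dominate maxima. Threshold = max/3; segments with deviation >= threshold
are flagged (strictly > 0 when the threshold degenerates to 0, so a fully
balanced genome reports 0%). The percent-AI denominator is covered
(segmented) autosomal length; X/Y are excluded by default.

## Trunk/branch comparison

For each patient, all samples' calls are merged; each union mutation is
re-examined in every sample's read counts. Presence = called there, or
rescued with >= `min_alt_reads` (default 2) alternate reads. The minimum
depth needed to detect a mutation at its lowest observed VAF with
probability `detect_prob` (default 0.95) is the smallest `d` with
`(1 - VAF)^d <= 1 - detect_prob`; positions under-covered in any sample are
dropped rather than scored, so shallow sequencing cannot masquerade as a
private mutation. Survivors present in all samples are trunk, the rest
branch; with two or three samples per patient, the presence partition fully
determines the phylogeny, so no tree search is performed. Both `detect_prob`
and `min_alt_reads` are package choices (the procedure's detection standard
is not otherwise pinned down) and are configurable.

## Immune and methylation scoring

RNA cell-type scores are unweighted means of the set genes' normalized
log-expression; the immune score is their sum. Median dichotomization is
literal "strictly above the median": values tied with the median go to the
low group, everywhere in the package (RNA IS, protein IS, PD-1/PD-L1,
feature dichotomization). Gene symbols match case-insensitively; a gene set
that resolves below 50% of its genes is an error rather than a silent
shrink.

Protein immune scores sum the six immune cell fractions (T-helper, CTL,
Treg, B-cell, M1, M2) per region; the median split is computed within each
region across the cohort. Subtypes: intratumoral-low/peritumoral-low =
desert, low/high = excluded, intratumoral-high = infiltrated regardless of
the peritumoral label.

CpG selection (hyper direction): autosomal probes with mean beta < 0.2 in
both normal references and beta > 0.3 in >= 4 tumors; eligible probes are
ranked by the number of methylated tumors and then variance, top n = 5000.
The 0.2/0.3 cutoffs are common beta-value conventions (the source procedure
does not state its cutoffs) and are configurable; the hypo direction mirrors
the predicates in `1 - beta`. Consensus clustering follows Monti: resample
80% of samples (default 1000 resamples), Ward/Euclidean hierarchical
clustering, co-clustering frequencies among co-sampled pairs; final labels
from average-linkage clustering of `1 - consensus`. The number of clusters
is chosen to minimize the proportion of ambiguous consensus entries (PAC,
entries strictly between 0.1 and 0.9) — a robust operationalization of the
"biggest consensus-CDF gap" idea — unless `k` is fixed.

## Response labels and integration

NAC response = pathological stage pT0/pTa/CIS with N0 after cystectomy.
First-line response = RECIST CR or PR; a radiologic CR with an intact
bladder and available post-treatment pathology must show pT0/pTa to remain
a response (the definitive-CR rule; a downgraded CR is scored
non-response — radiology said no lesion but pathology found invasive tumor,
and inventing a PR would overstate certainty). Records missing a decisive
field are unevaluable (`None`), never silently non-responders. Patients
evaluated in both contexts use the first-line evaluation.

HGI/LGI: high genomic instability iff any of SBS5 count, indel count, or
percent AI is strictly above the cohort median (medians over complete
cases; configurable) or BRCA2 is mutated. Note that an OR over three
above-median criteria labels ~7/8 of a cohort HGI when the features are
independent; that is a property of the rule, not a bug.

Association sweep: per feature (booleans as-is, continuous median-split),
2x2 counts against response, cross-product odds ratio with a 0.5 continuity
correction on zero cells (flagged), normal-approximation 95% CI on the log
OR, two-sided Fisher exact p (sum of hypergeometric probabilities at most
as likely as the observed table — the convention that reproduces the
published TCGA anchor tables to two decimals). Continuous features also get
a univariable logistic p. Raw p-values are reported; Bonferroni is left to
the caller per analysis. `stratify.logistic_effects` fits the joint
(multivariable) logistic model and is the right tool for recovering
*conditional* effects — the marginal 2x2 OR is non-collapsible and will
understate a planted conditional log-odds when other effects are present.

## The synthetic generator

`simulate.simulate_cohort` draws, per sample: a Dirichlet signature mixture
(concentrations (0.8, 1.2, 2.0, 1.2) over SBS1/SBS2/SBS5/SBS13, favouring
the SBS5- and APOBEC-dominated profiles typical of this tumor type); SNV and
indel burdens from gamma-Poisson (negative-binomial) models with means
600/60 and shapes 1.5/1.2 — chosen so the simulated burden median (~520
SNVs) and two-orders-of-magnitude range resemble a chemotherapy-treated
exome cohort; a BRCA2-mutant flag (rate 0.08) that doubles the SBS5 count
(multiplier 2.0); a true AI fraction from Beta(2, 4) (mean ~33% of the
genome); a consensus expression subtype from (LumP 0.35, LumU 0.15,
Stroma-rich 0.15, Ba/Sq 0.35); an immune-hot latent (rate 0.5) that shifts
the immune/APM gene sets and the imaging cell fractions; and a response
from the logistic model `logit p = 0 + 1.0*HGI - 1.0*BaSq + 0.5*immune`,
which yields an overall response rate near 0.57 and stratum rates ordered
HGI/non-Ba/Sq highest to LGI/Ba/Sq lowest. Clinical records are emitted so
that `stratify.response_label` recovers the drawn response exactly.
Variant contexts are placed on a bundled seeded random reference (default
200 kb; ~1 Mb is equally supported) so trinucleotide extraction runs end to
end against a real FASTA-shaped object.

What the generator does **not** emulate: real genome coordinates, germline
variation, driver-gene positive selection, sequencing error beyond binomial
read sampling, FFPE artifacts, batch effects, or correlated gene-gene
mutation structure. A green recovery test therefore establishes that the
procedures compute what they claim on data with the stated statistical
structure — not that the biological findings of any real cohort would be
reproduced.

All randomness flows from `numpy.random.default_rng(seed)`; identical
configs and seeds serialize byte-identically. Ground truth is stored beside
the data (`truth.json`) and read only through its declared keys.

## Known limitations

- The exact-p option of the rank-sum statistic does not handle ties
  (midrank approximation is used instead); this matters only for tiny
  tie-heavy groups outside the permutation loop.
- Curveball mixing (`5 x ones` trades) is a heuristic; uniformity is
  verified empirically on small matrices, not proven for every shape.
- `min_required_depth` assumes binomial sampling of reads with no
  base-quality model; quality filtering is assumed upstream.
- The DDR damaging rule defaults to requiring *both* predictors to flag a
  missense variant (`rule="and"`); the alternative either-predictor reading
  is available (`rule="or"`) because the defining sentence is ambiguous.
- The consensus-clustering k selection (PAC) can differ from eyeballing
  consensus CDFs on weakly structured data; fix `k` when the cluster number
  is known.
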