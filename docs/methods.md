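# Methods

## The screening model

A sample's autosomal read counts are treated as a composition: with
`n_i` autosomal reads, the count on autosome `c` is binomial with a
chromosome- and protocol-specific success probability, and that
probability is itself beta-distributed across libraries,

    p_c ~ Beta(alpha_c, beta_c),      k_ic | n_i, p_c ~ Binomial(n_i, p_c),

so marginally `k_ic` is beta-binomial. The beta layer is what makes the
method workable on heterogeneous collections: library chemistry,
sequencing run and DNA preservation all shift chromosome proportions by
more than binomial noise, and a binomial-only null would declare
overdispersed euploids significant. Models are fitted **independently
per library protocol** because protocol is the dominant, known source of
that shift. Proportions are taken relative to the **autosomal total**
(not the 24-chromosome total), so the 22 means sum to one and the
trisomy renormalisation below is self-consistent; sex inference uses
fractions of the full total instead.

Assumptions worth stating: full (non-mosaic) autosomal trisomies only;
read counts are exchangeable within a protocol; no GC-bias or
mappability correction beyond what protocol stratification absorbs; the
per-chromosome beta-binomials are treated as independent in the
likelihood (the compositional constraint induces small negative
correlations, which matter little because each chromosome is a small
fraction of the total).

## Null-model estimation

Shape parameters are estimated by maximising the beta log-likelihood of
the observed proportions of panel samples with at least `min_fit_reads =
10,000` autosomal reads, one autosome at a time. The optimiser is BFGS
in `(log alpha, log beta)` with the analytic digamma gradient, started
from method-of-moments values. Convergence is declared when the gradient
norm falls below `1e-6` relative to the log-likelihood magnitude (an
absolute `1e-8` norm is below float64 resolution once the log-likelihood
is of order 10^3). Degenerate inputs — fewer than two qualifying
samples, proportions outside (0, 1), or zero variance — raise errors
rather than returning garbage.

Fitting a beta to *proportions* (rather than the joint beta-binomial to
counts) is exact only when binomial noise is negligible next to
between-library scatter. At the 10,000-read floor the binomial term is
not always negligible, so the fitted concentration `alpha+beta`
*underestimates* the generating concentration (by roughly the ratio of
total to between-library variance). The consequence is a conservative
null — slightly inflated model variance, Z-scores mildly shrunk for deep
samples — which costs a little power but never specificity. Samples
later called as carriers are not excluded from panel fits by default;
one carrier among hundreds of panel samples perturbs the fit negligibly.

## Scoring and calls

* `Z_ic = (k_ic − mean) / sqrt(var)` with the exact beta-binomial
  moments at the sample's own depth.
* Fold-increase `F_ic = p̂_ic / m_c`, centred on the protocol mean by
  default; a median-of-negatives centring is available for parity with
  how negative groups are sometimes summarised.
* The posterior compares 23 hypotheses jointly (euploid + 22 trisomies)
  under a uniform prior. A third copy of autosome `c` adds `0.5·m_c` of
  mappable content, so the trisomy hypothesis shifts the target mean to
  `1.5·m_c/(1+0.5·m_c)`, deflates every other mean by `1/(1+0.5·m_c)`,
  and preserves each chromosome's concentration. All likelihood work is
  in log space with log-sum-exp normalisation; posteriors sum to one to
  1e-12 by construction. A 23-way joint comparison was chosen over 22
  pairwise tests because it yields a single coherent probability vector;
  for clear positives the two normalise identically.

Call logic, in order: `insufficient-reads` below 1000 autosomal reads;
`ambiguous` when more than one autosome is significantly overrepresented
(one-sided Bonferroni at 0.05/22 — one-sided because a trisomy only ever
*adds* reads, and a two-sided rule would flag the deflation of other
chromosomes in strong positives); otherwise `trisomy-c` when that
posterior reaches `call_threshold = 0.99` **and** the fold lies in
`[1.3, 1.7]`; otherwise `euploid`. The two gates are deliberately
conservative reporting filters and are configurable.

Because the Bonferroni rule compares Z-scores against a *normal*
quantile while the null is a right-skewed beta-binomial, the realised
euploid family-wise rate runs slightly above nominal (≈ 0.06 at nominal
0.05 in the calibration simulations). This is a property of the
screening filter, not of the posterior, and is harmless for its purpose
of catching multi-chromosome artefacts.

### Detection power

Detection is information-limited at the screening floor: at 1000 reads a
small autosome receives ~17 reads in expectation and a carrier ~25, so
the expected log-Bayes-factor is only ~1.7 nats — far short of the ~4.6
needed for a 0.99 posterior — and the default gates detect essentially
nothing at that depth. The `power_curve` utility quantifies this:
detection is negligible at 10^3 reads, rises steeply through a few
thousand reads, and saturates at 1 well before 10^5. The 1000-read floor
should therefore be read as "samples this shallow are *screenable*
without breaking calibration", not as the depth at which single carriers
are reliably confirmed; confident single-sample confirmation wants
~10^4+ reads, where the posterior saturates to 1 within machine
precision.

## Genetic sex

Sex is assigned from `p_y`, the fraction of all mapped reads on Y:
1-dimensional 2-means clustering splits the cohort, the low-`p_y`
cluster (background mismapping only, no Y) is called XX and the other
XY. Samples under 1000 total reads, or within two binomial standard
deviations of the midpoint between cluster means, stay `unassigned`.
The buffer exists purely to protect shallow samples from coin-flip
assignments; accuracy on simulated cohorts is 100% at 50,000 reads.

## Prevalence statistics

Observed case counts are compared with modern per-birth rates (Down
1:705, Edwards 1:3226, Patau 1:7143; under-20 maternal rate for Down
1:1282) by the exact binomial test. The two-sided p-value uses the
minimum-likelihood convention — the sum of probabilities of all outcomes
no more likely than the observed one — matching the convention of the
standard statistical software this kind of analysis is reported with;
the exact value is always reported rather than an approximation. Rate
strings `1:N` round half-up. An age-stratified comparison table and
log-scale plot are produced from a user-supplied map of maternal
age-band rates.

## The cohort simulator

Each sample draws a 24-chromosome proportion vector from
`Dirichlet(s · w)` and counts multinomially at its depth. The Dirichlet-
multinomial was chosen over independent per-chromosome beta-binomials
because counts must sum to the depth, and its per-chromosome marginals
(and sub-compositions) are *exactly* beta-binomial — the simulator's
truth is the screen's null, so parameter-recovery tests are meaningful.

Defaults, and why:

* **Base weights** proportional to GRCh37 chromosome lengths (chr21 ≈
  1.7% of the autosomal total). XY samples carry one X at half weight
  and one Y scaled by a 0.3 mappability factor (the Y is repeat-rich),
  giving `p_y ≈ 3×10⁻³`; XX samples get a 5×10⁻⁴ Y background from
  mismapping.
* **Depth law** log-uniform over 10^3–10^7 reads, spanning shotgun
  survey sequencing.
* **Two protocols** whose weight profiles differ by a small power tilt,
  so protocol stratification has something real to absorb.
* **Concentration `s = 10^5` per protocol.** This sets the
  between-library scatter of a small autosome's proportion to ~2.5% of
  its mean, which is the regime the method's reported behaviour implies:
  carrier fold-increases spread over roughly ±0.05 around 1.49, and the
  correct-hypothesis posterior saturates to 1 within machine precision
  at survey depth. A markedly larger dispersion (e.g. `s = 10^4`) would
  spread folds over ±0.15 and cap log-Bayes-factors near 20 nats at any
  depth, contradicting both behaviours.
* **Carriers** multiply the target autosome's weight by 1.5 *before*
  renormalisation, which is precisely the three-copy model the screen
  inverts; the realised fold concentrates on `1.5/(1+0.5·m_c) ≈ 1.49`.

What the simulator does **not** emulate: GC- and mappability-driven
proportion biases (real chr21 mapping proportions run below its length
share), post-mortem damage and contamination, mosaicism, partial
trisomies, and sex-chromosome aneuploidies. Passing tests therefore
demonstrate correctness of the statistical machinery under its own
generative assumptions, not robustness to every artefact of real ancient
DNA; on real data the protocol stratification carries the burden the
simulator's clean protocols do not exercise.

## Problem sizes used in the test suite

Calibration and specificity checks use 5,000–10,000 simulated samples;
panel fits use 500–600 samples; power and low-depth checks use 200
replicates per condition; the acceptance computation uses 5,000 euploids
plus 500 carriers at 10^6 reads. These sizes put Monte-Carlo error
comfortably below every asserted tolerance while keeping any single
check to seconds.

## Known limitations

* The 0.99-posterior and fold-window gates make sub-~3000-read positives
  undetectable by design; lower the gates (at a specificity cost) if
  screening very shallow material is the goal.
* Fitting a beta to proportions biases the concentration downward when
  panel depths are near the 10,000-read floor (conservative, see above).
* One protocol must contribute at least two panel samples at depth;
  singleton protocols cannot be screened.
* Chromosome-name handling is GRCh37-style ("chr21"/"21"); other
  assemblies work if their nuclear chromosome names normalise the same
  way, but the simulator's default weights are GRCh37 lengths.
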