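# Methods

## Mixture model and estimation

A metagenome's domain profile **y** (relative frequencies over D domain
families) is modelled as a convex combination of K fixed reference
signatures **x**ᵢ, the columns of a column-stochastic matrix **X**:
ŷ = **X**w with w on the probability simplex. Treating every domain hit as
an i.i.d. draw from the mixture density p(j) = Σᵢ wᵢ x_ij gives the
log-likelihood

    L(w) = Σⱼ y′ⱼ log Σᵢ wᵢ x_ij ,

maximised by EM for mixture proportions with fixed components:
responsibilities r_ij = wᵢ x_ij / Σₖ wₖ x_kj, update wᵢ ← Σⱼ y′ⱼ r_ij. The
update preserves the simplex and never decreases L; because L is concave in
w for fixed components, the fixed point reached from the uniform start
w = 1/K is a global maximiser, so no restarts are needed and runs are
deterministic. When reference columns are collinear the weights are not
identifiable; the fit then still yields a well-defined ŷ and well-defined
aggregated abundances, and only those should be interpreted.

**Supported-family restriction.** Families observed in the metagenome but
absent from every reference would pin L at −∞. They are excluded from the
likelihood; y is renormalised over the supported families (y′ above) for
the likelihood only. Their total is reported as `unsupported_mass`, and
they are retained in the FDU, which is always computed on the full,
unrestricted profile. If *all* observed mass is unsupported the fit raises
a degenerate-fit error rather than returning something meaningless.

**Convergence.** Iteration stops when the log-likelihood change per update
falls below `rel_tol · max(1, |L|)` (default `rel_tol = 1e-9`) or after
`max_iter = 10 000` updates; the `converged` flag records which. The
default targets abundance-level accuracy (absolute weight errors well below
1%). For studies of the estimator itself — e.g. recovering planted weights
to ≤1e-4 L1 on noise-free data — the tolerance must be tightened (the test
suite uses `rel_tol = 1e-14`), because near an interior optimum the
likelihood change scales with the *square* of the remaining weight error.
A density floor of 1e-300 inside logarithms guards against −∞ on families
a boundary iterate assigns zero mass.

**Likelihood weighting.** The fit operates on relative frequencies, not raw
hit counts. Scaling y by a total count multiplies L by a constant and does
not move the optimum, so profiles without a known `total_hits` are handled
identically.

## Model-quality indices

- **FDU** = ½ Σⱼ |yⱼ − ŷⱼ| ∈ [0, 1]: the fraction of domain-hit mass the
  model fails to reconstruct. Since both vectors are unit-sum, the
  underpredicted mass Σ max(y−ŷ, 0) equals the overpredicted mass
  Σ max(ŷ−y, 0), each equal to the FDU. Applied to two taxonomic
  abundance vectors the same statistic is the Bray-Curtis dissimilarity.
- **FSU** = 1 − (#reads with ≥1 domain hit)/(total reads): how much of the
  dataset contributed domain information at all. A read with several hits
  counts once for the FSU but contributes every hit to the profile — the
  profile is a hit-frequency distribution, the FSU a per-sequence rate.

Low FDU with high FSU means a well-fitting model on a thin statistical
basis; both should be inspected before trusting an estimate.

## Abundance aggregation

A taxon's abundance is the sum of the weights of the reference signatures
carrying that taxon at the requested rank. References with no annotation at
that rank (metagenome-derived viral signatures carry only a superkingdom)
contribute to an explicit `unclassified <superkingdom>` bucket, so mass is
conserved at every rank. For cross-tool comparisons restricted to a taxon
subset (e.g. archaea vs bacteria only), `renormalize_subset` rescales the
selected fractions to unit sum; in the CLI this is applied at superkingdom
rank via `--subset`.

## Reference building

Domain-frequency signatures depend on sequence length, so genomes are cut
into half-overlapping windows (default 400 bp, step = length/2) before
external domain detection, making genomic signatures compatible with
metagenomic ones. Regular windows start at multiples of the step. The tail
rule: when the last regular window leaves at least `min_tail` bp uncovered,
one extra window anchored at the sequence end is emitted; sequences shorter
than the window but at least `min_tail` long yield one whole-sequence
fragment. With the default `min_tail = step` the leftover tail of a
sequence longer than one window is always shorter than the step, so the
anchored window only fires when `min_tail` is lowered explicitly — the
default reproduces plain half-overlapping tiling. Fragmentation uses the
forward strand only; strand handling belongs to the downstream detector.
Short phage genomes cannot support a stable frequency estimate and are
dropped by a strict `length > 100 000` bp filter before signature
computation. N-containing fragments are emitted unchanged; filtering on
ambiguous bases is the detector's concern.

## Signature vetting (stepwise elimination)

Candidate metagenome signatures (label +1) must be separable from the
opposing class (label −1) by a ridge classifier on domain frequencies,
minimising Σ(label − w·x − b)² + λ‖w‖² with unpenalised bias. With the data
centered, the primal solution is (XᵀX + λI)⁻¹Xᵀy; with more families than
samples the push-through identity Xᵀ(XXᵀ + λI)⁻¹y gives the same solution
at sample-space cost, and both paths agree to 1e-8 (verified against an
independent solver). Prediction is sign(w·x + b) with an exact zero scored
as +1.

Each vetting round runs stratified 5-fold cross-validation, repeated 10
times with fresh seeded partitions; λ is chosen per repeat from the decade
grid 1e-4 … 1e2 by total CV error (ties: smallest λ). A sample's
misclassification rate is the fraction of repeats in which its test-fold
prediction was wrong. If any error occurred, the *eligible* sample with the
highest rate is eliminated (ties: lexicographically smallest id — one
elimination per round keeps the trace deterministic) and the round repeats
on the reduced set; the loop stops when no test error occurs anywhere. By
default only candidate-class samples are eligible, mirroring a vetting run
that may only discard candidate references. Two guarded endings: if errors
persist only on ineligible samples the procedure stops with
`stopped_clean = False`; if an elimination would leave a class with fewer
members than folds, it aborts carrying the partial trace. All rounds draw
their partitions from one seed, so results are bit-reproducible.

## Synthetic study conditions

The fixture generator emulates exactly the structure the model assumes:

- **References**: Dirichlet draws over D = 2000 families (default), grouped
  as 12 bacterial (α = 0.5), 3 archaeal (α = 0.4), 2 eukaryotic (α = 0.6)
  genome signatures and 3 viral metagenome signatures (α = 0.2,
  superkingdom-only lineage) — a bacteria-dominated collection with
  group-specific sparsity, sparser for viral profiles.
- **Metagenome**: a planted simplex weight vector (drawn Dirichlet(2) from
  the seed unless given) observed through 100 000 multinomial domain hits —
  finite-read sampling noise.
- **Hit tables**: each of n reads receives a hit with probability p, so
  FSU has planted value 1 − p (default p = 0.7, n = 10 000).
- **Vetting sets**: two Dirichlet classes whose mean profiles are tilted on
  complementary halves of the family universe; the tilt is solved by
  bisection so the symmetric KL divergence of the means equals the
  requested separation. Planted contamination = candidate-labelled samples
  drawn from the opposing class. Per-family Dirichlet concentration
  defaults to 5, giving within-class noise small enough that a separation
  of 2 is linearly separable while keeping samples visibly dispersed.

What these fixtures do *not* emulate: sequencing error, read-length
variation, correlated domain co-occurrence within genomes, database bias,
or real Pfam universe structure. Passing tests therefore demonstrate the
correctness of the estimator and procedures under the model's own
assumptions, not profiling accuracy on real metagenomes.

## Numerical choices

- Family universes are aligned on the lexicographically sorted union with
  zero fill and no renormalisation: observed mass with no reference support
  must stay visible to the FDU, and reference columns keep unit sums.
- Unit-sum normalisation iterates `v / v.sum()` to a deterministic fixed
  point (handling the one-ulp 2-cycles of floating-point division), which
  makes normalisation exactly idempotent and outputs byte-stable.
- TSV values are written with 17 significant digits; write/read round trips
  are bit-exact.
- No sparsity thresholding of small weights: fractions below 1% are
  meaningful and are reported as estimated.
- Problem sizes in the test suite (100 random EM instances at D ≤ 200;
  20-seed recovery studies at D = 2000, K = 20; one fit at D = 12 621,
  K = 2096; 20-seed vetting runs at 20+20 samples) were chosen as the
  smallest sizes at which the statistical claims are meaningful, keeping
  the whole suite around a minute plus the single full-scale fit.

## Known limitations

- The method is profile-level by design: it never classifies individual
  reads and inherits the coding-region restriction of domain detection.
- Domain detection itself (HMM scanning, ORF calling) is out of scope; the
  package consumes hit tables or ready profiles.
- Weights are point estimates; no uncertainty quantification beyond the
  FDU/FSU indices is provided.
- Collinear reference collections make individual weights unidentifiable
  (see above).
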