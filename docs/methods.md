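# Methods

## Model

Optimal local alignment scores of a fixed query against randomized subjects
are treated as draws from a type-I extreme value (Gumbel) distribution,

F(x) = exp(−e^{−λ(x−μ)}),   λ > 0,

the classical model for maxima of gapless local alignment scores. For gapped
alignment no asymptotic law is known, but gapped score distributions are
empirically close to Gumbel, and that approximation is adopted here, as is
standard in this line of work. The null is generated by *permutation*: the
subject is shuffled, which preserves its length and residue composition
exactly while destroying any ordering signal, so the null is conditioned on
the pair's compositions — the property that makes pairwise significance
database-free.

Significance is expressed in Karlin–Altschul form. With K ≡ e^{λμ}/(mn),

E(x) = K·m·n·e^{−λx} = e^{−λ(x−μ)},   pss = P(S > x) = 1 − e^{−E(x)}.

The observed score never enters the fit; the null is the N permuted
alignments only.

## Alignment

Score-only Smith–Waterman with affine gaps. **Gap convention:** a gap of
length k costs open + extend·k — the first gap residue costs open + extend
(12 with the defaults). Tools that define "open" as the total cost of the
first gap residue need open′ = open + extend when comparing. Scores are
integers; the DP accumulates in 64-bit, so lengths up to 10⁵ are safe by a
wide margin.

Both substitution matrices and query profiles feed the same kernel through a
(|alphabet| × m) score slab: for a matrix, column i is the matrix column of
query[i] (the "local profile" layout transform, provably score-neutral); for
a PSSM, the slab is the PSSM itself. Two evaluation schedules exist behind
one contract: row-major with O(m) memory (default; batches loop over tasks)
and an anti-diagonal wavefront schedule mirroring cooperative-parallel
evaluation. They are asserted equal on random instances; an exhaustive
enumerator over all alignment skeletons (all increasing matched-position
subsets, gap runs costed per sequence) provides a DP-free oracle for tiny
instances, and Bio.Align.PairwiseAligner provides an independent
cross-check at moderate lengths.

## Randomization

Permutation streams use the POSIX lrand48 LCG (a = 0x5DEECE66D, c = 11,
modulus 2⁴⁸, srand48-style seeding, 31-bit outputs) — chosen because it is
bit-exactly documented and widely implemented. A master stream seeded with
the run seed emits one 31-bit seed per permutation; each permutation then
runs descending Fisher–Yates (j = draw mod (i+1)) on its own fresh stream.
Consequences: any single permutation is reproducible in isolation; subject
j's seeds are master draws [j·N, (j+1)·N), a function of (master seed,
subject index, N) only, which is what makes the three batching strategies
bit-identical and data reuse semantically transparent. The modulo index
reduction has a bias of order n/2³¹ — negligible for protein lengths — and
is accepted in exchange for one draw per swap. The swap schedule and index
reduction are normative for this package: other permutation-based
implementations may use a different (unpublished) schedule and will produce
different, statistically equivalent nulls.

## Censored fitting

Left-censoring: scores ≤ c contribute log F(c) through their count z alone;
scores above c contribute full log-density terms. `censor="auto"` (default)
sets c to the empirical 25th percentile, discarding the non-Gumbel low tail
while keeping ≥ 750 of N = 1000 points; c is fully configurable and
`censor=None` gives the plain ML fit. The fit requires at least 50 observed
scores (configurable) and positive variance above c.

Numerics: μ is profiled out in closed form, leaving a one-dimensional score
equation g(λ) = 1/λ − x̄ + T₁(λ)/S₀(λ) = 0 whose left side is strictly
decreasing (its derivative is −1/λ² minus a variance), so the root is
unique. Newton iteration starts from the moment estimate λ₀ = π/(√6·sd),
maintains a sign-change bracket, and bisects whenever a Newton step leaves
it; convergence is |Δλ| ≤ 10⁻⁶·λ, at most 200 iterations. Scores are
shifted by their minimum before exponentiation (shift-invariant equations)
so large integer scores cannot overflow. E-values are computed as
e^{−λ(x−μ)} rather than through K·m·n to avoid overflowing e^{λμ}.
The likelihood treats integer scores as continuous Gumbel draws; the
discreteness correction is ignored, as is usual in this practice.

## Device model and batching

The SIMT model is pure arithmetic — no hardware probing: occupancy =
(B·T_num)/T_max with B = min(B_user, B_reg, B_shr, B_hw, ⌈T_max/T_num⌉,
workload share), and the adaptive tile size T = ⌊SM·T_max/N⌋ (an
infeasible T = 0 raises with advice to reduce N). The default profile
(SM = 14, T_max = 1024, B_hw = 8, warp 32) is a Tesla C2050-class device.
B_reg/B_shr default to unconstrained since they depend on kernel resource
usage this model does not simulate; a warning is issued when T_num is not a
warp multiple. The planner orders work the way a coalesced-memory
implementation would ship it (tile of subjects → N permutations each → one
fit per pair), but this is a scheduling convention here, not a memory-system
claim; wall-clock performance of real devices is out of scope.

In this package alignment batches may be executed concurrently in principle,
but fitting is sequential per pair on the host side; all strategies are
value-deterministic by contract.

## Synthetic data

The fixture generator emulates a protein comparison workload: i.i.d.
residues over the 20 standard amino acids, uniform by default or with any
requested composition, default length 200 (a typical protein domain length,
and the smallest sequence-length condition used in the multi-pair analyses
this package's batch arithmetic reproduces). Synthetic PSSMs are BLOSUM62
query columns plus small integer noise (±2), written in the PSI-BLAST ASCII
dialect. What this does **not** emulate: real domain databases have length
variation, composition bias, low-complexity regions, and true homologous
structure; synthetic PSSMs carry no real conservation signal. Passing tests
therefore demonstrate the estimator's internal correctness and statistical
calibration under its own model — not retrieval accuracy on real protein
families, which would require curated homolog databases and is out of scope.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| N (permutations) | 1000 | shuffles | standard choice balancing fit stability (≥750 observed after quartile censoring) against N alignments per pair |
| gap open / extend | 10 / 2 | score units | the common BLOSUM62 pairing 10 + 2k |
| matrix | BLOSUM62 | — | 24-letter NCBI table, bundled via Biopython |
| censor | 25th percentile | score units | robustly drops the non-Gumbel low tail; configurable/off |
| master seed | 0 | — | all randomness derives from it; runs are byte-reproducible |
| device profile | tesla-c2050 | — | SM=14, T_max=1024, B_hw=8, warp 32 |

## Design decisions taken where the design was open

- **PSSM parsing** reads only the 20 log-odds columns of the ASCII PSSM and
  ignores the weighted-percentage block; rows for B/Z/X/* (absent from
  PSSMs) default to BLOSUM62 against the query residue at that position,
  with a constant-penalty alternative.
- **Strict validation** of residues by default, with an opt-in
  map-unknown-to-X mode for real-world files.
- **The observed pair is scored in the same batch** as its permutations
  (row 0), so x and the null come from one kernel invocation.
- **Per-subject, query-independent seeding** was chosen to make the three
  strategies comparable and testable for bit-identity.
- **Test problem sizes**: the strategy-equivalence suite runs 3 queries × 5
  subjects at length 200 with N = 1000; fit-recovery uses 100 replicates of
  N = 1000 per λ ∈ {0.1, 0.3, 0.7}. These sizes give stable statistics while
  keeping the full suite fast on one CPU.

## Limitations

- Gumbel-with-permutation is an approximation for gapped scores; no
  finite-size (edge) correction or island statistics are applied.
- Empirical P-values by direct counting are not the contract (the fit is);
  λ and K estimates carry sampling error of order 1/√N.
- Score-only: no tracebacks or alignment strings.
- The device model predicts occupancy arithmetic, not wall-clock speed.
- Retrieval-accuracy evaluation against curated databases is out of scope.
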