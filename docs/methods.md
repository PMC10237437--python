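# Methods

## Model and pipeline

`kleevec` operates on a multiple sequence alignment partitioned into
sequence sets (usually species). The alignment must already be built and
trimmed — alignment construction is upstream and out of scope. Only DNA
alphabets are supported.

**Encoding.** Residues map to four-weight blocks over (A, C, G, T):
unambiguous bases are unit basis vectors, `U` is treated as `T`, gaps
(`-`, `.`) are all-zero, and an IUPAC ambiguity code covering *k* bases
puts 1/*k* on each covered base, so every non-gap block sums to 1.
Parsing is case-insensitive; any character outside this alphabet is a
hard error rather than being coerced to `N`, because silent coercion
hides alignment corruption.

**N imputation.** Within each set and column, an `N` is replaced by the
column's modal character unless that mode is a gap or is tied among
several non-gap characters. The mode is computed over *all* characters
of the column (gaps and `N` included), and replacement candidates are
the modal characters minus gaps and minus `N` itself; imputation happens
only when exactly one candidate remains. This makes the rule total: a
column whose mode is `N` (e.g. a singleton set's own `N`) keeps `N`, a
tie between a gap and one base resolves to the base, and a tie between
two bases keeps `N`. Imputation reads pre-imputation column contents
only, so it cannot cascade, and it is idempotent. A modal ambiguity code
(e.g. a column of `R`s) is an eligible replacement: the rule replaces
`N` by the most frequent character, whatever it is.

**Reference matrix.** `R = Σ_j S_j/m_j` with `S_j = s_jᵀ s_j` the 4s×4s
position-space Gram matrix of set *j* and `m_j` its sequence count. The
normalisation by `m_j` is what allows sets of unequal size. `R` is
symmetric positive semi-definite, and because it is a plain sum, any
partition of the sets into batches gives partial references that merge
(by matrix addition, with disjointness of set names enforced) into the
monolithic result, up to float summation reordering (≤1e-10 relative in
practice; accumulation is plain float64 with no compensated summation).

**Indicator vectors.** For an in-reference set,
`M_i = N/(N−1)·S_i/m_i − 1/(N−1)·R = N/(N−1)·(S_i/m_i − R/N)`; summed
over all in-reference sets these contrasts cancel exactly, a useful
end-to-end algebra check. The indicator vector is the unit eigenvector
for the algebraically largest eigenvalue of `M_i`, required to be
strictly positive (a zero or negative leading eigenvalue means the set
is indistinguishable from the reference mean — e.g. duplicated sets —
and is reported as a degenerate-contrast error naming the set). Sets
absent from the reference use `M = S_i/m_i − R/N`: the in-reference
formula without self-exclusion (impossible for an unseen set) and
without the positive scalar `N/(N−1)`, which cannot change eigenvectors.

**Structure matrix.** Pairwise similarity of the indicator vectors.
The default is Pearson correlation (vectors mean-centred, then
normalised inner product); raw cosine of the unit vectors is available
via `similarity="cosine"` since the two differ only by centring and
either can be preferred for comparing with other tools. Oneshot mode
computes one matrix product; streaming mode computes one row at a time
holding at most one row plus two vectors; `auto` switches to streaming
above 5,000 vectors. Both modes agree within 1e-12 elementwise.

## Numerical choices

- **Eigensolver.** Dense symmetric decomposition (`numpy.linalg.eigh`)
  up to 512 dimensions; above that, Lanczos (`scipy.sparse.linalg.eigsh`,
  `k=1`, largest-algebraic, tolerance 1e-10, max 10,000 iterations) with
  a fixed all-ones starting vector so results are deterministic. The 512
  threshold reflects the measured crossover: at 4s = 1600 the dense path
  is ~60× slower for no accuracy benefit, and the iterative path is
  validated against the dense decomposition in the test suite (λ within
  1e-8 relative, vector within 1e-6 up to sign). Every returned pair is
  checked against the residual bound ‖Mv − λv‖ ≤ 1e-8·‖M‖.
- **Sign convention.** Eigenvectors are defined up to sign; the
  component of largest magnitude is made positive (ties broken by lowest
  index) so repeated runs and split runs produce identical files.
  Downstream comparisons between *independently produced* vector sets
  still use absolute correlations, since different references can flip
  the geometry.
- **Near-degenerate spectra.** When the dense path sees
  (λ₁−λ₂)/λ₁ < 1e-6 it logs a warning that the indicator vector may be
  unstable; the vector is still returned.
- **Projected fast path.** Every contrast matrix built from any subset
  of the sets lies in the span of the encoded sequence rows, so the
  reference-subset experiments project onto an orthonormal basis of that
  span (rank ≤ total sequence count) and solve small dense eigenproblems
  with identical positive leading eigenpairs — the orthogonal complement
  contributes only zero eigenvalues. Equivalence with the full-space
  computation is asserted in the tests at 1e-8.
- **File formats.** The reference matrix and the structure matrix use
  small endian-pinned binary formats (magics `BIVR`/`BIVS`, versioned);
  the reference stores its contributing set names so merge disjointness
  can be enforced; the structure file stores the lower triangle as one
  record per set so updates append without touching existing bytes.
  Indicator vectors are CSV with 17 significant digits, so reading
  restores exact float64 values and split runs merge by concatenation
  (repeated header lines are skipped on read). The CSV does not record
  whether a vector was extrapolated; readers treat all vectors alike,
  which is correct for every downstream computation.
- **Parallelism.** The per-set computations are embarrassingly parallel;
  `--workers` exercises a partitioned code path whose contract is result
  equivalence (within 1e-10 for sums, 1e-12 for per-set results), not a
  particular backend. No MPI runtime is required.

## Synthetic data

The simulator emulates the hierarchical similarity structure of curated
barcode datasets: an ancestral sequence is mutated per-site (probability
*d*, uniform choice among the three other bases — a Jukes–Cantor-like
process) into group ancestors, set ancestors, and member sequences, with
the constraint `d_within_set ≤ d_between_sets ≤ d_between_groups` so a
clade signal exists. Noise injection replaces a member's site with a gap
(`p_gap`), an `N` (`p_N`), or a random 2/3-base ambiguity code covering
the true base (`p_iupac`). The default "medium" dataset — 5 groups × 10
sets × 3 members, s = 400, divergences 0.15/0.05/0.01, noise
0.01/0.01/0.002 — mirrors at reduced scale a curated mammalian barcode
alignment of a few hundred species with a few sequences each and rare
ambiguity codes; the sizes keep the full test suite in minutes on one
CPU. The generator produces no indels beyond injected gap characters, no
rate heterogeneity, no codon structure and no saturation, so passing
tests demonstrate the correctness of the linear algebra and the file
contracts on clade-structured input, not realism of COI evolution; on
real data the absolute correlation levels will differ even though the
invariances (partition, update, mode equivalence) carry over unchanged.

## Missingness experiment

`run_missingness_experiment` drops a random fraction *f* of the sequence
sets from the reference (10%–90% in the bundled experiment, 10
replicates per fraction, seeded per replicate), recomputes every set's
indicator vector against the reduced reference — extrapolating the
dropped sets — and reports per-set absolute Pearson correlation with the
full-reference vectors. Dropping whole sets is the default because
indicator vectors are per-set and extrapolation concerns sets absent
from the reference; `drop_level="sequence"` instead removes individual
sequences, letting partially sampled sets remain in the reference. On
the medium synthetic dataset the median correlation stays above 0.999
at 10% missing and degrades monotonically to ≈0.985 at 90%, the
qualitative pattern expected when the reference summarises many sets
and each contrast is dominated by the set's own Gram matrix.

## Known limitations

- Only additive reference merges are supported; removing a set from a
  reference requires recomputation from the surviving sets.
- Only the leading eigenpair is extracted; sets whose structure needs
  several eigenvectors are summarised by one.
- The structure file cannot delete or reorder records; it only appends.
- Imputation never fills ambiguity codes other than `N`, and the
  encoding treats all IUPAC codes as uninformative mixtures rather than
  quality-weighted calls.
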