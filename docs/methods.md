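# Methods

## Model

A genome is a set of chromosomes, each an ordered sequence of signed
genes; chromosomes are linear at initialization, and circular fragments
arise only through excision. A simulation starts from `c` linear
chromosomes of equal size totalling `N` genes, with a fraction µ of
genes flagged *sensitive* (drawn uniformly without replacement).

One move makes two cuts at uniformly random adjacencies (telomeric cut
sites included by default; coincident cut pairs are resampled) and
rejoins the four ends by one of the two non-identity reconnections,
chosen uniformly and independently of the cut positions. Depending on
cut locations and reconnection, the move realizes an inversion, a
reciprocal translocation (tail-swap or cross variant), an excision of a
circular fragment, a reintegration, a fission into a circle plus a
linear piece, or a fusion. The simulator counts *accepted* moves: a run
of length `n` applies exactly `n` moves that pass the active model's
acceptance rule, with a proposal budget guarding against stalls.

Acceptance rules:

- **dcj** — accept everything.
- **ds** — accept iff the partition of sensitive genes among chromosomes
  is unchanged by the move; evaluated by closed-form fragment tests, and
  cross-checked in the tests against a brute-force partition oracle.
- **maxT** — intra-chromosomal moves are free; a translocation is
  accepted iff both exchanged fragments are at most `T_max` genes; an
  excision iff the excised circle is at most `T_max`.
- **maxL** — maxT's rules with `T_max := L_max`, plus inversions longer
  than `L_max` genes are rejected.
- **pfix** — every proposed inter-chromosomal move is accepted with
  probability `p_fix` (then applied unconditionally); intra-chromosomal
  moves are free.

Randomness is split into three independent streams (initialization,
proposals, model decisions) so that every constrained model at its
limiting parameter reproduces the plain-DCJ run bit for bit under the
same seed.

## Synteny statistics

Given two genomes sharing a gene universe and a marker set (uniform
sample without replacement, or all genes):

- **Macro-synteny p.** Each chromosome of genome *a* is matched to the
  chromosome of *b* maximizing the z-score
  `z = (O − E)/sqrt(V)` with `O` the shared marker count,
  `E = m_i m_j / N_m`, and `V = m_i q (1 − q)`, `q = m_j / N_m`.
  `p` is the fraction of markers residing on matched chromosome pairs.
  Markers stranded on circular fragments are counted as not conserved.
- **Micro-synteny s.** Both genomes are reduced to the marker set; `s`
  is the fraction of marker adjacencies of *a* present in *b*
  (unordered, orientation-ignoring by default; a signed variant is
  available). Circular chromosomes contribute their wrap-around
  adjacency.

`p` is robust to marker subsampling; `s` is intrinsically
marker-density dependent (sparser markers span longer gene paths), so
marker counts must be matched between compared genome pairs — the test
suite demonstrates both behaviors.

## Parameter fitting

For an observed pair `(p_obs, s_obs)` with `N_m` markers, the objective
is `χ² = ((mean_s − s_obs)/σ_s)² + ((mean_p − p_obs)/σ_p)²`, where
means and standard deviations are over replicate simulations at
`(n, parameter)` (default 10 replicates, with a small σ floor).
Replicate seeds are derived from the fit seed only, so every evaluation
within a fit reuses the same random streams (common random numbers);
this keeps the objective deterministic and far smoother than
independent seeding. With few replicates the per-point σ estimates are
noisy enough to break the optimizer, so the 10-replicate default is
load-bearing.

Estimation is two-phase: (1) alternating bounded Brent minimizations
over `n` and the model parameter (relative tolerance 1%, at most 10
sweeps; `p_fix` is optimized in log10 space); (2) a 7×7 grid spanning
±15% of the phase-one optimum, a least-squares quadratic surface
`a + bx + cy + dx² + ey² + fxy`, and its stationary point when the
Hessian is positive definite (grid argmin otherwise). Results are
returned as a model/result object pair with the evaluation grid
attached.

Trees are built by neighbor joining (scikit-bio) on fitted
accepted-move distances, with negative branch lengths clamped to zero;
matrices round-trip through square PHYLIP format and trees through
Newick.

## Multi-lineage simulation

Star or Newick-specified trees evolve one root genome along each branch
for a branch-specific number of accepted moves. In `shared` mode every
branch keeps the root's sensitive set; in `independent` mode each
branch redraws it. A gene family counts as conserved across all leaves
iff, in every leaf, it lies on the chromosome that is the best z-score
match of its root chromosome. The closed-form comparison point for `k`
leaves is `N_fam · q^k` with `q² = mean pairwise p`.

## Generator realism and limitations

- Gene content is fixed: no duplication, loss, or sequence evolution;
  a "gene" is an abstract ordered marker.
- All genes are equally spaced; cut probabilities are uniform per
  adjacency, so gene length and rearrangement hot spots are ignored.
- The sensitive fraction is a stationary property (no turnover of
  sensitivity), and sensitivity is binary.
- Under maxT/maxL, capped inter-chromosomal exchanges concentrate near
  chromosome ends, producing breakpoint reuse; micro-synteny therefore
  decays more slowly per accepted move than under DS at matched
  macro-synteny.
- Micro-synteny comparisons require matched marker densities (see
  above); cross-density comparisons are not meaningful.
- Time is measured in accepted moves; no molecular clock or population
  dynamics is modeled, so fitted `n` values are relative divergences,
  not times.
- Fitted parameters from the bundled five-genome table are taken as
  published inputs; this package recomputes forward checks from them
  but does not refit the underlying genome assemblies.
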