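# Methods

## Model class and assumptions

The aggregation machinery applies to undirected, weighted networks
whose connection matrix `K` is Laplacian-like: symmetric with zero row
sums (validated to 1e-9 absolute; violations warn rather than error,
because empirical weighted graphs are often non-conservative, but the
aggregability check then refuses to certify the reduction). The node
set carries a user-supplied partition into `r` non-empty areas; nodes
are stored area-by-area so the slow/fast transform is block structured.
Community detection is out of scope — the partition is an input.

The sparsity parameters are combinatorial: a weighted link counts as a
single link when computing `c^I` (min internal links per node), `c^E`
(max external links per node) and `γ^E` (max external links per area).
Weights enter only the dynamics. Two node-parameter variants are
provided: the worst-case ratio `d = c^E/c^I` and the per-node average
`d_ave` (mean over nodes of each node's own external/internal ratio),
which is the more robust summary for empirical graphs. Neither is
treated as canonical; reports carry both.

## Slow/fast transform

Within-area difference coordinates use the orthonormal difference
matrix (first column constant `−1+(n−1)υ`, remaining block `1−υ` on
the diagonal and `−υ` off it, `υ = (n−√n)/(n(n−1))`), whose
pseudoinverse is its transpose. The plain (−1 | identity) difference
dialect is available behind `q_dialect="difference"` for
cross-checking; it uses the explicit pseudoinverse in the coupling
blocks and leaves the reduced spectra unchanged (verified in tests).
Singleton areas contribute empty fast blocks; a single-area partition
has no inter-area difference matrix `R` (flagged, not an error).

The symbol `υ` above is a scalar matrix parameter; it is unrelated to
the reference velocity `v(t)` of the flow-network model, which is a
separate argument of the flow simulator (constants and callables are
accepted).

## Reduction and its validity

The unscaled block system is built exactly as
`A11t = G K^E U`, `A12t = G K^E Qᵀ`, `A21t = Q K^E U`,
`A22t = Q (K^I + K^E) Qᵀ`, then rescaled by `c^I δ`, `c^I d` and `c^I`.
The reduced slow matrix is `A0 = A11 − d A12 A22⁻¹ A21`; the fast
subsystem is `A22` with the corrected initial condition
`z_f(0) = z(0) + d A22⁻¹ A21 y(0)`.

The theory guarantees the separation only for sufficiently small
`d, δ` without giving thresholds. The implemented, falsifiable reading
is a check list: zero row sums hold; every node has an internal link;
`d < 1` and `δ < 1`; the fast block is nonsingular (condition number
≤ 1e12) and Hurwitz (all real parts < −1e-9). Any failed check makes
a network "not aggregable" with the reasons listed — this also
represents the empirical case of graphs that cannot be aggregated.

Two caveats the tests document explicitly:

- The reduced model carries an O(d) approximation error even when the
  initial state is area-constant (`z(0) = 0`): the coupling block
  `A21t` re-excites the fast variable from the slow one. The full and
  reduced area means therefore agree to a few percent of the signal,
  not to integrator tolerance.
- Eigenvalue convergence of the full system to `A0`'s spectrum (and of
  `A0` to the rigid aggregate `M_a⁻¹ K_a`) is checked on an external
  weight sweep ε ∈ {1, ½, ¼, ⅛}: errors must shrink monotonically.

## Pinning criteria

The global test symmetrizes the `Nn × Nn` matrix before the eigenvalue
check; negative definiteness means `λ_max < −1e-9` (a Cholesky
factorisation of the negated matrix serves as an independent oracle in
tests). The decoupled per-node test uses per-node constants `c_i`
(uniform `c` by default; an optional log-grid search over
`c ∈ [1e-2, 1e2]` reports the best achievable margin per node). The
pinning gain enters as `−d_i I`, an exact spectral shift, so the
minimal repairing gain equals the zero-gain margin; it is nevertheless
computed by bisection (bracket doubled from 1, tolerance 1e-6) and the
two must agree — a regression guard on the matrix assembly.

Sign and bound conventions for the 3-node worked example: the printed
self-decay magnitudes `a_i` are implemented as drifts `A_i = −a_i`
(with positive drifts every node is unstable and no single node is
singled out; the decay convention reproduces the printed outcome), and
the sigmoid output is `tanh(K x)` with `K = 1`, giving the Lipschitz
bound `Γ = K·I`. The printed pinning gain 1.5 is applied to the
identified node, node 3. An alternative Schur-complement block form of
the per-node test is implemented verbatim as a cross-check mode only:
its coupling bound goes through the identity rather than `Γ`, so it is
not algebraically equivalent to the primary test and no reconciliation
is guessed.

## Simulation

All integrators are adaptive RK45 with rtol 1e-8 / atol 1e-10,
dense-sampled on a uniform output grid, with a divergence guard at
state magnitude 1e12. Flow-network nonlinearities must satisfy the
sector condition `f(θ)·θ > 0` (checked on a logarithmic sample grid
before integrating); the dissipative link term is orthogonal to the
ones vector, so total activation is conserved (linear case) or drifts
exactly at the reference velocity. The fast-transient duration is
reported as the first time `|Q x(t)|` drops below 5% of its initial
value (reported, never asserted); an initial fast norm below 1e-12
counts as an exactly slow start. Lyapunov decay of the pinned observer
error uses `V(t) = ½ Σ|e_i|²` and tolerates discrete differences up to
+1e-9.

## Synthetic generator

The generator emulates the assumed topology class: per area, a random
spanning tree plus extra edges until the internal minimum degree is
met (connectedness guarantees a nonsingular internal Laplacian block,
hence a Hurwitz fast subsystem); external links are placed uniformly
at random under per-node and per-area caps, so the emitted network's
`d` and `δ` are bounded by the cap-implied ratios. Matrices are
emitted as negative weighted Laplacians, making every generated
instance conservative and (by construction) aggregable. Defaults
mirror the worked example's regime: unit weights, internal minimum
degree 2, one external link per node, two per area.

What the generator does **not** emulate: empirical degree
distributions (no scale-free tails), signed or directed couplings,
and measurement noise. Passing tests on generated instances therefore
demonstrate correctness of the algorithms on the assumed topology
class, not robustness to real connectome estimation artifacts.
Heterogeneous dynamics are generated with uniformly drawn stable decay
rates plus a small random skew part and a sparse symmetric coupling
matrix with entries in [−0.5, 0.5].

## Problem sizes

The worked examples are 8 nodes / 2 areas and 3 nodes; generated
instances in the tests use 8–22 nodes and simulations run to t ≤ 50 at
output steps of 0.01–0.5, which resolves every reported rate while
keeping the whole suite in the seconds range. Larger networks are
generated on demand rather than stored.

## Known limitations

- The aggregability thresholds (`d, δ < 1`, Hurwitz fast block) are a
  conservative, checkable proxy for the existence statement of the
  underlying theorem; they can reject networks that a sharper analysis
  would accept.
- Directed networks, partition inference, time-varying or adaptive
  pinning gains, and optimal pinned-set selection are out of scope.
- Tables of empirical connectome results cannot be reproduced here
  because the underlying adjacency data were never published; the
  `aggregate` command emits the same report fields on generated
  stand-in networks instead.
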