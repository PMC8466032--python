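# Methods

## Model and decomposition

A discrete Bayesian network N on X = {X1..Xn} is a DAG plus one
conditional probability table per variable on its family
f(Xi) = {Xi} ∪ pa(Xi); the joint is p = Π_i φ_i.  For two networks on the
same variables, the divergence of the approximation N^B from the
reference N^A is

    KL(N^A, N^B) = LL(N^A, N^A) − LL(N^A, N^B),
    LL(N^A, N^B) = Σ_i Σ_{x_fi} log(φ_i^B(x_fi)) · (p^A)↓fi(x_fi),

so everything reduces to marginals of the reference joint on the union
of both networks' families.  Potentials (nonnegative tables over a
scope) support exactly three operations — pointwise product on the union
scope, summation removal of a variable, and selection (slicing at an
observed configuration) — and all engines are compositions of these.
Scopes are kept in a canonical order (ascending declaration index) so
that equal-scope potentials always share axis order; tables are stored
in linear space, and logarithms enter only in the divergence layer, so
the algebra keeps its textbook contracts (e.g. a CPT summed over its
child is identically 1).

## Engines

**Brute force.**  Materializes both joints (identical canonical axis
order makes the comparison a flat array operation) and sums
p^A (log p^A − log p^B) over the support of p^A.  Guarded by a
state-space cap (default 2^22 entries); this is the oracle every other
engine is tested against, feasible precisely because the test networks
are desk-scale.

**Evidence propagation.**  For each variable Xi of N^B and each parent
configuration x_pa: prune the reference CPT set to the requisite
potentials, restrict them to the evidence pa = x_pa, delete every other
variable, and multiply the survivors into q with
q(x_i) = p^A(x_i, x_pa).  The LL term accumulates q(x_i) ·
log φ_i^B(x_i, x_pa); q is deliberately *not* normalized — the evidence
mass is part of the decomposition.  The engine performs
Σ_i Π_{X_j ∈ pa(X_i)} n_j elimination runs per LL term (asserted exactly
in the tests), which is what makes it expensive on dense networks.

Pruning for this engine passes a Bayes-ball over the query set
{target} ∪ evidence with an *empty* observed set.  The classical
posterior-requisite variant (evidence nodes blocking balls from their
children) would drop the evidence variables' own prior CPTs, which
cancel in a normalized posterior but are required for the unnormalized
q used here; with the joint-mass formulation the requisite set is the
ancestral closure of {target} ∪ evidence, and the traversal is kept as
a genuine ball-passing so the two pruning rules of the package remain
independently implemented and cross-checked.

**Cached variable elimination.**  All K family marginals are planned in
one batch over the reference network.  Two repositories are kept:

* R_Φ (potentials): id → (scope, time); the numeric table exists only
  during execution.  `time` is the planner clock value of the last
  operation needing the potential; −1 marks query results, which are
  never reclaimed.
* R_O (operations): registers (id, type, arg1, arg2, result) for every
  symbolic combination or marginalization, keyed by the ordered argument
  pair (combinations are always enumerated in ascending repository-id
  order, so an unordered key would add nothing).

Planning walks the queries in order.  For each query: select the
relevant CPTs (ancestral rule — a CPT is relevant iff its variable is in
the query or an ancestor of a member), eliminate the out-of-query
variables in min-weight order, combining the potentials that mention
each variable pairwise through the *conditional* operations, then
combine the survivors into the query result.  A conditional operation
first looks in R_O: on a hit it only refreshes time stamps; on a miss it
creates the symbolic result and a new register.  The clock t starts at 1
and increments after every conditional call, *hits included*, and a
register's id is the clock at creation — so ids may skip values wherever
a hit consumed a tick.  This discipline is what makes the worked-example
trace deterministic: for the three-variable pair with queries
{X1}, {X1,X2}, {X1,X3}, {X2,X3} the registers carry ids 1, 2, 4, 5, the
lone marginalization is id 5, and the fourth query's first combination
is a hit on the register created during query 2.

Execution walks t = 1..T: the register with id t (if any) is computed
numerically — each register exactly once — and then every repository
entry stamped t is reclaimed.  Reclamation sweeps by stamp rather than
only the register's three operands so that potentials whose *last* use
was a cache hit (a tick with no register) are also freed; either way an
entry is dead exactly when the clock passes its stamp.  On return only
protected entries survive (asserted), and the counters are reported as
ops = |R_O| (numeric operations executed), rep = cache hits (operations
avoided), del = potentials reclaimed.

## Orderings and tie-breaks

Elimination orders come from the greedy min-weight heuristic on the
interaction graph induced by the current scopes: repeatedly remove the
eliminable variable whose closed neighborhood has the smallest product
of cardinalities, connecting its neighbors.  Ties break on the lowest
declaration index, making every plan deterministic.  Any order produces
the same numbers (asserted against 10 random orders per instance); it
changes only which operations repeat.  Within one deletion, potentials
are combined pairwise in ascending repository-id order; optimizing that
combination order is an open efficiency question, not a correctness one.

## Numerical conventions

* Logarithms: natural log by default; base 2 via `log_base=2`
  (`kl_bits == kl_nats / ln 2` is asserted to 1e-12).
* Zeros: 0·log 0 := 0 always.  Reference mass on a configuration where
  N^B has probability zero makes the divergence +∞; the default
  "extended" policy returns `inf` with a `ZeroProbabilityWarning`,
  `"strict"` raises.  Learned networks with structural zeros are common,
  and silently clamping them would misreport an infinite divergence, so
  neither policy perturbs the tables.
* CPT normalization is validated, never repaired: each column must sum
  to 1 within 1e-9 for programmatic construction; file readers allow
  1e-6 (published networks carry rounded parameters) and either warn
  (default) or raise (`strict=True`).
* The BIF writer prints floats with `repr`, so a write/read round trip
  is exact and KL(N, reread(N)) = 0 to machine precision.

## Synthetic data

The generator emulates the original-versus-learned benchmark setting.
`random_network` draws a random topological order, samples up to
`max_parents` parents per node from its predecessors, and fills each CPT
column with a symmetric Dirichlet(α) draw.  Defaults (α = 1, binary
states, 3 parents max) give diffuse, fully supported CPTs.
`perturb_network` plays the learned network: it applies a given number
of edge moves, each drawn uniformly from the currently feasible
additions/removals/reversals (feasible = acyclic and within the parent
bound), and re-samples the CPTs of the families whose parent set
changed.  `forward_sample` draws ancestral samples for completeness of
the benchmark workflow.

The engine test battery runs on pairs of 8 binary variables, max 3
parents, Dirichlet(1) CPTs, 3 edge moves, over 100 seeds — small enough
that the brute-force oracle (256-entry joints) verifies every value,
while still exercising caching (rep > 0 on most instances).  What these
tests do *not* show: behavior at the scale where the cached engine's
advantage is dramatic (hundreds of variables, large parent sets), memory
behavior on near-infeasible instances, or CPTs with the deterministic
zeros real expert-built networks contain (zeros are covered separately
by the policy tests).  Wall-clock comparisons between engines are
reported by the bench harness but never asserted.

## Known limitations

* Discrete networks only; no Gaussian/continuous potentials.
* No structure or parameter learning; the package evaluates networks it
  is given.
* The operation cache lives within one planning batch; there is no
  cross-invocation persistence.
* Only min-weight ordering is built in (the planner accepts any
  user-supplied ordering function behind the same contract).
* The brute-force oracle is capped and genuinely unusable beyond ~22
  binary variables; above desk scale the two local-computation engines
  check each other.
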