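# Methods

## Model

### Automata and composition

Types are encoded by the 4-bit mask of their transition set (bit values
1 = 0→0, 2 = 0→1, 4 = 1→0, 8 = 1→1), so the type index *is* the algebraic
object and composition is the relational product of two bit-relations.
`compose(a, b)` is the machine obtained by passing the signal through `a`
first and `b` second (operator notation T_b ∘ T_a).  The full 16×16 table
is computed once and cached; every other module consumes the cached table
rather than recomputing compositions.  Composition on transition sets is
associative, T9 (the identity relation) is a two-sided identity, T15 (the
total relation) never composes to T0, and the 0↔1 alphabet swap
(1↔8, 2↔4, 3↔12, 5↔10, 7↔14, 11↔13) is an automorphism of the table; the
test suite asserts all four properties exhaustively.

### Lattice dynamics

One production time step = one replacement attempt at a uniformly chosen
site.  With probability Φ the occupant is replaced by a uniform draw from
the influx set; otherwise one of the two opposite von-Neumann neighbour
pairs (north/south or east/west) and an acting order are drawn, each of
the four ordered arrangements with probability 1/4, and the composition
product replaces the occupant unless it is T0.  Influx and composition are
mutually exclusive within a step, matching the stated probabilities Φ and
1 − Φ.  After each production step, c mixing events each pick a site, a
cardinal direction (independent of the displacement), and a displacement
d ~ Normal(0, v) ("variance v", so the standard deviation is √v), rounded
to the nearest integer with ties away from zero; |d| = 0 is a no-op.  Swap
sites are drawn with replacement — for c ≪ N the difference from
without-replacement sampling is negligible, and with-replacement is the
simplest scheme consistent with "c events per production step".  Influx
draws may equal the displaced occupant.

The inner loop is a numba kernel over int8 grids with an explicitly seeded
generator; per-phase kernel seeds derive from the run seed via NumPy's
`SeedSequence`, making every output a pure function of (config, schedule,
seed).

### Mean-field dynamics

The well-mixed drift is

    ḟ_c = P_c(f)(1 − f_c) − f_c(1 − P_c(f) − P_0(f)),
    P_x(f) = Σ_{(a,b): a∘-product = x} f_a f_b,

reconstructed from two requirements: the gain term is the probability of
producing T_c times the probability that the replaced occupant is not
already T_c, and the loss term is the probability that some other
successful product replaces a T_c occupant.  The drift sums to zero on the
simplex, and fixed points satisfy f_c = P_c/(1 − P_0); both identities are
asserted numerically.  Constant factors such as the 1/4 arrangement
probability rescale time only and are omitted — they cannot move fixed
points.  Three independent anchors validate the reconstruction: the
restricted fixed point of {1,2,4,8} is exactly uniform, that of {6,9} is
exactly (1/2, 1/2), and the full-population fixed point extinguishes
{6,7,9,11,13,14} while tiering the nine survivors.

Integration is explicit Euler with step 0.1, clipping at zero and
renormalising each step; the map is smooth and bounded on the simplex, so
no stiff machinery is warranted.  Convergence tolerance 1e-9 on the drift
(1e-12 in the census, where fixed points feed classification), budget 10⁶
steps.  The extinction threshold for restricted dynamics is 1e-6: three
orders of magnitude below the smallest meaningful fixed-point mass on a
≤15-type simplex and far above accumulated Euler error.

### Information measures

C_μ(G) is the base-2 Shannon entropy of the weights f_a f_b / V over the
207 productive ordered pairs (V the normalising sum).  An alternative
reading that first aggregates the weights per product type is exposed as
`production_complexity`; only the pair-level entropy attains log₂ 207 at
the uniform population, which pins it as the niche-complexity measure.
The production threshold H(X) is the base-2 entropy of the distribution
x_i = (within-subset pairs producing type i)/(total within-subset pairs);
it is defined on type subsets, not frequency vectors.  0·log 0 = 0
throughout.  For threshold bookkeeping each named niche carries a
*production core*: the subset whose internal production dominates the
niche (e.g. {1,2,4,8} for both B and the equalised secondary niche X,
whose dynamics are governed by the same elementary network even while
decaying trace types remain visible).

## Network census

Every subset of 2–15 types induces a production digraph with edges from
both operands of each within-subset productive pair to its product.  The
taxonomy:

1. **network** — every member is produced by at least one within-subset
   interaction beyond pure self-replication and participates in producing
   a member other than itself.  7831 of the 32 752 subsets qualify.
2. **candidate strongly connected** — the production digraph is strongly
   connected (mutual production through directed cycles); 308 subsets.
3. **dynamically stable** — additionally closed under composition, and no
   member falls below the extinction threshold under restricted dynamics
   from a uniform start (Euler horizon 10⁵ steps); 29 subsets.  For this
   composition table, stability is equivalently characterised as closed ∧
   strongly connected — every closed candidate retains all members.
4. **elementary** — stable with no proper stable sub-network; 12 subsets,
   leaving 17 reducible stable networks.

Irreducibility is implemented as minimality rather than literal
single-member removal: a stable network like {1,3,5,15} survives every
leave-one-out test (all its 3-subsets fail closure) yet contains the
stable sub-networks {1,3} and {5,15}, so it is reducible in the sense that
matters — it can be decomposed into smaller self-producing parts.
Minimality also yields the clean 17 + 12 split of the 29 stable networks.

The candidate count is the one census class for which no clean structural
rule reproduces the historically reported figure of 129; a systematic
sweep (≈1600 combinations of degree metrics, self-loop handling,
thresholds and connectivity notions, plus component-level and
context-graph variants) found rules yielding 13, 29, 97, 100-free values,
251, 308, 398 … but never 129, while the neighbouring counts (7831, 29,
17 + 12) are all reproduced exactly.  The package reports the strong-
connectivity count of 308 and flags the discrepancy rather than fitting an
ad-hoc rule to the target.

The niche hierarchy builds level 0 from the elementary networks contained
in a stable niche and level k from stable pairwise unions of level-(k−1)
networks, recording types newly producible at each union and, per type,
how many elementary networks produce it (redundancy).  For the
nine-survivor niche this gives 11 → 6 → 1 levels, with every type covered
by ≥2 elementary networks except T2 and T4, which depend on {1,2,4,8}
alone.

## Niche classification

Classification is a pure function of a steady-state frequency vector plus
the survivor set.  A type is *sustained* above 0.003 (30 occupants on the
scaled lattice); lower frequencies are decaying traces or influx noise.
Clusters group sustained types whose consecutive sorted frequencies differ
by less than a factor 1.5 (the nine-survivor niche's tiers sit at ratio
≈1.8).  Rules, in evaluation order: near-uniform over all 15 (max
deviation < 0.01) → D; f(T15) ≥ 0.95 → Y; T15 dominant (> 0.5) over a
sustained {6,7,9,11,13,14} with the other eight gone → F; all 15
sustained with T2, T4 the two leading types and joint mass ≥ 0.25 → E
(influx dilutes the B-like dominance well below one half); all 15
sustained with T15 maximal → C; the nine survivors with T15 maximal → A;
{1,2,4,8} (± trace partners) with a {2,4} cluster above one half → B,
with an equalised {1,2,4,8} cluster → X.  Anything else is reported
`unclassified` rather than forced.

Perturbation experiments run three phases (establish, perturb, revert),
classify each phase's trailing-window mean, and mark a transition
reversible when the reverted phase re-establishes the original label.
The information rule — a transition that loses production-threshold bits
is irreversible unless the reverted environment has Φ > 0 — is checked on
every record.

## Scaled study conditions

All spatial experiments in the tests and the acceptance script use
n = 100 (N = 10⁴), with step budgets scaled by N from the full-size
protocol (N = 9 × 10⁴, up to 10⁷ steps): the dynamics are per-site local,
so time measured in replacements per site is the invariant quantity.  The
scaled well-mixed setting is c = 1000, v = 25 (each site is swapped ~0.1
times per production step, ample to keep the population near mean-field);
steady state on the frozen lattice is declared when every type's frequency
range over a trailing 5 × 10⁴-step window falls below 0.005.  Under
mixing, demographic noise at N = 10⁴ exceeds that tolerance, so mixed
phases run to their step budgets instead — budgets sized at 1.5–3 × 10⁵
steps, several times the observed relaxation time.  Perturbation phase
budgets (1.5 × 10⁵ / 6–8 × 10⁵ / 3 × 10⁵) correspond to the full-size
protocol's phase lengths under the same scaling.

What the scaled runs show — and what they do not: niche selection,
extinction order, steady-state composition and transition directions
reproduce at N = 10⁴ with frequencies within ~0.02 of the mean-field
values; absolute extinction times and trace-type lifetimes are *not*
scale-invariant (smaller absolute subpopulations die sooner), so
quantities tied to rare-type persistence are read qualitatively, not
numerically.

## Known limitations

* The mean-field fixed point of the full population has C_μ = 5.7495
  bits; measurements quoted at one decimal (5.8) from finite simulations
  sit just outside a ±0.05 band around it.
* The candidate strongly connected count (see above) does not reproduce
  the historical 129.
* Secondary niche X is not compositionally closed — (5,3) composes to
  T15 — so X is a long-lived spatial state rather than a mean-field
  attractor; the classifier keys on its equalised {1,2,4,8} cluster.
* The transitionless machine T0 is modelled only as a failed composition;
  channel semantics (the 50% output branching of e.g. T3) never affect
  the composed type and are not simulated.
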