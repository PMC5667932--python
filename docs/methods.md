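# Methods

## The model

`commitnet` treats the six commitment-associated phosphatases (DUSP6,
PPTC7, PTPN1, PTPN13, PPP3CA, DUSP10) as a Boolean gene network updated
synchronously: every gene reads the same input state and all genes update
together, one step per hour of the suspension time course. A *concrete
network* is a set of signed directed interactions plus one regulation rule
per gene. The default rule is activator-disjunctive and
inhibitor-dominant:

- a gene is ON at the next step iff at least one activator is ON and no
  inhibitor is ON;
- a gene with no incoming activating interaction holds its current value
  unless an inhibitor is ON.

Two further rules ship in the catalogue (`all_activators`,
`activator_override`); all rules are machine-checked to be monotone
non-decreasing in activator activity and non-increasing in inhibitor
activity, exhaustively over the 2^4 regulator-predicate combinations and
both current values. The searchable catalogue is off by default: a single
documented rule keeps witnesses reproducible, and alternative update
semantics can be opted into per gene (`rule_choices` on an ABN).

An *Abstract Boolean Network* (ABN) splits interactions into *definite*
(always present) and *possible* (present or absent). A (source, target)
pair listed with both signs is an exclusive three-way choice
(absent/activating/inhibiting) — a pair cannot be simultaneously
activating and inhibiting — while a single-signed possibility is an
independent two-way choice. The model count is therefore a closed-form
product; with every ordered pair over six genes (including self-loops)
carrying an exclusive choice it is 3^36 ≈ 1.5 x 10^17, which is the
magnitude the acceptance script reports.

## Constraints and solving

Expression is discretised per sample: a gene is ON iff its replicate-mean
expression strictly exceeds the average over the genes in the same sample
(ties are "similar", hence OFF). The averaging set defaults to the six
network genes in the sample — the only expression set the Boolean analysis
consumes — and can be replaced by an externally supplied per-time
reference; averaging is on the linear scale by default (log2 optional).
Discretised states at 0/4/8/12 hr become partial observations at steps
0/4/8/12 of a 12-step trajectory constraint. Constraints may also pin the
index of the representative network at given steps and may carry a
mandatory-switch flag.

Consistency of an ABN with a constraint is decided by complete explicit
search: enumerate concrete networks in deterministic lexicographic order
(bounded by an enumeration limit, default 2^20), enumerate completions of
the partial step-0 observation, simulate, and prune on the first violated
observation. No SMT solver is involved; the point of the explicit search
is that it is directly checkable against a naive enumerate-and-simulate
oracle, which the test suite does on hundreds of random instances. Every
SAT answer carries a witness (network, initial state, trajectory) that is
independently replayed by `commitnet.io.verify_witness`; UNSAT means no
concrete network and no completion of the partial observations admits a
satisfying trajectory.

A possible interaction is classified *required* if forcing it absent makes
the instance UNSAT (it is present in every consistent solution, so it can
be promoted to definite), *disallowed* if forcing it present does, and
*optional* otherwise. Classification is only defined on SAT instances;
promoting required interactions and deleting disallowed ones provably
preserves the solution set, which the suite asserts on random instances.

Switching problems place an ordered tuple of stage ABNs (N0, N4, N8, N12)
behind one constraint. Switching is monotonic — the system may stay or
move forward, never back — and one concrete network is chosen per stage
and reused across its whole span. Schedules are monotone step-to-stage
maps enumerated explicitly (for 12 steps over 4 stages, a few hundred),
combined with per-stage concrete choices and initial completions.
`classify_switch_paths` reports which deduplicated stage sequences admit
any solution; `is_pattern_compatible` asks whether a (partial) expression
pattern is reachable at a given horizon under any concrete network of one
stage ABN, from any initial state.

## Statistical inference of mechanistic networks

Knockdown tables are analysed per target gene on the log2 scale. The
design is a two-way layout (perturbation x time with interaction); the
residual variance is computed as the pooled within-cell variance, which is
identical to the residual mean square of the corresponding OLS interaction
model (asserted against `statsmodels` in the suite, and far cheaper inside
Monte-Carlo loops). Each knockdown-vs-control contrast at each time uses
that pooled variance and its residual degrees of freedom. Per target
gene, all knockdown x time contrasts form one comparison family adjusted
by Holm-Sidak step-down (`statsmodels.stats.multitest.multipletests`); the
closed-form step-down formula serves as an independent oracle in the
tests. Self-knockdowns are excluded: silencing a gene trivially lowers
that gene, so self-edges are not inferable from knockdown data and enter
the analysis only as possible ABN interactions.

Edges are called at adjusted p < alpha (default 0.05), signed by
fold-change direction (negative log2 fold-change under knockdown =
activating), weighted 1/p. With zero residual variance (noise-free
simulated data) a non-zero contrast is assigned the smallest positive
float and a zero contrast p = 1, which makes noise-free recovery exact; a
significant contrast with exactly zero fold-change has no defined sign and
raises an error rather than guessing. Node colours of the inferred
networks are mean log2 fold-changes of the control series versus 0 hr.

## The synthetic-data generator

The generator emulates the study design — knockdown RT-qPCR time courses
relative to a housekeeping reference with 3 independent replicates — from
a known ground truth. Silencing gene *i* multiplies *i*'s expression by
the knockdown efficiency (default 0.2, i.e. 80% knockdown) and shifts each
direct target *j* of edge *i -> j* (sign *s*, strength beta in log2 units)
by `-s * beta`. Propagation is deliberately one-step (direct targets
only): the inference stage calls direct knockdown-to-gene effects, so a
transitive simulation would make the ground truth of a recovery benchmark
ambiguous. Overexpression is the sign-flipped knockdown shift. Noise is
Gaussian on the log2 scale (sd default 0.2); the underlying study does not
report its measurement noise magnitude, so the default is a conventional
qPCR-scale choice, recorded in `RunConfig` and held fixed across all
benchmarks. Drug profiles add a specified per-gene log2 shift to the
control baseline.

The default ground truth is a fixed 8-edge signed network (no self-edges,
one sign per pair, beta = 1) active at all four time points, with baseline
profiles sketching the qualitative kinetics (pro-commitment phosphatases
peak at 4 hr and decline; DUSP10 rises late). Under these conditions a
single contrast has effect 1 log2 unit against sd 0.2 with n = 3 — large
but comparable to a clean qPCR knockdown effect — and the recovery
benchmark (precision/recall of signed (edge, time) calls) lands above 0.9
without being saturated at the family-wise threshold.

SILAC tables draw each site independently: with probability
`frac_confounded` a site is *confounded* (|phospho change| <= 0.1 with
total-protein change > +0.5 log2, the case the exclusion rule must
remove); otherwise it is a changed site with |d_phospho| = 0.3 +
|N(0, effect_sd)| — safely outside the constant band — negative with
probability `frac_dephospho` (default 2/3) and a small uncorrelated total
change. The generated `confounded` flag is ground truth for benchmarking
only; the analysis functions never read it.

What the generator does *not* emulate: microarray/MS measurement pipelines
and their normalisation artefacts, transitive regulatory effects,
correlated replicate structure, batch effects, and protein-level dynamics
beyond a single per-site ratio pair. Passing recovery benchmarks
therefore demonstrate correctness of the statistics and solvers under the
stated generative model, not robustness to those real-data complications.

## The shipped commitment model

The study's exact discretised observation vectors and stage networks are
not distributed here, so `commitnet.commitment` ships a *synthetic*
six-gene, four-stage model constructed to reproduce the qualitative
reasoning chain with exhaustively checkable sizes. Each stage is a relay
motif under the default rule: the active marker gene (DUSP10 -> DUSP6 ->
PPTC7 -> PPP3CA) hands activity to the next stage's marker and is then
silenced. The model satisfies, with machine-verified witnesses:

- no stage ABN alone, and no single concrete network drawn from the
  pooled ABN of all stage interactions (3 x 2^12 = 12,288 networks),
  satisfies the untreated 0/4/8/12 hr states — the time course forces a
  topology change;
- monotonic switching N0 -> N4 -> N8 -> N12 satisfies it; the untreated
  constraint carries a mandatory switch;
- within N4, the stem-to-commitment activation is classified *required*
  (and its inhibiting alternative *disallowed*) — the commitment marker
  has no other route on;
- the PKCi 12 hr pattern (stem state) is reachable without leaving N0;
- the TSA pattern requires leaving N0 and admits exactly the visited
  paths N0->N4->N8 and N0->N8;
- neither drug pattern is compatible with N12 at any reachable horizon
  state.

## Numerical and design choices

- Deterministic everything: enumeration orders are lexicographic, schedule
  enumeration is by non-decreasing switch times, and all generators take
  explicit seeds, so witnesses and tables are bit-reproducible.
- Enumeration limits (default 2^20 concrete networks) cause an explicit
  refusal rather than an open-ended search; the 10^17-model family is
  counted in closed form, never enumerated.
- p-values are clamped to the smallest positive float so inverse-p weights
  stay finite; adjusted p-values are clipped to (0, 1].
- The constant band of the phospho exclusion rule defaults to
  |d_phospho| <= 0.2 ("remained constant" is not quantified by the
  ranking's definition, so the band is configurable); the total-protein
  threshold is +0.5 log2. Ranking ties are broken by site id so output is
  independent of input row order.
- Monte-Carlo problem sizes in the test suite and acceptance script
  (50/25 recovery seeds, 200/100 null simulations, 3000 SILAC sites,
  200 + 100 random solver instances) were chosen to keep sampling error
  well inside the asserted margins while the full run stays in the
  tens-of-seconds range on a laptop.

## Known limitations

- The solvers are explicit-search decision procedures intended for
  constrained stage ABNs of desk scale (up to ~10^6 concrete networks);
  they are not a replacement for SMT-based synthesis on unconstrained
  families.
- The ANOVA assumes homoscedastic log2 expression across cells; grossly
  unequal variances would distort the pooled contrasts.
- Discretisation against the within-sample six-gene average is one
  reading of "average of all genes"; a genome-wide reference can be
  supplied externally but is not computed here.
- The commitment model is a constructed stand-in: its SAT/UNSAT pattern
  matches the qualitative biology, but its specific interactions are not
  inferred from data.
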