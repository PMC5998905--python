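# Methods

## Scope and data model

`fluxshift` starts from three inputs: a stoichiometric network (SBML
L3 + FBC via cobrapy, or a plain TSV dialect), a gene × sample FPKM
table, and a sample manifest giving the tissue order and stage labels.
Upstream steps (read QC, alignment, transcript assembly) are out of
scope; when raw quantities are available, `compute_fpkm` converts
fragment counts to FPKM as fragments / (mapped reads in millions × exon
length in kb).

The network container enforces referential integrity only: unique ids,
every stoichiometry entry resolving to a known metabolite, lb ≤ ub.
Reactions missing explicit bounds default to [−1000, 1000] if written
with a reversible arrow and [0, 1000] otherwise; negative flux means the
reverse direction. Exchange (boundary) reactions are detected as
single-metabolite rows or by the `EX_` id prefix. No mass/charge
balancing or gap analysis is attempted.

## Discretization

Each sample is discretized independently: per-sample quantiles make the
states comparable across libraries of different depth, and any strictly
monotone transform of a sample's values leaves the states unchanged
(the rule is rank-based). With n genes and quantile fractions
`low_q = high_q = 0.15`, the cutoffs are the k-th order statistics with
k = ⌈0.15·n⌉. The high class is therefore exactly the top k values when
values are distinct. Ties at a cutoff join the extreme class only when
the tie block is itself no larger than k; a value shared by more than
the nominal fraction of genes (typically a large block of zeros) stays
moderate, and a value claimed by both extremes (constant or near-
constant samples) is moderate. This makes the rule total and
deterministic with no random tie-breaking, at the cost of extreme
classes that can undershoot their nominal fraction on heavily tied data.

Gene states map to reaction states through GPR rules with AND = min and
OR = max over {−1, 0, +1} — a complex is only as expressed as its
least-expressed subunit; one high isozyme suffices. Genes present in the
model but absent from the table evaluate as 0, so missing evidence never
asserts activity. Empty GPRs (exchanges, spontaneous reactions) give 0.

## iMAT

For reaction states s_r, let R_H = {r : s_r = +1} and R_L = {r : s_r =
−1}. The MILP maximizes the number of expression-consistent reactions
over steady-state fluxes:

- continuous v with S·v = 0 and lb ≤ v ≤ ub;
- for r ∈ R_H, binary y⁺_r with the implication y⁺_r = 1 ⇒ v_r ≥ ε,
  linearized as v_r + y⁺_r(lb_r − ε) ≥ lb_r; reversible reactions also
  get y⁻_r with v_r + y⁻_r(ub_r + ε) ≤ ub_r and y⁺_r + y⁻_r ≤ 1;
- for r ∈ R_L, binary y_r forcing v_r = 0 when y_r = 1 (bound-shifted
  big-M on both sides);
- objective: maximize Σ_{R_H}(y⁺ + y⁻) + Σ_{R_L} y.

ε (default 1.0, flux units) is the activation threshold separating "the
reaction carries flux" from numerical noise; it is configurable and
should sit well below the R_H reactions' capacity (a warning fires
otherwise). The solver is HiGHS through `scipy.optimize.milp`, with a
60 s default time limit per sample (desk-scale instances solve in
milliseconds; the status is surfaced if the limit is hit).

**Alternate optima.** MILP solvers may return any vertex of the optimal
face, which would make flux heatmaps and downstream statistics
irreproducible. The integer assignment is therefore fixed and a second
LP minimizes Σ|v_r| (split-variable formulation) subject to the chosen
activations (v_r ≥ ε forward, v_r ≤ −ε backward, v_r = 0 for satisfied
lows). HiGHS is deterministic, so identical inputs give byte-identical
outputs. A consequence worth knowing: canonical fluxes of activated
pathways sit at ε rather than at capacity, i.e. the reported
distribution is the *most parsimonious* optimal one.

The tissue-specific model keeps reactions with |v_r| > `activity_tol`
(default 1e−6) — a numerical-zero threshold deliberately distinct from
ε. This is one canonicalized optimum, not the union of all optima;
reactions active only in alternative optima are not included.

## FVA, rate limiting, flux comparisons

FVA solves the 2|R| LPs min/max v_r over S·v = 0 and bounds, with no
biomass constraint (the integration workflow defines no objective).
Results are clipped into the bounds and rounded to 9 decimals so
repeated runs serialize identically. By default FVA runs on the generic
(full) network; a `union` scope pins reactions inactive in every tissue
model to zero first. A per-tissue scope is deliberately not offered: the
flux-change ratio divides both tissues' fluxes by the same variability
range, which requires a scope shared by the compared pair.

Between two tissues, ratio = (|flux2| − |flux1|) / (maxflux − minflux);
|·| because reversible fluxes are signed and a plain fold change is
meaningless for them. Calls: ratio > 0.5 up, < −0.5 down. A degenerate
range (maxflux = minflux) yields call `undefined` with NaN ratio —
a value, never an exception. Reactions absent from a tissue model enter
all comparisons and series with flux 0.

Total variation of an ordered series f_1…f_k is Σ_{i=2..k} |f_i −
f_{i−1}| (k values, k − 1 consecutive differences; an implicit f_0 = 0
was rejected because it would make TV depend on the first tissue's
absolute flux rather than on fluctuation). The series order comes from
the manifest; TV is order-dependent, and reversal-invariant. Rate-
limiting reactions are those with v_r ≥ ub_r − tol under the generic
bounds (forward saturation; reverse saturation at a negative lb is
available behind a flag). Reactions with ub ≤ tol are skipped — zero
flux trivially "attains" a zero bound without any saturation meaning.
"Significantly active" reactions, used for per-tissue activity
enrichment, are interpreted as the top 25% of |v| among a tissue's
flux-carrying reactions (configurable quantile) since no canonical
threshold exists for the phrase.

Hierarchical clustering of the flux matrix uses Euclidean distance and
average linkage by default (both configurable and recorded in the output
header); equal-distance merges follow the input label order via scipy's
stable observation ordering. Trees are exported as Newick plus a
merge-height table.

## Enrichment

Pathway enrichment uses the hypergeometric upper tail P(X ≥ k) with
population N (universe), K pathway members, n selected, k overlap,
computed via the survival function (numerically stable; verified against
exact combinatorial sums to 1e−12 for N ≤ 60). The gene universe is the
model genes present in the expression table; the reaction universe is
all network reactions; both are overridable. Items with several pathway
labels count once per pathway. Benjamini–Hochberg adjusted p-values are
reported alongside raw ones; the default significance call uses raw
p < 0.05, with `--adjust`/`--alpha` switches. Up and down selections of
a compared pair are tested against the same universe.

## Synthetic scenarios

The generator emulates a multi-tissue expression-to-flux study on a toy
network: parallel chains (`EX_in → M_1 → … → M_L → EX_out`), one
subsystem label per chain, cross-links at branch points, GPRs cycling
through single-gene / AND-pair / OR-pair forms with private genes per
reaction. Chain-internal reactions carry the standard ±1000 (reversible,
drawn with probability `reversible_fraction`) or [0, 1000] bounds.
Exchanges carry a small capacity (default 1.5 flux units) and links are
irreversible low-capacity shunts (0.2): the capacity — not the nominal
internal bound — sets each reaction's FVA range, and keeping it within a
small factor of ε reproduces the regime of real tissue-model studies
where simulated fluxes are a large fraction of their variability range.
With wide-open boundaries the ratio statistic would be ≈ ε/2000 for
every reaction and no up/down call could ever fire.

Expression planting drives the genes of "on" pathways into a high
stratum (uniform 100–200 FPKM), "off" pathways into a low stratum
(0.1–1), everything else into a middle stratum (10–20). Filler genes
(ids `bg###`, absent from the model, carried but ignored downstream) pad
each sample's extreme classes to exactly k = ⌈0.15·n⌉, and the strata
gaps guarantee the quantile cutoffs fall between strata — so at zero
noise the discretization inverts the planting exactly, with no tolerance
fudging. Truncated Gaussian noise (at 0) can be added; recovery then
degrades gracefully. Every emitted scenario is checked at generation
time for realizability: an LP verifies a steady-state flux with
|v| ≥ ε on all planted-active reactions and v = 0 on all planted-
inactive ones, per sample.

The standard scenario (`make_scenario`) uses 4 samples over two stages,
6 chains, 5 cross-links, 25% reversible internals and zero noise:
pathway 1 always on, pathway 2 always off, pathways 3/4 toggled
oppositely across the stage boundary, the rest background — roughly 40
reactions and 50 model genes, large enough for branching and GPR variety
and small enough for the brute-force MILP cross-check to enumerate.

**What passing on synthetic data does and does not show.** The generator
exercises every code path (reversibility, GPR forms, ties, toggled and
constitutive pathways) with exactly known truth, but its expression
values are stratified rather than continuous, its pathways are almost
decoupled, and its topology has none of the cofactor coupling,
compartments, or shared enzymes of a genome-scale model. Recovery rates
of 100% on it validate correctness of the machinery, not expected
accuracy on real tissue data.

## Validation oracles

Two reference implementations live in `fluxshift.reference`,
deliberately independent of the production code paths: the iMAT optimum
by exhaustive enumeration of satisfied-flag subsets with plain LP
feasibility checks, and the hypergeometric tail by exact
binomial-coefficient sums. The test suite compares the MILP against the
enumeration on 1000 random networks of ≤ 12 reactions with 2–6 flagged
reactions (flag counts kept modest so the enumeration itself stays
fast), and `scripts/acceptance.py` re-runs a 300-instance sweep plus the
full planted-scenario pipeline at whatever seed it is given.

## Numerical choices and limitations

- Steady-state residuals ‖S·v‖∞ and bound violations are held to 1e−6;
  emitted fluxes and FVA ranges are rounded to 9 decimals (also
  normalizing −0.0) for stable serialization.
- Ranking ties (equal TV) break lexicographically by reaction id;
  enrichment ties (equal p) by pathway label.
- The pipeline's `config_hash` covers analysis parameters only (not the
  output directory or log level), so reruns into different directories
  still produce identical statistics files.
- Known limitations: no loopless FVA or thermodynamic refinement; one
  canonical optimum rather than optimum-space scanning; no INIT / GIMME /
  E-Flux variants; flat pathway labels (no ontology propagation);
  enrichment assumes a well-defined universe and independence across
  pathways.
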