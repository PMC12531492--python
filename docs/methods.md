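# Methods

## Scope and model class

`adaptuc` works on stoichiometric (constraint-based) metabolic models:
a matrix `S` (metabolites × reactions), flux bounds `LB ≤ v ≤ UB`, and
a biomass reaction whose flux is the growth rate (1/h).  All phenotype
predictions are flux balance analysis (FBA) — linear programs over
`S·v = 0` — so the usual FBA assumptions apply: steady state, no
kinetics or regulation, growth-optimal behaviour.  Knockouts are
reaction-level (`LB = UB = 0`); gene names appearing in published
strategy labels are treated as aliases of their reactions, and
gene–protein–reaction logic is out of scope.

Exchange fluxes follow the standard sign convention: negative flux is
uptake, and a substrate "open at 10 mmol/gDW/h" means the exchange
lower bound is −10.  All reported uptake rates are magnitudes.

## The design program

Given an unadapted carbon source (UC) exchange, a cosubstrate exchange,
a variant (A or B) and a knockout budget K, a design `y ∈ {0,1}ⁿ`
(y=1 ⇒ deleted) must satisfy three requirements, each defined through
an inner FBA problem on the knockout strain:

| inner problem | medium | outer condition |
|---|---|---|
| 1: max growth | UC only (−10) | A: ≤ 0.1·v0_uc;  B: ≥ 0.5·v0_uc |
| 2: max growth | cosubstrate only (−10) | ≤ 0.1·v0_cosub |
| 3: max growth | both (−10 each) | ≥ v0_cosub |
| 4: min UC uptake s.t. growth ≥ v0_cosub | cosubstrate −10, UC −1000 | value = vUC |

v0_uc and v0_cosub are the pre-deletion maxima on each substrate alone.
The UC bound is deliberately looser (−1000) in problem 4: it asks how
much UC the strain *must* consume when supply is not limiting.  The
objective is the substrate assimilation driving force

    SADF = (v0_cosub − v2bio) / vUC      [gDW/mmol],

the growth regained per unit UC uptake.  The second evaluation metric,
UC/Co, is computed by two sequential LPs: minimise UC uptake subject to
growth ≥ 0.1 h⁻¹, then fix that uptake and minimise the cosubstrate
uptake; the ratio of the two minima measures how parsimoniously the
starting strain can use the new substrate.  When the second minimum is
zero the ratio is reported as an infinite-coupling sentinel rather than
a number.

The requirement fractions (0.5, 0.1, 0.1), uptake bounds (10, 1000) and
the 0.1 h⁻¹ UC/Co growth floor are configurable `DesignConfig` fields
with those defaults.

## Single-level reformulation

The outer maximisation over `y` with inner optima is collapsed into one
MILP.  The certificate used for each inner problem is the weakest
sufficient one, which keeps the bilinear-term count low:

* *"inner max ≥ b"* (variant-B requirement 1, requirement 3): a primal
  witness — one feasible flux vector reaching `b` — proves the maximum
  does too.  Knockout bounds `LB(1−y) ≤ v ≤ UB(1−y)` are linear in `y`.
* *"inner max ≤ b"* (variant-A requirement 1): a dual-feasible point of
  the inner LP whose objective is ≤ b bounds the maximum by weak
  duality.  The dual objective contains products `(1−y)·α` of binaries
  with dual variables, linearised with big-M envelopes (`α ≤ M_dual`).
* *values entering the objective* (`v2bio`, `vUC`): full strong duality
  — primal witness, dual-feasible point, and primal objective ≥ dual
  objective — pins the variable to the true inner optimum.  Without
  this, the outer problem could understate `v2bio` (faking requirement
  2 and inflating SADF); `vUC` additionally gets pushed to its true
  minimum by the objective itself, so its dual block is a safety net
  for feasible-but-suboptimal incumbents.

The fractional objective is linearised by the Charnes–Cooper
substitution `t = 1/vUC`: blocks 2 and 4 are scaled (`w = t·v`, duals
likewise), the normalisation `vUC·t = 1` becomes a linear row, and the
objective `v0_cosub·t − c·w2` *equals* the SADF.  Products `t·y` are
linearised exactly via the bounds `t ∈ [1/1000, 1/ε_uc]` (ε_uc = 1e−4,
the smallest representable minimal uptake); products of scaled duals
with binaries reuse the big-M envelope with cap `M_dual·t_max`.

Numerical choices: `M_dual = 1000` (configurable); MIP relative gap
1e−4; LP feasibility left at HiGHS defaults; reported-equality
comparisons use 1e−6 absolute.  After every solve, any dual or product
variable that lands within 0.1% of its big-M cap flags the incumbent
and triggers a rebuild with a tenfold larger constant (twice at most).
Degenerate optima: objective values are the contract; when a flux
*distribution* is reported, a parsimonious (total-flux-minimising)
secondary LP makes it reproducible, and the output is flagged as such.

Every MILP incumbent is post-verified by direct FBA (requirements
re-checked, SADF re-scored); a solution is only marked `verified` when
the re-scored SADF agrees with the MILP objective to 1e−3 relative.
The evaluation layer never reads values off MILP certificates, so
scores are independent of the reformulation.

## Enumeration and the integer cut

Alternative designs are found by re-solving after adding an integer cut
over the last solution's knockout set S.  The default cut is the
standard no-good form `Σ_{j∈S} yⱼ ≤ |S| − 1`, which excludes S and all
of its supersets.  A stricter variant (`strict_cut=True`) uses
`≤ |S| − 2`, additionally excluding every set that keeps all but one
member of S — but it makes any singleton solution terminal (the cut
becomes unsatisfiable), so the superset-excluding form is the default;
enumeration order admits near-optimal alternatives, and objectives are
not guaranteed monotone.

A fallback workflow (`enumerate_then_score`) drops the ratio objective
entirely: a feasibility MILP (requirements + budget, minimising the
knockout count) is enumerated with the same cuts and each set is scored
exactly by LP.  It agrees with direct ratio optimisation on the whole
toy family and is the recommended mode when fractional-objective
numerics are suspect at genome scale.

Minimal support: MILP optima may include deletions that do not affect
the score (the objective is indifferent to them).  Solutions are
greedily reduced — a knockout is dropped when removing it changes
neither feasibility nor SADF (1e−6 relative) — before cutting and
reporting.

## Candidate prefiltering

Genome-scale models have thousands of reactions; the MILP receives a
reduced candidate list assembled by ordered, fully-traced filters:
exchanges and biomass; the two substrates' exchange/transport steps
(transporters are recognised as non-exchange reactions moving the
substrate's species between compartments, matched by base id across
compartment suffixes — a heuristic that is exact for BiGG-style
naming); gene-unassociated reactions; blocked reactions (flux
variability (0,0) with both substrates open — such reactions can carry
no flux in any inner problem); a user-supplied peripheral-pathway
exclusion list (empty by default; the published candidate counts depend
on an unenumerated external list, so no attempt is made to reproduce
them exactly); and, optionally, reactions whose single deletion already
destroys growth recovery (sound because growth is monotone
non-increasing under additional knockouts).

## Model preparation

The ribulose-monophosphate methanol pathway is grafted as three
reactions — methanol dehydrogenase (NAD-dependent by default; the
cofactor is configurable because sources differ), hexulose-6-phosphate
synthase, 6-phospho-3-hexuloisomerase — plus a methanol exchange and
transport step when absent.  The *E. coli* profile deactivates the
anaerobic formate lyases (PFL, OBTFL) and two reactions reported
unrealistic (DRPA, PAI2T); the *C. glutamicum* profile adds a xylose
transporter.  Both profiles close the CO2/bicarbonate-*consuming
direction* of carbon-fixation reactions outside a whitelist (PEP
carboxylase, carbamate kinase, isocitrate dehydrogenase,
carbamoyl-phosphate synthase, pyruvate carboxylase, acetyl-CoA
carboxylase, methylmalonate-semialdehyde dehydrogenase); only the
fixing direction is blocked so ordinary decarboxylations keep running.
Missing targets are logged, never fatal, since reaction inventories
drift between model versions.

Media: `set_medium` opens the listed carbon exchanges at the given
uptake and closes every other *carbon* exchange, leaving non-carbon
components (oxygen, ions) at the source model's defaults.  Carbon
exchanges are recognised by formula annotation; without formulas an
exchange is conservatively treated as carbon unless listed in the
model's `base_medium` annotation.

## Producibility and coupling classes

For each substrate-side metabolite of the biomass reaction, a demand
sink is added on the cosubstrate-only medium and maximised; the
precursor is producible when the demand flux exceeds 1e−4 (guarding
against numerically trivial leak fluxes).  Mass fractions are
`|coefficient| × molar mass / Σ`, with molar masses computed from
formula annotations; when any formula is missing or unparseable
(polymer placeholders), fractions fall back to a coefficient basis with
a warning.  The coupling fraction is the summed mass fraction of
non-producible precursors.  Classes: *full* when no precursor is
producible, *minimal* when the coupling fraction is ≤ 10% — the
boundary was chosen so that the canonical minimal-coupling exemplar
(a 5.48 wt% cell-wall precursor group) and the full-coupling exemplar
(ribose-5-phosphate-isomerase deletion on xylose) land in their named
classes — otherwise *intermediate*.

## The toy family and what it shows

The synthetic test bed is a four-metabolite network: cosubstrate A and
UC M enter by exchange; `rP: A→P` makes the bulk precursor; `rQ1: A→Q`
is the designable cosubstrate-only route to the coupled precursor;
`rQ2: A+M→2Q` mimics the 1:1 formaldehyde/ribulose-5-phosphate
condensation; biomass consumes `(1−φ)P + φQ`.  With unit
uptake-to-growth yield, deleting the cosubstrate-only route(s) gives
exact answers: `v2bio = 0`, `vUC(g) = φ·g/2`, hence `SADF = 2/φ` and
`UC/Co = φ/(2−φ)` — and the monotonicity of both metrics in φ is the
desk-scale embodiment of the coupling principle.  Optional features: a
UC-only route (M→P, M→Q) making variant B non-trivial; an inefficient
leak route `c_leak·A→Q` (default cost 2) that violates requirement 2
until co-deleted, which the generator verifies analytically at build
time; and seeded dead-end decoy reactions (some gene-less) that enlarge
the candidate set without changing any answer.

What passing the toy suite does **not** show: toys have no cofactor or
redox coupling, no maintenance ATP, no compartments, unit yields and a
single coupled precursor, so they exercise the *logic* of the
formulation (certificates, budget, cuts, scaling) and the exactness of
the metrics, not the biological fidelity of genome-scale predictions.
Genome-scale behaviour (degenerate optima, medium sensitivity, MEDH
cofactor choice) is probed by the reproduction scripts, which require
the published iML1515/iCW773 models as inputs.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
toys: the closed-form grid φ ∈ {1, 0.5, 0.25, 0.1, 0.05}; an
oracle-equivalence family of 24+ seeded toys (≤ 12 candidate reactions,
budgets ≤ 3, exhaustive enumeration as the independent oracle); and the
two-alternative enumeration network.  These sizes keep exhaustive
enumeration exact and the whole suite in the tens of seconds on one
CPU while covering both variants, leak routes and decoys.

## Known limitations

Reaction-level deletions only (no GPR mapping); two model dialects
(SBML-L3/FBC, BiGG JSON); no thermodynamic or enzyme-capacity
constraints, so flux directions that are thermodynamically implausible
are only excluded where the preprocessing profiles do so explicitly;
published flux-fraction narratives at degenerate optima are treated as
descriptive, not contractual; big-M certificates can in principle
reject a valid design if true dual magnitudes exceed the escalated
caps — the post-verification layer makes such failures visible rather
than silent.
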