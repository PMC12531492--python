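# adaptuc

Reaction-knockout design for microbes that must learn to eat a new
carbon source.

Industrial hosts such as *Escherichia coli* and *Corynebacterium
glutamicum* cannot grow on substrates like methanol even after the
missing assimilation pathway has been installed; adaptive laboratory
evolution (ALE) with a familiar cosubstrate is the standard route to a
working strain.  The success of that campaign hinges on the *starting*
strain: its metabolism must be rewired so that growth depends on the
new, "unadapted" carbon source (UC), creating selective pressure to use
it.  `adaptuc` finds such rewirings in genome-scale metabolic models
and quantifies how strong the resulting pressure is.

## The design problem

A knockout set `y` (budget `Σ yⱼ ≤ K`) must satisfy three requirements,
each an FBA problem on the knockout strain:

1. **UC-only growth** — variant **A**: `v1ᵇⁱᵒ ≤ 0.1·v0ᵇⁱᵒ_uc` (no
   growth on the UC alone); variant **B**: `v1ᵇⁱᵒ ≥ 0.5·v0ᵇⁱᵒ_uc`
   (robust growth preserved);
2. **dependence** — `v2ᵇⁱᵒ ≤ 0.1·v0ᵇⁱᵒ_cosub`: on the cosubstrate
   alone the strain barely grows;
3. **recovery** — `v3ᵇⁱᵒ ≥ v0ᵇⁱᵒ_cosub`: with both substrates the
   pre-deletion growth rate is restored.

Here `v0ᵇⁱᵒ_uc`, `v0ᵇⁱᵒ_cosub` are the reference (pre-deletion) growth
rates on each substrate alone.  Designs are ranked by two metrics:

* **SADF** (substrate assimilation driving force, gDW/mmol):
  `(v0ᵇⁱᵒ_cosub − v2ᵇⁱᵒ) / vUC`, the growth regained per unit UC
  uptake, where `vUC` is the minimal UC uptake restoring the reference
  growth — the selective pressure toward UC assimilation;
* **UC/Co**: the parsimonious ratio of minimal UC uptake to minimal
  cosubstrate uptake at a 0.1 h⁻¹ growth floor — how little of the new
  substrate the starting strain needs to survive.

The bilevel search (outer knockouts, inner FBA optima) is collapsed
into a single mixed-integer linear program using LP duality
certificates — weak duality bounds an inner maximum from above, a
primal witness from below, and strong duality pins the values
(`v2ᵇⁱᵒ`, `vUC`) that enter the objective — with the fractional SADF
objective linearised by a Charnes–Cooper substitution `t = 1/vUC`.
Alternative designs are enumerated with integer cuts, and every
incumbent is re-verified by plain FBA before being reported.  The key
scientific finding the scores expose: the *smaller* the mass fraction
of biomass precursors forced to come from the UC, the *higher* the
driving force and the *lower* the substrate requirement.

## Worked example

A parametric toy network with known answers ships with the package:
with UC-coupled biomass fraction φ, the best single deletion has
SADF = 2/φ and UC/Co = φ/(2−φ) exactly.

```sh
adaptuc make-toy --phi 0.1 --out toy.json
cat > run.yaml <<EOF
model: toy.json
uc_exchange: EX_M
cosub_exchange: EX_A
variant: A
max_knockouts: 2
outdir: out
EOF
adaptuc design run.yaml
cat out/solutions.tsv
```

prints

```
knockouts	sadf	ucco	coupling_class	status	verified
rQ1	20	0.0526316	minimal	optimal	True
```

deleting `rQ1` (the cosubstrate-only route to the coupled precursor)
leaves 10% of biomass dependent on the UC: SADF = 2/0.1 = 20 gDW/mmol,
UC/Co = 0.1/1.9 ≈ 0.0526, and the producibility analysis classes the
design as *minimal coupling*.  `adaptuc evaluate`, `curve`,
`producibility` and `prefilter` score fixed knockout sets, trace
minimal-UC-uptake-vs-growth curves, test per-precursor producibility
and audit the candidate reduction.

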