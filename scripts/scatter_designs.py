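#!/usr/bin/env python
"""Enumerate knockout designs across many cosubstrates (SADF vs UC/Co scatter).

Generates the design landscape for one model and a list of cosubstrate
exchanges: for each cosubstrate the prefiltered candidate set is built
and up to ``--max-solutions`` designs are enumerated with the
feasibility MILP + exact LP scoring, then everything is written to one
TSV (cosubstrate, knockouts, SADF, UC/Co, coupling class) suitable for
plotting.  With a genome-scale model this is a long run; start with a
small ``--max-solutions``.

Usage:
    python scripts/scatter_designs.py --model iML1515.json --pathway rump \
        --preprocessing ecoli --uc EX_meoh_e \
        --cosubstrates EX_succ_e,EX_fru_e,EX_glc__D_e,EX_ac_e,EX_glu__L_e,EX_glyc_e,EX_glyc__R_e,EX_pyr_e,EX_xylu__L_e,EX_rib__D_e \
        --max-knockouts 5 --max-solutions 10 --out scatter.tsv
"""

from __future__ import annotations

import argparse
import sys

from adaptuc import (
    DesignConfig,
    add_pathway,
    apply_preprocessing,
    candidate_knockouts,
    enumerate_then_score,
    load_model,
    rump_pathway,
)


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--model", required=True)
    parser.add_argument("--dialect", default=None, choices=["bigg-json", "sbml-fbc"])
    parser.add_argument("--pathway", default=None, choices=[None, "rump"])
    parser.add_argument("--preprocessing", default="none",
                        choices=["none", "ecoli", "cglutamicum"])
    parser.add_argument("--uc", required=True, help="UC exchange id")
    parser.add_argument("--cosubstrates", required=True,
                        help="comma-separated cosubstrate exchange ids")
    parser.add_argument("--variant", default="A", choices=["A", "B"])
    parser.add_argument("--max-knockouts", type=int, default=5)
    parser.add_argument("--max-solutions", type=int, default=10)
    parser.add_argument("--time-limit", type=float, default=600.0,
                        help="MILP time limit per solve (s)")
    parser.add_argument("--out", default="scatter.tsv")
    args = parser.parse_args(argv)

    model = load_model(args.model, args.dialect)
    if args.pathway == "rump":
        model = add_pathway(model, rump_pathway())
    model = apply_preprocessing(model, args.preprocessing)
    print(f"model prepared: {len(model.reactions)} reactions")

    rows = []
    for cosub in args.cosubstrates.split(","):
        config = DesignConfig(uc_exchange=args.uc, cosub_exchange=cosub,
                              variant=args.variant,
                              max_knockouts=args.max_knockouts)
        trace = candidate_knockouts(model, config)
        print(f"{cosub}: {len(trace.final_candidates)} candidates")
        solutions = enumerate_then_score(model, config, trace.final_candidates,
                                         args.max_solutions,
                                         time_limit=args.time_limit)
        for sol in solutions:
            rows.append([cosub, ";".join(sorted(sol.knockouts)),
                         f"{sol.sadf:.6g}" if sol.sadf is not None else "undefined",
                         f"{sol.ucco:.6g}" if sol.ucco is not None else "undefined",
                         sol.verified])
        print(f"{cosub}: {len(solutions)} design(s)")
    with open(args.out, "w") as fh:
        fh.write("cosubstrate\tknockouts\tsadf\tucco\tverified\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    print(f"wrote {len(rows)} designs to {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
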