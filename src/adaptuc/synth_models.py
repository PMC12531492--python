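"""Parametric toy networks with closed-form answers, plus a brute-force oracle.

The toy family embodies the coupling principle on four metabolites:

* ``EX_A`` / ``EX_M`` — cosubstrate (A) and unadapted carbon source (M)
  exchanges;
* ``rP``:  A → P       (the bulk biomass precursor route);
* ``rQ1``: A → Q       (the deletion target: a cosubstrate-only route to Q);
* ``rQ2``: A + M → 2Q  (a condensation coupling Q synthesis to the UC in a
  1:1 molar ratio, mimicking formaldehyde + ribulose-5-phosphate);
* ``biomass``: (1−φ) P + φ Q → growth.

With unit uptake-to-growth yield the answer key is exact: wild-type
growth on A alone equals the uptake bound; after deleting the
cosubstrate-only route(s) to Q the strain cannot grow on A alone
(v2bio = 0), the minimal UC uptake at growth target g is φ·g/2, hence
SADF = 2/φ and UC/Co = φ/(2−φ).  Because molar masses are implicitly 1,
biomass mass fractions equal stoichiometric coefficients and the
coupling fraction of the designed strain is φ.

Optional features: a UC-only route (M → P, M → Q) so variant-B designs
are exercisable; an inefficient leak route (c_leak·A → Q) that makes
requirement 2 nontrivial (the leak must be co-deleted); and seeded
blocked/orphan decoy reactions that exercise the prefilter and enlarge
the candidate set without changing the oracle answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import metrics
from .config import DesignConfig
from .errors import SizeError
from .model_core import DEFAULT_BOUND, MetabolicModel, Reaction


@dataclass
class ToySpec:
    """Parameters of the toy family.

    ``phi`` is the UC-dependent biomass mass fraction, the single knob
    the closed forms depend on.  ``c_leak`` is the stoichiometric cost of
    the leak route (A per Q); any ``c_leak`` below ``(1/req2 − 1 + φ)/φ``
    leaves the leak efficient enough to violate requirement 2, which the
    generator asserts analytically at build time.
    """

    phi: float
    uptake_bound: float = 10.0
    include_uc_only_route: bool = False
    include_leak_route: bool = False
    c_leak: float = 2.0
    duplicate_rq1: bool = False
    series_rq1: bool = False
    decoys: int = 0
    seed: int = 0
    req2_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.phi <= 1):
            raise ValueError("phi must lie in (0, 1]")
        if self.c_leak <= 1:
            raise ValueError("c_leak must exceed 1 (the efficient-route cost)")
        if self.decoys < 0:
            raise ValueError("decoys must be >= 0")
        if self.duplicate_rq1 and self.series_rq1:
            raise ValueError("duplicate_rq1 and series_rq1 are mutually exclusive")


@dataclass
class ToyAnswerKey:
    """Analytically derived expectations for a generated toy."""

    expected_best_knockouts: set[str]
    expected_sadf: float
    expected_ucco: float
    expected_v0_cosub: float
    expected_coupling_fraction: float
    leak_violates_req2: bool = False
    alternative_best_knockouts: list[set[str]] = field(default_factory=list)


def default_config(spec: ToySpec, variant: str = "A", max_knockouts: int = 2) -> DesignConfig:
    """The design configuration matching a generated toy."""
    return DesignConfig(
        uc_exchange="EX_M",
        cosub_exchange="EX_A",
        variant=variant,
        max_knockouts=max_knockouts,
        uptake_bound=spec.uptake_bound,
        req2_fraction=spec.req2_fraction,
    )


def make_toy(spec: ToySpec) -> tuple[MetabolicModel, ToyAnswerKey]:
    """Generate a toy model and its closed-form answer key."""
    phi = spec.phi
    ub = DEFAULT_BOUND
    mets = ["A", "M", "P", "Q"]
    reactions = [
        Reaction("EX_A", {"A": -1.0}, lb=-spec.uptake_bound, ub=ub),
        Reaction("EX_M", {"M": -1.0}, lb=-spec.uptake_bound, ub=ub),
        Reaction("rP", {"A": -1.0, "P": 1.0}, lb=0.0, ub=ub),
        Reaction("rQ2", {"A": -1.0, "M": -1.0, "Q": 2.0}, lb=0.0, ub=ub),
    ]
    best = set()
    alternatives: list[set[str]] = []
    if spec.series_rq1:
        # A → Qi → Q: deleting either leg blocks the route — two
        # equal-score singleton alternatives for enumeration tests.
        mets.append("Qi")
        reactions.append(Reaction("rQ1a", {"A": -1.0, "Qi": 1.0}, lb=0.0, ub=ub))
        reactions.append(Reaction("rQ1b", {"Qi": -1.0, "Q": 1.0}, lb=0.0, ub=ub))
        best = {"rQ1a"}
        alternatives = [{"rQ1a"}, {"rQ1b"}]
    elif spec.duplicate_rq1:
        reactions.append(Reaction("rQ1a", {"A": -1.0, "Q": 1.0}, lb=0.0, ub=ub))
        reactions.append(Reaction("rQ1b", {"A": -1.0, "Q": 1.0}, lb=0.0, ub=ub))
        best = {"rQ1a", "rQ1b"}
    else:
        reactions.append(Reaction("rQ1", {"A": -1.0, "Q": 1.0}, lb=0.0, ub=ub))
        best = {"rQ1"}
    biomass_stoich = {"P": -(1.0 - phi), "Q": -phi}
    if phi == 1.0:
        biomass_stoich = {"Q": -1.0}
    reactions.append(Reaction("biomass", biomass_stoich, lb=0.0, ub=ub, has_gene=False))
    if spec.include_uc_only_route:
        reactions.append(Reaction("rPM", {"M": -1.0, "P": 1.0}, lb=0.0, ub=ub))
        reactions.append(Reaction("rQM", {"M": -1.0, "Q": 1.0}, lb=0.0, ub=ub))
    leak_violates = False
    if spec.include_leak_route:
        reactions.append(Reaction("rLeak", {"A": -spec.c_leak, "Q": 1.0}, lb=0.0, ub=ub))
        # with only the efficient routes deleted the strain still grows on A
        # alone at uptake/(1-phi+c_leak*phi); requirement 2 is violated iff
        # that exceeds req2_fraction * uptake
        leak_growth = spec.uptake_bound / (1.0 - phi + spec.c_leak * phi)
        leak_violates = leak_growth > spec.req2_fraction * spec.uptake_bound
        if leak_violates:
            best = best | {"rLeak"}
            alternatives = [s | {"rLeak"} for s in alternatives]
    rng = np.random.default_rng(spec.seed)
    for k in range(spec.decoys):
        # dead-end in, dead-end out: structurally blocked in every medium
        d_in, d_out = f"D{k}_in", f"D{k}_out"
        mets.extend([d_in, d_out])
        reactions.append(
            Reaction(
                f"decoy{k}",
                {d_in: -1.0, d_out: 1.0},
                lb=0.0,
                ub=ub,
                has_gene=bool(rng.integers(0, 2)),
            )
        )
    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        biomass_id="biomass",
        exchange_ids={"EX_A", "EX_M"},
        annotations={"base_medium": ()},
    )
    key = ToyAnswerKey(
        expected_best_knockouts=best,
        expected_sadf=2.0 / phi,
        expected_ucco=phi / (2.0 - phi),
        expected_v0_cosub=spec.uptake_bound,
        expected_coupling_fraction=phi,
        leak_violates_req2=leak_violates,
        alternative_best_knockouts=alternatives or [best],
    )
    return model, key


_SUBSET_GUARD = 100_000


def brute_force_designs(
    model: MetabolicModel,
    config: DesignConfig,
    candidates: list[str],
    max_knockouts: int | None = None,
) -> list[metrics.StrategyScore]:
    """Exhaustively score every knockout subset of size <= K by direct LP.

    The independent oracle for the design MILP: every subset is pushed
    through :func:`metrics.check_requirements`; passers are scored with
    SADF and UC/Co and returned sorted by SADF descending, ties broken
    by fewer knockouts then lexicographic ids.  Guarded to 1e5 subsets.
    """
    K = config.max_knockouts if max_knockouts is None else max_knockouts
    n = len(candidates)
    total = sum(math.comb(n, k) for k in range(K + 1))
    if total > _SUBSET_GUARD:
        raise SizeError(f"{total} subsets exceed the {_SUBSET_GUARD} enumeration guard")
    ordered = sorted(candidates)
    failed_req3_singletons: set[str] = set()
    passers: list[metrics.StrategyScore] = []
    for k in range(K + 1):
        for combo in combinations(ordered, k):
            ko = set(combo)
            # growth only decreases under extra knockouts, so any superset
            # of a requirement-3-failing singleton also fails
            if ko & failed_req3_singletons:
                continue
            report = metrics.check_requirements(model, ko, config)
            if k == 1 and not report.req3_pass:
                failed_req3_singletons.add(combo[0])
            if not report.passed:
                continue
            passers.append(metrics.score_strategy(model, ko, config))
    def sort_key(score: metrics.StrategyScore):
        sadf = score.sadf if score.sadf is not None else -math.inf
        return (-sadf, len(score.knockouts), tuple(sorted(score.knockouts)))
    passers.sort(key=sort_key)
    return passers
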