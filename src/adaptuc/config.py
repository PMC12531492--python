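"""Design configuration shared by the metrics and MILP layers.

A :class:`DesignConfig` fixes the identities of the two substrates, the
design variant, the knockout budget, and the numeric thresholds of the
three starting-strain requirements:

1. growth on the unadapted carbon source (UC) alone — forbidden for
   variant A (≤ ``req1_fraction`` of the reference UC growth, default
   10%), required for variant B (≥ ``req1_fraction``, default 50%);
2. growth on the cosubstrate alone must collapse to ≤ ``req2_fraction``
   (default 10%) of the reference cosubstrate growth;
3. growth on both substrates must recover the reference cosubstrate
   growth.

All uptake rates are magnitudes in mmol/gDW/h; growth rates are 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class DesignConfig:
    """Substrate identities, variant, budget and thresholds for a design run.

    Parameters
    ----------
    uc_exchange : str
        Exchange-reaction id of the unadapted carbon source (e.g. methanol).
    cosub_exchange : str
        Exchange-reaction id of the cosubstrate.
    variant : {"A", "B"}
        "A" couples growth to *both* substrates (no growth on the UC
        alone); "B" preserves robust growth on the UC alone.
    max_knockouts : int
        Knockout budget K (``sum(y) <= K``).
    uptake_bound : float
        Maximum substrate uptake used in the inner growth problems
        (mmol/gDW/h).
    req1_fraction : float, optional
        Fraction of the reference UC growth used by requirement 1.
        Defaults to 0.1 for variant A (upper bound) and 0.5 for
        variant B (lower bound) when left unset.
    req2_fraction : float
        Requirement-2 ceiling as a fraction of the reference cosubstrate
        growth.
    ucco_growth : float
        Growth floor (1/h) used by the parsimonious UC/Co ratio.
    uc_recovery_bound : float
        UC uptake bound used when probing growth recovery and the minimal
        UC uptake (the UC supply is effectively unlimited there).
    """

    uc_exchange: str
    cosub_exchange: str
    variant: str = "A"
    max_knockouts: int = 5
    uptake_bound: float = 10.0
    req1_fraction: float | None = None
    req2_fraction: float = 0.1
    ucco_growth: float = 0.1
    uc_recovery_bound: float = 1000.0
    base_medium: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.variant not in ("A", "B"):
            raise ValueError(f"variant must be 'A' or 'B', got {self.variant!r}")
        if self.max_knockouts < 0:
            raise ValueError("max_knockouts must be >= 0")
        if self.req1_fraction is not None and not (0 < self.req1_fraction <= 1):
            raise ValueError("req1_fraction must lie in (0, 1]")
        if not (0 < self.req2_fraction <= 1):
            raise ValueError("req2_fraction must lie in (0, 1]")
        if self.ucco_growth <= 0:
            raise ValueError("ucco_growth must be > 0")
        if self.uptake_bound <= 0 or self.uc_recovery_bound <= 0:
            raise ValueError("uptake bounds must be > 0")

    @property
    def effective_req1_fraction(self) -> float:
        """Requirement-1 fraction with the variant-specific default applied."""
        if self.req1_fraction is not None:
            return self.req1_fraction
        return 0.1 if self.variant == "A" else 0.5
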