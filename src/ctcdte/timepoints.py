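"""Treatment timepoint vocabulary shared by the cohort modules.

Blood draws follow a two-cycle schedule: baseline (cycle 1 day 1), four
hours and 24 hours after the first dose, one week in (day 8), and the same
pattern around the second cycle.
"""

from __future__ import annotations

#: Allowed timepoint labels, in schedule order.
TIMEPOINT_LABELS: tuple[str, ...] = (
    "C1D1",
    "C1D1+4h",
    "C1D2",
    "C1D8",
    "C2D1",
    "C2D1+4h",
    "C2D8",
)

#: Baseline vs week-1 pairs used for the longitudinal response contrast.
#: The 4-hour and 24-hour draws never enter the contrast.
CONTRAST_PAIRS: dict[int, tuple[str, str]] = {
    1: ("C1D1", "C1D8"),
    2: ("C2D1", "C2D8"),
}

__all__ = ["TIMEPOINT_LABELS", "CONTRAST_PAIRS"]
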