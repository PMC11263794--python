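"""Expected-vs-found model for H3 methylation under altered variant ratios.

When a chaperone mutant shifts the H3.1:H3.3 balance, the null hypothesis of
a pure variant exchange predicts the mutant's mark abundances from the WT
within-variant modification profiles weighted by the mutant's own mixture:
expected(mark on variant v) = f_v(mutant) x WT_profile_v(mark). Deviations
of the measured ("found") values from this expectation indicate that the
variants' modification behavior itself changed (e.g. H3.3 being repurposed
into an H3.1-like role).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import InvalidDataError
from .quantify import VariantMixture


def mixture_from_ratio(r: float) -> VariantMixture:
    """H3.1/H3.3 mixture from a ratio r = H3.1:H3.3 normalized to H3.3 = 1."""
    if not (r >= 0 and r == r and r != float("inf")):
        raise InvalidDataError("ratio must be finite and non-negative")
    return VariantMixture(f_h31=r / (1.0 + r), f_h33=1.0 / (1.0 + r))


def _check_closed(parts: Mapping[str, float], label: str) -> None:
    total = sum(parts.values())
    if abs(total - 100.0) > 1e-6:
        raise InvalidDataError(f"{label} profile sums to {total}, expected 100")


def expected_mark_abundance(
    wt_profile_h31: Mapping[str, float],
    wt_profile_h33: Mapping[str, float],
    mutant_mixture: VariantMixture,
) -> dict[tuple[str, str], float]:
    """Theoretical per-(variant, mark) abundances under a pure exchange.

    WT within-variant profiles (each closed to 100%) are held fixed and only
    the variant mixture is replaced by the mutant's. Keys are
    (variant, mark); values sum to 100 across all cells.
    """
    _check_closed(wt_profile_h31, "H3.1")
    _check_closed(wt_profile_h33, "H3.3")
    out: dict[tuple[str, str], float] = {}
    for mark, pct in wt_profile_h31.items():
        out[("H3.1", mark)] = mutant_mixture.f_h31 * pct
    for mark, pct in wt_profile_h33.items():
        out[("H3.3", mark)] = mutant_mixture.f_h33 * pct
    return out


def aggregate_over_variants(
    per_variant: Mapping[tuple[str, str], float]
) -> dict[str, float]:
    """Sum per-(variant, mark) cells over variants (mark-level view)."""
    agg: dict[str, float] = {}
    for (_, mark), pct in per_variant.items():
        agg[mark] = agg.get(mark, 0.0) + pct
    return agg


def compensation_delta(
    expected: Mapping, found: Mapping, tolerance: float = 0.5
) -> pd.DataFrame:
    """Found - expected per mark with an up/down/none call.

    ``tolerance`` is the percentage-point dead band below which a delta is
    called 'none'.
    """
    missing = set(expected) ^ set(found)
    if missing:
        raise InvalidDataError(f"mark keys differ between maps: {sorted(map(str, missing))}")
    rows = []
    for mark in expected:
        delta = found[mark] - expected[mark]
        if delta > tolerance:
            direction = "up"
        elif delta < -tolerance:
            direction = "down"
        else:
            direction = "none"
        rows.append(
            {
                "mark": mark if isinstance(mark, str) else ":".join(mark),
                "expected": expected[mark],
                "found": found[mark],
                "delta": delta,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
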