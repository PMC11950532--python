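"""Stage 2: concordance between morphometric and sensitivity
significance sets.

The Jaccard index |A n B| / |A u B| quantifies the overlap between the
region sets flagged significant by the two analyses.  When both sets are
empty the index is 0 by convention, but the two analyses actually agree
perfectly; the report therefore carries a ``both_empty`` flag and a
complementary whole-universe status-agreement fraction so that
"perfect null agreement" stays machine-readable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

__all__ = [
    "SignificanceSet",
    "JaccardResult",
    "jaccard",
    "status_agreement",
    "significance_set_from_stats",
    "concordance_report",
]


@dataclass(frozen=True)
class SignificanceSet:
    """Region labels flagged significant, within a fixed region universe."""

    regions: frozenset
    universe: frozenset
    map_type: str = ""
    modality: str = ""
    factor: str = ""

    def __post_init__(self):
        object.__setattr__(self, "regions", frozenset(self.regions))
        object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.regions <= self.universe:
            raise ValueError("significant regions must lie in the universe")


class JaccardResult(NamedTuple):
    value: float
    both_empty: bool


def _check_universes(a: SignificanceSet, b: SignificanceSet):
    if a.universe != b.universe:
        raise ValueError("significance sets have different region universes")


def jaccard(a: SignificanceSet, b: SignificanceSet) -> JaccardResult:
    """|A n B| / |A u B|; (0, both_empty=True) when both sets are empty."""
    _check_universes(a, b)
    union = a.regions | b.regions
    if not union:
        return JaccardResult(0.0, True)
    return JaccardResult(len(a.regions & b.regions) / len(union), False)


def status_agreement(a: SignificanceSet, b: SignificanceSet) -> float:
    """Fraction of universe regions with matching in/out status (1.0 for
    two empty sets)."""
    _check_universes(a, b)
    if not a.universe:
        raise ValueError("empty region universe")
    disagree = len(a.regions ^ b.regions)
    return 1.0 - disagree / len(a.universe)


def significance_set_from_stats(stats: pd.DataFrame, factor: str,
                                modality: str | None = None) -> SignificanceSet:
    """Extract a SignificanceSet from a stage-1 StatTable for one factor
    (and one modality, if the table holds several)."""
    sub = stats[stats["factor"] == factor]
    if modality is not None:
        sub = sub[sub["modality"] == modality]
    if sub.empty:
        raise ValueError(f"no rows for factor={factor!r}, modality={modality!r}")
    universe = frozenset(sub["region"])
    sig = frozenset(sub.loc[sub["significant"], "region"])
    map_type = sub["map_type"].iloc[0] if "map_type" in sub else ""
    return SignificanceSet(regions=sig, universe=universe, map_type=map_type,
                           modality=sub["modality"].iloc[0] if "modality" in sub else "",
                           factor=factor)


def concordance_report(morph_stats: pd.DataFrame, sens_stats: pd.DataFrame,
                       factors=("age", "condition")) -> pd.DataFrame:
    """One row per (modality, factor): Jaccard, both_empty, agreement and
    the two set sizes.  Region order in the inputs is irrelevant."""
    m_mods = sorted(morph_stats["modality"].unique())
    s_mods = sorted(sens_stats["modality"].unique())
    if m_mods != s_mods:
        raise ValueError(f"modality mismatch: morphometric {m_mods} vs "
                         f"sensitivity {s_mods}")
    rows = []
    for modality in m_mods:
        for factor in factors:
            a = significance_set_from_stats(morph_stats, factor, modality)
            b = significance_set_from_stats(sens_stats, factor, modality)
            jac = jaccard(a, b)
            rows.append({
                "modality": modality,
                "factor": factor,
                "jaccard": jac.value,
                "both_empty": jac.both_empty,
                "agreement": status_agreement(a, b),
                "n_sig_morph": len(a.regions),
                "n_sig_sens": len(b.regions),
            })
    return pd.DataFrame(rows)
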