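"""Weighted min–max scoring of truncation variants.

Each variant carries four factors: docking binding energy A (kcal/mol,
lower is better), protein–ligand hydrogen-bond count B (higher is better),
serine attack distance C (Å, lower is better) and cavity volume D (Å³,
higher is better).  Each factor column is min–max normalized to [0, 1]
within the scored table, the lower-is-better columns are inverted
(1 − fraction), and the composite score is the weighted sum

    score = 0.10·a + 0.30·b + 0.40·c + 0.20·d

so that a variant dominating on every factor scores exactly 1 and a variant
dominated on every factor scores 0.  A degenerate column (max = min) cannot
discriminate and contributes a neutral 0.5 for every variant.

Normalization is per input table: score the candidates of one parent enzyme
together unless cross-enzyme comparability is explicitly wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pocket_metrics import FactorRecord


@dataclass(frozen=True)
class ScoringWeights:
    """Fractional weights for (A, B, C, D); must sum to 1."""

    w_A: float = 0.10
    w_B: float = 0.30
    w_C: float = 0.40
    w_D: float = 0.20

    def __post_init__(self) -> None:
        for name, w in self.as_dict().items():
            if not 0 <= w <= 1:
                raise ValueError(f"weight {name} = {w} outside [0, 1]")
        if abs(sum(self.as_dict().values()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.as_dict().values())}")

    def as_dict(self) -> dict[str, float]:
        return {"w_A": self.w_A, "w_B": self.w_B, "w_C": self.w_C, "w_D": self.w_D}


_COLUMNS = {
    "A": ("A_binding_energy", True),   # lower is better -> invert
    "B": ("B_hbond_count", False),
    "C": ("C_attack_distance", True),  # lower is better -> invert
    "D": ("D_cavity_volume", False),
}


def _records_frame(records: list[FactorRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("need at least one FactorRecord")
    df = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "A_binding_energy": [r.A_binding_energy for r in records],
            "B_hbond_count": [r.B_hbond_count for r in records],
            "C_attack_distance": [r.C_attack_distance for r in records],
            "D_cavity_volume": [r.D_cavity_volume for r in records],
        }
    )
    for factor, (col, _) in _COLUMNS.items():
        bad = df.loc[~np.isfinite(df[col].astype(float)), "variant_id"]
        if len(bad):
            raise ValueError(f"non-finite factor {factor} for variant(s) {list(bad)}")
    return df


def normalize_factors(records: list[FactorRecord]) -> pd.DataFrame:
    """Min–max fractions a, b, c, d in [0, 1], inverted for A and C.

    Degenerate columns (max = min) yield 0.5 for every variant.
    """
    df = _records_frame(records)
    for factor, (col, invert) in _COLUMNS.items():
        x = df[col].astype(float).to_numpy()
        lo, hi = x.min(), x.max()
        if math.isclose(lo, hi, rel_tol=0.0, abs_tol=0.0) or hi == lo:
            frac = np.full_like(x, 0.5)
        else:
            frac = (x - lo) / (hi - lo)
            if invert:
                frac = 1.0 - frac
        df[factor.lower()] = frac
    return df[["variant_id", "a", "b", "c", "d"]]


def score(
    records: list[FactorRecord], weights: ScoringWeights = ScoringWeights()
) -> pd.DataFrame:
    """Score table: raw factors, normalized fractions, weighted score, rank.

    Ranks are 1-based, descending by score; ties break by smaller attack
    distance (the heaviest-weighted factor), then lexicographic variant id.
    """
    df = _records_frame(records)
    norm = normalize_factors(records)
    df = df.merge(norm, on="variant_id")
    df["score"] = (
        weights.w_A * df["a"]
        + weights.w_B * df["b"]
        + weights.w_C * df["c"]
        + weights.w_D * df["d"]
    )
    order = df.sort_values(
        by=["score", "C_attack_distance", "variant_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
    df["rank"] = ranks.sort_index()
    return df


def rank(table: pd.DataFrame, top_k: int) -> list[str]:
    """The ``top_k`` variant ids of a score table, best first."""
    if table.empty:
        raise ValueError("empty score table")
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    ordered = table.sort_values("rank")
    return ordered["variant_id"].head(top_k).tolist()
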