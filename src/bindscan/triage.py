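"""Disruption calls, hotspot ranking, heatmap matrix and prioritisation.

A mutation disrupts binding when its ΔK* drops by at least the cutoff
(default 3 log10 units, i.e. ΔK* ≤ −3; the boundary counts) or when the
mutant complex loses all ensemble mass ("X").  Histidine mutations carry
three protonation-variant scores and count as disruptive only if all three
variants disrupt.  Mutations reachable only by substituting all three codon
bases are excluded outright, whatever their scores.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .confspace import ALL_AA1
from .kstar import COMPLETE_DISRUPTION, DeltaKStar

DeltaLike = Union[float, str, DeltaKStar]

VERDICT_DISRUPTIVE = "disruptive"
VERDICT_NON_DISRUPTIVE = "non_disruptive"
VERDICT_EXCLUDED_TRIPLE = "excluded_triple"

# heatmap row order: one row per target residue, histidine expanded into its
# three protonation variants
HEATMAP_ROWS: List[str] = []
for _aa in ALL_AA1:
    if _aa == "H":
        HEATMAP_ROWS.extend(["H1", "H2", "H3"])
    else:
        HEATMAP_ROWS.append(_aa)


@dataclass
class TriageConfig:
    cutoff: float = -3.0  # Log10 K* units; adaptable at the user's discretion
    his_rule: bool = True  # all three protonation variants must disrupt
    exclude_triples: bool = True

    def __post_init__(self) -> None:
        if self.cutoff >= 0:
            raise ValueError("cutoff must be negative (a score decrease)")


def _delta_value(d: DeltaLike) -> Optional[float]:
    """None encodes the complete-disruption sentinel."""
    if isinstance(d, DeltaKStar):
        return d.value
    if isinstance(d, str):
        if d == COMPLETE_DISRUPTION:
            return None
        raise ValueError(f"unrecognised ΔK* value {d!r}")
    return float(d)


@dataclass
class DisruptionCall:
    position: int
    wildtype_aa: str
    target_aa: str
    variant_deltas: List[Optional[float]]  # 1 entry, or 3 for histidine
    verdict: str
    reason: str
    path_class: str = "single"
    chain_id: str = ""

    def __post_init__(self) -> None:
        expected = 3 if self.target_aa == "H" else 1
        if len(self.variant_deltas) != expected:
            raise ValueError(
                f"{self.target_aa} mutation must carry {expected} variant value(s)"
            )

    @property
    def sort_delta(self) -> float:
        """Most disruptive variant value ("X" counts as −inf) for ordering."""
        vals = [(-math.inf if v is None else v) for v in self.variant_deltas]
        return min(vals)

    @property
    def label(self) -> str:
        return f"{self.wildtype_aa}{self.position}{self.target_aa}"


def classify_disruption(
    deltas: Sequence[DeltaLike],
    path_class: str = "single",
    cfg: Optional[TriageConfig] = None,
    *,
    position: int = 0,
    wildtype_aa: str = "?",
    target_aa: Optional[str] = None,
    chain_id: str = "",
) -> DisruptionCall:
    """Turn per-variant ΔK* values into a single disruption verdict.

    ``deltas`` holds one value, or three for a histidine target (one per
    protonation state).  A value is disruptive when ≤ cutoff or when it is
    the complete-disruption sentinel.
    """
    cfg = cfg or TriageConfig()
    if not deltas:
        raise ValueError("empty ΔK* list")
    values = [_delta_value(d) for d in deltas]
    if target_aa is None:
        target_aa = "H" if len(values) == 3 else "?"

    if path_class == "triple" and cfg.exclude_triples:
        verdict = VERDICT_EXCLUDED_TRIPLE
        reason = "reachable only by mutating all three codon bases"
    else:
        hits = [v is None or v <= cfg.cutoff for v in values]
        if len(values) > 1 and not cfg.his_rule:
            disruptive = any(hits)
            rule = "any protonation state"
        else:
            disruptive = all(hits)
            rule = "all protonation states" if len(values) > 1 else "ΔK*"
        if disruptive:
            verdict = VERDICT_DISRUPTIVE
            reason = f"{rule} ≤ cutoff {cfg.cutoff:g} (X counts as disruptive)"
        else:
            verdict = VERDICT_NON_DISRUPTIVE
            reason = f"{rule} above cutoff {cfg.cutoff:g}"
    return DisruptionCall(
        position=position,
        wildtype_aa=wildtype_aa,
        target_aa=target_aa,
        variant_deltas=values,
        verdict=verdict,
        reason=reason,
        path_class=path_class,
        chain_id=chain_id,
    )


@dataclass
class HotspotReport:
    counts: Dict[int, int]  # residue position -> number of disruptive mutations
    ranking: List[int]  # positions, descending count, ties by position
    top_k: int = 3

    @property
    def top_positions(self) -> List[int]:
        return self.ranking[: self.top_k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.ranking,
                "disruptive_mutations": [self.counts[p] for p in self.ranking],
            }
        )


def hotspot_rank(calls: Iterable[DisruptionCall], top_k: int = 3) -> HotspotReport:
    """Rank residue positions by their number of disruptive mutations."""
    counts = Counter(
        c.position for c in calls if c.verdict == VERDICT_DISRUPTIVE
    )
    ranking = sorted(counts, key=lambda p: (-counts[p], p))
    return HotspotReport(dict(counts), ranking, top_k)


WT_MARK = "wt"
TRIPLE_MARK = "triple"


def heatmap_matrix(calls: Sequence[DisruptionCall]) -> pd.DataFrame:
    """ΔK* matrix: rows = target residues (His as H1/H2/H3), columns =
    scanned positions; wildtype cells marked ``wt``, triple-excluded cells
    ``triple``, complete disruption ``X``."""
    columns: List[str] = []
    for c in calls:
        col = f"{c.wildtype_aa}{c.position}"
        if col not in columns:
            columns.append(col)
    mat = pd.DataFrame("", index=HEATMAP_ROWS, columns=columns, dtype=object)

    def put(row: str, col: str, value: str) -> None:
        if mat.at[row, col] != "":
            raise ValueError(f"duplicate heatmap cell ({row}, {col})")
        mat.at[row, col] = value

    for c in calls:
        col = f"{c.wildtype_aa}{c.position}"
        if c.target_aa == c.wildtype_aa:
            put(c.target_aa if c.target_aa != "H" else "H2", col, WT_MARK)
            continue
        if c.target_aa == "H":
            rows = ["H1", "H2", "H3"]
        else:
            rows = [c.target_aa]
        for row, v in zip(rows, c.variant_deltas):
            if c.verdict == VERDICT_EXCLUDED_TRIPLE:
                put(row, col, TRIPLE_MARK)
            elif v is None:
                put(row, col, COMPLETE_DISRUPTION)
            else:
                put(row, col, f"{v:.2f}")
        # a wildtype reference row for the scanned residue, if not itself a call
        wt_row = c.wildtype_aa if c.wildtype_aa != "H" else "H2"
        if mat.at[wt_row, col] == "":
            mat.at[wt_row, col] = WT_MARK
    return mat


def prioritize(
    calls: Sequence[DisruptionCall],
    hotspots: HotspotReport,
    probs: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Ranked table of disruptive mutations at the top hotspot positions.

    With mutation-formation probabilities, order is probability descending
    (the clinically likeliest first); without (the no-cancer-type mode),
    order is ΔK* ascending — the strongest predicted disruption first.
    """
    top = set(hotspots.top_positions)
    selected = [
        c for c in calls if c.verdict == VERDICT_DISRUPTIVE and c.position in top
    ]
    if not selected:
        return pd.DataFrame(
            columns=["position", "wildtype_aa", "target_aa", "delta_kstar",
                     "relative_probability"]
        )
    prob_map: Dict[Tuple[int, str], Optional[float]] = {}
    if probs is not None:
        for p in probs:
            prob_map[(p.protein_position, p.target_aa)] = p.relative_probability
        missing = [
            c.label for c in selected if (c.position, c.target_aa) not in prob_map
        ]
        if missing:
            raise ValueError(f"no formation probability for mutation(s) {missing}")
        selected.sort(
            key=lambda c: (
                -(prob_map[(c.position, c.target_aa)] or 0.0),
                c.position,
                c.target_aa,
            )
        )
    else:
        selected.sort(key=lambda c: (c.sort_delta, c.position, c.target_aa))
    rows = []
    for c in selected:
        rows.append(
            {
                "position": c.position,
                "wildtype_aa": c.wildtype_aa,
                "target_aa": c.target_aa,
                "delta_kstar": "/".join(
                    COMPLETE_DISRUPTION if v is None else f"{v:.2f}"
                    for v in c.variant_deltas
                ),
                "relative_probability": (
                    "" if probs is None
                    else prob_map[(c.position, c.target_aa)]
                ),
            }
        )
    return pd.DataFrame(rows)


def calls_table(calls: Sequence[DisruptionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "chain": c.chain_id,
                "position": c.position,
                "wildtype_aa": c.wildtype_aa,
                "target_aa": c.target_aa,
                "variant_deltas": "/".join(
                    COMPLETE_DISRUPTION if v is None else f"{v:.4f}"
                    for v in c.variant_deltas
                ),
                "path_class": c.path_class,
                "verdict": c.verdict,
                "reason": c.reason,
            }
        )
    return pd.DataFrame(rows)


def plot_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Render the scan heatmap (wildtype cells black, excluded triples grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    values = np.full(matrix.shape, np.nan)
    for i, row in enumerate(matrix.index):
        for j, col in enumerate(matrix.columns):
            cell = matrix.iat[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                pass
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * len(matrix.columns), 1 + 0.3 * len(matrix.index))
    )
    im = ax.imshow(values, aspect="auto", cmap="viridis")
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            cell = matrix.iat[i, j]
            if cell == WT_MARK:
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, color="black"))
            elif cell == TRIPLE_MARK:
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, color="grey"))
            elif cell == COMPLETE_DISRUPTION:
                ax.text(j, i, "X", ha="center", va="center", color="red")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    fig.colorbar(im, ax=ax, label="ΔK* (Log10)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
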