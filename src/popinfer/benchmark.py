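"""Early precision-recall evaluation against a reference network.

Following the common GRN-benchmarking convention, candidate edges are
restricted to pairs whose regulator and target both occur in the
reference (so precision never penalizes unevaluable pairs), ranked by
|W|, and scored by the area under the precision-recall curve over a
restricted recall range [0, r_max], normalized by r_max (AUEPRC).
Equal-score predictions enter the curve as one atomic tie group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import ValidationError
from .io import validate_edge_list

__all__ = [
    "ReferenceNetwork",
    "EPRCResult",
    "build_evaluable_predictions",
    "early_prc",
    "run_benchmark",
]


@dataclass(frozen=True)
class ReferenceNetwork:
    """Ground-truth positives plus the evaluable gene universes."""

    positives: frozenset[tuple[str, str]]
    regulator_universe: frozenset[str]
    target_universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positives:
            raise ValidationError("reference network has no positives")
        if any(r == t for r, t in self.positives):
            raise ValidationError("reference network contains self-pairs")

    @classmethod
    def from_edges(cls, edges: pd.DataFrame | Iterable[tuple[str, str]]) -> "ReferenceNetwork":
        if isinstance(edges, pd.DataFrame):
            pairs = list(zip(edges["regulator"].astype(str), edges["target"].astype(str)))
        else:
            pairs = [(str(r), str(t)) for r, t in edges]
        return cls(
            positives=frozenset(pairs),
            regulator_universe=frozenset(r for r, _ in pairs),
            target_universe=frozenset(t for _, t in pairs),
        )


@dataclass
class EPRCResult:
    """Early precision-recall curve and its normalized area."""

    recall_points: np.ndarray
    precision_points: np.ndarray
    r_max: float
    aueprc: float


def build_evaluable_predictions(net, ref: ReferenceNetwork) -> pd.DataFrame:
    """Score every evaluable pair and rank by descending |W|.

    Accepts a SignedNetwork / square DataFrame or an edge-list DataFrame
    (in which case unlisted evaluable pairs get score 0).  Candidates are
    pairs with regulator in the reference's regulator universe and target
    in its target universe, self-pairs removed.
    """
    scores: Mapping[tuple[str, str], float]
    if hasattr(net, "to_frame") or (
        isinstance(net, pd.DataFrame) and "regulator" not in net.columns
    ):
        frame = net.to_frame() if hasattr(net, "to_frame") else net
        genes_r = [g for g in frame.index if g in ref.regulator_universe]
        genes_t = [g for g in frame.columns if g in ref.target_universe]
        scores = {
            (r, t): abs(float(frame.at[r, t]))
            for r in genes_r
            for t in genes_t
            if r != t
        }
    else:
        edges = validate_edge_list(pd.DataFrame(net))
        scores = {}
        listed = set()
        genes = set(edges["regulator"]) | set(edges["target"])
        for r, t, w in zip(edges["regulator"], edges["target"], edges["weight"]):
            if r in ref.regulator_universe and t in ref.target_universe:
                scores[(r, t)] = abs(float(w))
                listed.add((r, t))
        for r in genes & ref.regulator_universe:
            for t in genes & ref.target_universe:
                if r != t and (r, t) not in listed:
                    scores[(r, t)] = 0.0
    if not scores:
        raise ValidationError(
            "no evaluable pairs: network genes "
            "do not overlap the reference regulator/target universes"
        )
    df = pd.DataFrame(
        [(r, t, s) for (r, t), s in scores.items()],
        columns=["regulator", "target", "score"],
    )
    return df.sort_values(
        ["score", "regulator", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)


def early_prc(
    ranked: pd.DataFrame,
    positives: Iterable[tuple[str, str]],
    r_max: float,
) -> EPRCResult:
    """Precision-recall curve over recall in [0, r_max], area / r_max.

    The curve is evaluated after each distinct score threshold (tie
    groups enter atomically).  The area follows the step convention:
    each recall increment contributes the precision at its right
    endpoint, with the final increment truncated at r_max.
    """
    if not 0.0 < r_max <= 1.0:
        raise ValidationError("r_max must lie in (0, 1]")
    positives = set(positives)
    pairs = list(zip(ranked["regulator"], ranked["target"]))
    is_pos = np.array([p in positives for p in pairs], dtype=bool)
    P = int(is_pos.sum())
    if P == 0:
        raise ValidationError("no reference positive among the candidates")
    scores = ranked["score"].to_numpy(dtype=float)
    # indices of the last element of each tie group
    group_ends = np.nonzero(np.diff(scores, append=np.nan) != 0)[0]
    cum_tp = np.cumsum(is_pos)
    tp = cum_tp[group_ends]
    n_pred = group_ends + 1
    recall = tp / P
    precision = tp / n_pred

    area, r_prev = 0.0, 0.0
    for rec, prec in zip(recall, precision):
        if rec > r_prev:
            inc = min(rec, r_max) - r_prev
            area += prec * inc
            r_prev = min(rec, r_max)
        if r_prev >= r_max:
            break
    return EPRCResult(recall, precision, r_max, area / r_max)


def run_benchmark(
    nets: Mapping[str, object],
    ref: ReferenceNetwork,
    r_max: float = 0.1,
) -> pd.DataFrame:
    """AUEPRC per named network under identical candidate restriction.

    Networks that cannot be evaluated (no identifier overlap, no positive
    among candidates) are reported with NaN and an error message rather
    than aborting the whole comparison.
    """
    rows = []
    for name, net in nets.items():
        try:
            ranked = build_evaluable_predictions(net, ref)
            result = early_prc(ranked, ref.positives, r_max)
            rows.append((name, result.aueprc, ""))
        except ValidationError as exc:
            rows.append((name, np.nan, str(exc)))
    return pd.DataFrame(rows, columns=["name", "aueprc", "error"])
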