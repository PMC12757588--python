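"""Post-inference network operations: thresholding, hubs, consensus.

Edges are called from the averaged weight matrix by strict magnitude
threshold (|W| > tau, default 0.4), so strong inhibitions count as much
as strong activations.  Hub regulators are ranked by out-degree, split
into activating and inhibitory targets.  A consensus network is the
sign-consistent intersection of several thresholded networks, e.g.
across dietary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ValidationError
from .io import validate_edge_list

__all__ = ["threshold_network", "rank_hubs", "consensus", "ConsensusNetwork"]


def threshold_network(net, tau: float) -> pd.DataFrame:
    """Edges with |W| strictly above tau, in deterministic order.

    Accepts a SignedNetwork or a labeled square DataFrame (rows =
    regulators, columns = targets).  Output columns: regulator, target,
    weight (the signed W value), sign; sorted by |weight| descending,
    then regulator, then target.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValidationError("tau must lie in [0, 1]")
    frame = net.to_frame() if hasattr(net, "to_frame") else pd.DataFrame(net)
    W = frame.to_numpy(dtype=float)
    regs, targets = np.nonzero(np.abs(W) > tau)
    edges = pd.DataFrame(
        {
            "regulator": frame.index[regs],
            "target": frame.columns[targets],
            "weight": W[regs, targets],
            "sign": np.sign(W[regs, targets]).astype(int),
        }
    )
    edges = edges[edges["regulator"] != edges["target"]]
    edges = edges.assign(_mag=edges["weight"].abs())
    edges = edges.sort_values(
        ["_mag", "regulator", "target"], ascending=[False, True, True]
    ).drop(columns="_mag")
    return edges.reset_index(drop=True)


def rank_hubs(edges: pd.DataFrame) -> pd.DataFrame:
    """Rank regulators by number of outgoing edges.

    Returns columns gene, out_degree, n_activating, n_inhibitory, sorted
    by out-degree descending with alphabetical tie-break.  Activating and
    inhibitory counts partition the out-degree when signs are present
    (sign-0 edges count toward neither).
    """
    edges = validate_edge_list(pd.DataFrame(edges)) if len(edges) else edges
    if len(edges) == 0:
        return pd.DataFrame(columns=["gene", "out_degree", "n_activating", "n_inhibitory"])
    grouped = edges.groupby("regulator", sort=False)
    table = pd.DataFrame(
        {
            "gene": list(grouped.groups),
            "out_degree": grouped.size().values,
            "n_activating": grouped["sign"].apply(lambda s: int((s == 1).sum())).values,
            "n_inhibitory": grouped["sign"].apply(lambda s: int((s == -1).sum())).values,
        }
    )
    table = table.sort_values(["out_degree", "gene"], ascending=[False, True])
    return table.reset_index(drop=True)


@dataclass
class ConsensusNetwork:
    """Sign-consistent intersection of several networks."""

    edges: pd.DataFrame       # regulator, target, sign present in all inputs
    conflicts: pd.DataFrame   # pairs present in all inputs but with sign disagreement
    source_count: int


def consensus(nets: Sequence[pd.DataFrame], require_sign: bool = True) -> ConsensusNetwork:
    """Intersect thresholded edge lists across conditions.

    An edge survives if its (regulator, target) pair appears in every
    input and (when ``require_sign``) carries the same sign everywhere;
    pairs present everywhere but with conflicting signs are reported
    separately.  The operation is commutative, associative and
    idempotent.
    """
    if len(nets) < 2:
        raise ValidationError("consensus needs at least 2 networks")
    frames = [validate_edge_list(pd.DataFrame(n)) for n in nets]
    pair_sets = [set(zip(f["regulator"], f["target"])) for f in frames]
    common = set.intersection(*pair_sets)

    kept, conflicted = [], []
    sign_maps = [dict(zip(zip(f["regulator"], f["target"]), f["sign"])) for f in frames]
    for pair in sorted(common):
        signs = {m[pair] for m in sign_maps}
        if not require_sign or len(signs) == 1:
            kept.append((*pair, signs.pop() if len(signs) == 1 else 0))
        else:
            conflicted.append((*pair, tuple(sorted(signs))))
    edges = pd.DataFrame(kept, columns=["regulator", "target", "sign"])
    conflicts = pd.DataFrame(conflicted, columns=["regulator", "target", "signs"])
    return ConsensusNetwork(edges, conflicts, len(frames))
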