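"""Sensory information-flow ranking over the connectivity graph.

From each sensory modality's seed neurons, a stochastic traversal spreads
through the synapse-weighted graph: at every step, an inactive neuron
receiving a fraction f of its total input weight from already-active
neurons becomes active with probability min(1, f / f_max).  The rank of a
neuron for a modality is its mean activation step over repeated runs; a low
rank means a more direct connection from that sensory modality.  As
f_max → 0 the traversal degenerates to breadth-first search and ranks equal
shortest-path hop counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from neckconn.morpho import cluster_rows


def _adjacency(edges: pd.DataFrame, node_index: dict[str, int]) -> sparse.csr_matrix:
    n = len(node_index)
    rows = edges["post_id"].map(node_index).to_numpy()
    cols = edges["pre_id"].map(node_index).to_numpy()
    w = edges["weight"].to_numpy(float)
    return sparse.csr_matrix((w, (rows, cols)), shape=(n, n))


def information_flow_rank(
    edges: pd.DataFrame,
    seeds: dict[str, set[str] | list[str]],
    f_max: float = 0.3,
    runs: int = 100,
    max_step: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean traversal distance from each modality's seed set to every neuron.

    Returns a DataFrame (rows: neuron ids, columns: modalities).  Seeds have
    rank 0 in their own modality; a neuron never reached within ``max_step``
    contributes max_step + 1 to its mean.  Bit-reproducible given
    (seed, runs).
    """
    if not 0.0 < f_max <= 1.0:
        raise ValueError("f_max must be in (0, 1]")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    for modality, s in seeds.items():
        if not s:
            raise ValueError(f"modality {modality!r} has an empty seed set")

    node_ids = sorted(
        set(edges["pre_id"]) | set(edges["post_id"]) | {n for s in seeds.values() for n in s}
    )
    index = {n: i for i, n in enumerate(node_ids)}
    W = _adjacency(edges, index)
    total_in = np.asarray(W.sum(axis=1)).ravel()
    inv_in = np.where(total_in > 0, 1.0 / np.where(total_in > 0, total_in, 1.0), 0.0)

    rng = np.random.default_rng(seed)
    out = {}
    for modality in sorted(seeds):
        seed_vec = np.zeros(len(node_ids), bool)
        seed_vec[[index[s] for s in seeds[modality]]] = True
        ranks = np.zeros(len(node_ids))
        for _ in range(runs):
            active = seed_vec.copy()
            step_of = np.full(len(node_ids), max_step + 1, float)
            step_of[active] = 0.0
            for step in range(1, max_step + 1):
                f = (W @ active.astype(float)) * inv_in
                p = np.minimum(1.0, f / f_max)
                p[active] = 0.0
                fire = rng.random(len(node_ids)) < p
                if not fire.any():
                    if p.max() == 0.0:
                        break
                    continue
                step_of[fire] = step
                active |= fire
            ranks += step_of
        out[modality] = ranks / runs
    return pd.DataFrame(out, index=node_ids)


def average_rank_by_type(ranks: pd.DataFrame, type_map: dict[str, str]) -> pd.DataFrame:
    """Arithmetic mean of per-neuron ranks per type, per modality."""
    missing = [n for n in ranks.index if n not in type_map]
    if missing:
        raise ValueError(f"neurons without a type: {missing[:5]}")
    grouped = ranks.groupby([type_map[n] for n in ranks.index]).mean()
    grouped.index.name = "type"
    return grouped


def cluster_by_rank(type_ranks: pd.DataFrame, height: float, method: str = "ward") -> pd.Series:
    """Hierarchically cluster type rank vectors (Euclidean) and cut at height.

    Infinite entries are replaced by (finite max + 1) so unreachable types
    still cluster together rather than breaking the linkage.
    """
    mat = type_ranks.to_numpy(float).copy()
    if np.isinf(mat).any():
        finite_max = np.nanmax(np.where(np.isinf(mat), np.nan, mat))
        mat[np.isinf(mat)] = finite_max + 1.0
    labels = cluster_rows(mat, height=height, method=method, is_distance=False)
    return pd.Series(labels, index=type_ranks.index, name="cluster")
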