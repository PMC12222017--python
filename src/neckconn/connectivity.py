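"""Thresholded partner graphs, stereotypy statistics and synapse density.

Partner graphs around a focal neuron set are built with a synapse-count
threshold (weight ≥ 10) combined with an output-percentage threshold
(> 0.5% of the presynaptic neuron's total output); motor, sensory and
sensory-ascending partners are then added back at a lower weight threshold
(≥ 5) to compensate for their systematically sparser reconstruction.  The
retained adjacency is expressed as input percent to the receiving neuron
and can be averaged by type.

Stereotypy between hemispheres or datasets is summarised by the Pearson
correlation of paired connection weights and the least-squares slope
through the origin.  Effective (multi-hop) connectivity multiplies
input-fractions along paths of up to ``max_hops`` steps.  Synapse clouds
are summarised on a 5-µm voxel grid after an optional cleft-score filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PartnerGraph:
    """Directed weighted graph over neurons (or types) with input-percents."""

    nodes: pd.DataFrame  # columns: node_id, neuron_class
    edges: pd.DataFrame  # columns: pre_id, post_id, weight, input_pct
    thresholds: dict = field(default_factory=dict)

    def input_pct_matrix(self) -> pd.DataFrame:
        ids = self.nodes["node_id"].tolist()
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        for row in self.edges.itertuples(index=False):
            mat.at[row.pre_id, row.post_id] = row.input_pct
        return mat


def build_partner_graph(
    focal: set[str] | list[str],
    edges: pd.DataFrame,
    classes: dict[str, str],
    theta_w: int = 10,
    theta_pct: float = 0.5,
    theta_sens: int = 5,
    sensory_classes: tuple[str, ...] = ("MN", "SN", "SA"),
) -> PartnerGraph:
    """Build the thresholded partner graph around a focal neuron set.

    A partner enters if its edge with a focal neuron has weight ≥ theta_w
    AND carries > theta_pct percent of the presynaptic neuron's total
    output (measured dataset-wide, not within the subgraph).  Partners of
    the sensory/motor classes are then added back at weight ≥ theta_sens.
    Finally the all-by-all adjacency over the retained node set is
    converted to input percent of the receiving neuron (denominator: the
    neuron's dataset-wide total input), so column sums never exceed 100.
    """
    focal = set(focal)
    if not focal:
        raise ValueError("focal set is empty")
    total_out = edges.groupby("pre_id")["weight"].sum()
    total_in = edges.groupby("post_id")["weight"].sum()

    touching = edges[(edges["pre_id"].isin(focal)) | (edges["post_id"].isin(focal))]
    out_pct = touching["weight"] / touching["pre_id"].map(total_out).astype(float) * 100.0
    keep = (touching["weight"] >= theta_w) & (out_pct > theta_pct)
    partners: set[str] = set()
    for row in touching[keep].itertuples(index=False):
        partners.add(row.pre_id)
        partners.add(row.post_id)
    # add-back for classes with known under-reconstruction
    addback = touching[
        (touching["weight"] >= theta_sens)
        & (
            touching["pre_id"].map(classes).isin(sensory_classes)
            | touching["post_id"].map(classes).isin(sensory_classes)
        )
    ]
    for row in addback.itertuples(index=False):
        if classes.get(row.pre_id) in sensory_classes:
            partners.add(row.pre_id)
        if classes.get(row.post_id) in sensory_classes:
            partners.add(row.post_id)
    nodes = sorted(focal | partners)
    node_set = set(nodes)

    sub = edges[(edges["pre_id"].isin(node_set)) & (edges["post_id"].isin(node_set))].copy()
    sub["input_pct"] = sub["weight"] / sub["post_id"].map(total_in).astype(float) * 100.0
    node_df = pd.DataFrame(
        {"node_id": nodes, "neuron_class": [classes.get(n, "IN") for n in nodes]}
    )
    return PartnerGraph(
        nodes=node_df,
        edges=sub.reset_index(drop=True),
        thresholds={"theta_w": theta_w, "theta_pct": theta_pct, "theta_sens": theta_sens},
    )


def average_by_type(graph: PartnerGraph, type_map: dict[str, str]) -> PartnerGraph:
    """Collapse a neuron-level partner graph to types.

    The type-to-type input percent is the mean of the member-level values
    over all (pre-member, post-member) combinations, absent edges counting
    as 0; invariant to member ordering.
    """
    untyped = [n for n in graph.nodes["node_id"] if n not in type_map]
    if untyped:
        raise ValueError(f"nodes without a type: {untyped[:5]}")
    members: dict[str, list[str]] = {}
    for n in graph.nodes["node_id"]:
        members.setdefault(type_map[n], []).append(n)
    edge_lookup: dict[tuple[str, str], tuple[float, float]] = {
        (r.pre_id, r.post_id): (r.weight, r.input_pct) for r in graph.edges.itertuples(index=False)
    }
    rows = []
    for t_pre, pre_members in members.items():
        for t_post, post_members in members.items():
            pairs = [(a, b) for a in pre_members for b in post_members if a != b]
            if not pairs:
                continue
            w = [edge_lookup.get(p, (0.0, 0.0))[0] for p in pairs]
            pct = [edge_lookup.get(p, (0.0, 0.0))[1] for p in pairs]
            if any(v > 0 for v in w):
                rows.append((t_pre, t_post, float(np.mean(w)), float(np.mean(pct))))
    class_of_type: dict[str, str] = {}
    for r in graph.nodes.itertuples(index=False):
        class_of_type.setdefault(type_map[r.node_id], r.neuron_class)
    node_df = pd.DataFrame(
        {
            "node_id": sorted(members),
            "neuron_class": [class_of_type[t] for t in sorted(members)],
        }
    )
    edge_df = pd.DataFrame(rows, columns=["pre_id", "post_id", "weight", "input_pct"])
    return PartnerGraph(nodes=node_df, edges=edge_df, thresholds=dict(graph.thresholds))


def class_composition(
    focal: set[str] | list[str],
    edges: pd.DataFrame,
    classes: dict[str, str],
    direction: str = "in",
) -> dict[str, float]:
    """Synapse-weighted partner-class composition of a focal set.

    direction "in": classes of presynaptic partners of the focal neurons;
    "out": classes of postsynaptic partners.  Fractions sum to 1; an empty
    partner set yields an empty dict.
    """
    focal = set(focal)
    if direction == "in":
        sub = edges[edges["post_id"].isin(focal) & ~edges["pre_id"].isin(focal)]
        partner_col = "pre_id"
    elif direction == "out":
        sub = edges[edges["pre_id"].isin(focal) & ~edges["post_id"].isin(focal)]
        partner_col = "post_id"
    else:
        raise ValueError(f"invalid direction {direction!r}")
    if sub.empty:
        return {}
    by_class = sub.groupby(sub[partner_col].map(classes))["weight"].sum()
    return (by_class / by_class.sum()).to_dict()


def stereotypy_stats(weights_a, weights_b) -> dict[str, float]:
    """Pearson r and through-origin best-fit slope for paired weights.

    slope = Σ a·b / Σ a² (least squares constrained through the origin);
    a free-intercept slope is reported alongside for comparison.  With
    fewer than 2 points or zero variance, r is NaN.
    """
    a = np.asarray(weights_a, float)
    b = np.asarray(weights_b, float)
    if a.shape != b.shape:
        raise ValueError("paired weight vectors must have equal length")
    out: dict[str, float] = {}
    denom = float(np.sum(a * a))
    out["slope_through_origin"] = float(np.sum(a * b) / denom) if denom > 0 else float("nan")
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        out["pearson_r"] = float("nan")
        out["slope_free"] = float("nan")
        return out
    out["pearson_r"] = float(stats.pearsonr(a, b).statistic)
    res = stats.linregress(a, b)
    out["slope_free"] = float(res.slope)
    return out


def effective_connectivity(
    sources: set[str] | list[str],
    targets: set[str] | list[str],
    edges: pd.DataFrame,
    max_hops: int = 2,
) -> pd.Series:
    """Multi-hop effective connectivity from sources onto each target.

    The adjacency is normalized to input fractions (edge weight over the
    receiving neuron's total input, in [0, 1]); the effective weight of a
    target sums the products of fractions along every path of 1..max_hops
    steps from any source.
    """
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    nodes = sorted(set(edges["pre_id"]) | set(edges["post_id"]) | set(sources) | set(targets))
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))  # M[post, pre] = input fraction
    total_in = edges.groupby("post_id")["weight"].sum()
    for row in edges.itertuples(index=False):
        M[index[row.post_id], index[row.pre_id]] = row.weight / float(total_in[row.post_id])
    src_vec = np.zeros(n)
    src_vec[[index[s] for s in sources]] = 1.0
    acc = np.zeros(n)
    v = src_vec
    for _ in range(max_hops):
        v = M @ v
        acc += v
    return pd.Series({t: acc[index[t]] for t in sorted(set(targets))}, name="effective_weight")


@dataclass
class DensityGrid:
    """3-D synapse count grid; origin and voxel size in nm."""

    origin: np.ndarray
    voxel: float
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def save(self, path) -> None:
        """Plain-text export: JSON header line, then flattened counts."""
        import json

        header = {
            "origin": self.origin.tolist(),
            "voxel": self.voxel,
            "shape": list(self.counts.shape),
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            np.savetxt(fh, self.counts.reshape(-1, 1), fmt="%d")


def synapse_density(
    synapses: pd.DataFrame,
    voxel: float = 5000.0,
    cleft_min: float | None = None,
) -> DensityGrid:
    """Count synapses on an isotropic voxel grid over their bounding box.

    The grid is anchored at the floor of the bounding box to voxel
    multiples, making the binning deterministic and translation-covariant.
    ``cleft_min`` applies a strict cleft-score > filter before counting.
    """
    df = synapses
    if cleft_min is not None:
        df = df[df["cleft_score"] > cleft_min]
    xyz = df[["x", "y", "z"]].to_numpy(float)
    if len(xyz) == 0:
        logger.warning("no synapses left after filtering; empty density grid")
        return DensityGrid(origin=np.zeros(3), voxel=voxel, counts=np.zeros((0, 0, 0), int))
    origin = np.floor(xyz.min(axis=0) / voxel) * voxel
    idx = np.floor((xyz - origin) / voxel).astype(int)
    shape = idx.max(axis=0) + 1
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, tuple(idx.T), 1)
    return DensityGrid(origin=origin, voxel=voxel, counts=counts)
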