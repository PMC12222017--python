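"""Rule-based anatomical annotation: soma side, neuropil codes, tracts.

The neuropil rules summarise where a neuron collects input or delivers
output.  Brain profiles use postsynapses for descending neurons (their
dendrites live in the brain) and presynapses for ascending neurons (their
axons terminate there); VNC profiles use the opposite role per class.

Brain rule: a single neuropil is assigned if it holds ≥ 80% of the
labelled synapses; a two-neuropil code (top_second) if the top two jointly
reach 80% and each holds at least 5%; otherwise "multi".

VNC rule: a single two-letter code if one neuropil holds > 80%; otherwise
"ut" (upper tectulum) or "xl" (leg neuropils) if the respective region set
jointly holds > 80%; otherwise "xn".  A neuron with only a soma and soma
tract in the VNC is coded "XA".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from neckconn.model import Skeleton

#: Default two-letter codes for VNC neuropils.  The source vocabulary has a
#: collision ("hl" historically used for both the haltere tectulum and the
#: hind-leg neuropil); this default disambiguates HTct as "ht" and keeps
#: "hl" for LegNpT3.  Override via the ``code_map`` argument if your
#: nomenclature differs.
DEFAULT_VNC_CODE_MAP = {
    "NTct": "nt",
    "WTct": "wt",
    "HTct": "ht",
    "IntTct": "it",
    "LTct": "lt",
    "LegNpT1": "fl",
    "LegNpT2": "ml",
    "LegNpT3": "hl",
    "mVAC": "mv",
    "Ov": "ov",
    "ANm": "ad",
}

#: role of the synapses that define the profile, per (cns_region, class)
PROFILE_ROLE = {
    ("brain", "DN"): "post",
    ("brain", "AN"): "pre",
    ("vnc", "DN"): "pre",
    ("vnc", "AN"): "post",
}


@dataclass
class NeuropilProfile:
    neuron_id: str
    role: str
    fractions: dict[str, float]
    assigned_code: str = ""


def synapse_fractions(synapses: pd.DataFrame, neuron_id: str, role: str) -> dict[str, float]:
    """Fraction of a neuron's synapses (of one role) per neuropil label.

    Synapses without a neuropil label are excluded from the denominator, so
    the fractions sum to 1 over labelled synapses.
    """
    sub = synapses[(synapses["neuron_id"] == neuron_id) & (synapses["role"] == role)]
    labelled = sub[sub["neuropil"].notna() & (sub["neuropil"] != "")]
    if labelled.empty:
        return {}
    counts = labelled["neuropil"].value_counts()
    return (counts / counts.sum()).to_dict()


def assign_soma_side(
    soma_xyz: np.ndarray | None,
    midline_x: float,
    delta: float = 2000.0,
    crossing_xyz: np.ndarray | None = None,
) -> str:
    """Programmatic side call from the soma, or the neck-plane crossing.

    Neurons whose soma was lost use the x position where they cross the
    neck plane.  Within ±delta of the midline the call is "center"; with
    neither point available it is "unknown".
    """
    point = soma_xyz if soma_xyz is not None else crossing_xyz
    if point is None:
        return "unknown"
    x = float(np.asarray(point, float).reshape(-1)[0])
    if x < midline_x - delta:
        return "left"
    if x > midline_x + delta:
        return "right"
    return "center"


def assign_brain_neuropil(
    fractions: dict[str, float],
    threshold: float = 0.80,
    pair_floor: float = 0.05,
) -> str:
    """Brain neuropil code from a synapse-fraction profile (≥ thresholds)."""
    if not fractions:
        return "unassigned"
    ranked = sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0]))
    top_label, top = ranked[0]
    if top >= threshold:
        return top_label
    if len(ranked) > 1:
        second_label, second = ranked[1]
        if top + second >= threshold and top >= pair_floor and second >= pair_floor:
            return f"{top_label}_{second_label}"
    return "multi"


def assign_vnc_neuropil(
    fractions: dict[str, float],
    region_sets: dict[str, set[str]],
    soma_only: bool = False,
    threshold: float = 0.80,
    code_map: dict[str, str] | None = None,
) -> str:
    """VNC neuropil code from a synapse-fraction profile (strict > threshold).

    ``region_sets`` must provide ``upper_tectulum`` and ``leg_neuropils``.
    ``soma_only`` neurons (soma and soma tract only in the VNC) are "XA".
    """
    if soma_only:
        return "XA"
    if not fractions:
        return "unassigned"
    code_map = DEFAULT_VNC_CODE_MAP if code_map is None else code_map
    ranked = sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0]))
    top_label, top = ranked[0]
    if top > threshold:
        return code_map.get(top_label, top_label.lower()[:2])
    ut = sum(v for k, v in fractions.items() if k in region_sets.get("upper_tectulum", set()))
    if ut > threshold:
        return "ut"
    xl = sum(v for k, v in fractions.items() if k in region_sets.get("leg_neuropils", set()))
    if xl > threshold:
        return "xl"
    return "xn"


def assign_group_neuropil(
    members: list[dict[str, float]],
    rule,
    **rule_kwargs,
) -> str:
    """Resolve an inconsistent group by re-applying the rule to the mean profile.

    ``rule`` is :func:`assign_brain_neuropil` or :func:`assign_vnc_neuropil`;
    the member fraction vectors are averaged label-wise (equal member
    weight), which is permutation-invariant by construction.
    """
    if not members:
        return "unassigned"
    labels = sorted({k for m in members for k in m})
    mean = {lab: float(np.mean([m.get(lab, 0.0) for m in members])) for lab in labels}
    return rule(mean, **rule_kwargs)


def profile_neuron(
    synapses: pd.DataFrame,
    neuron_id: str,
    cns_region: str,
    neuron_class: str,
    region_sets: dict[str, set[str]] | None = None,
    soma_only: bool = False,
    **kwargs,
) -> NeuropilProfile:
    """Compute the synapse profile and code for one neuron in one CNS region."""
    role = PROFILE_ROLE.get((cns_region, neuron_class), "pre")
    fractions = synapse_fractions(synapses, neuron_id, role)
    if cns_region == "brain":
        code = assign_brain_neuropil(fractions, **kwargs)
    else:
        code = assign_vnc_neuropil(fractions, region_sets or {}, soma_only=soma_only, **kwargs)
    return NeuropilProfile(neuron_id=neuron_id, role=role, fractions=fractions, assigned_code=code)


# ---------------------------------------------------------------------------
# Tract assignment


@dataclass
class TractSet:
    """Named longitudinal tracts, each given by a centerline polyline (nm)."""

    tracts: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        self.tracts = [(name, np.atleast_2d(np.asarray(line, float))) for name, line in self.tracts]
        for name, line in self.tracts:
            if len(line) < 2:
                raise ValueError(f"tract {name} centerline needs >= 2 points")


def longest_neurite(skeleton: Skeleton, entry_node: int) -> np.ndarray:
    """Longest cable path from the entry node to any leaf, as xyz polyline.

    The tree is treated as an undirected graph (the entry need not be the
    SWC root); returns the node positions along the maximal-length path.
    """
    nodes = skeleton.nodes
    ids = nodes["node_id"].to_numpy()
    pos = {int(n): i for i, n in enumerate(ids)}
    xyz = skeleton.xyz()
    adj: dict[int, list[tuple[int, float]]] = {int(n): [] for n in ids}
    for nid, pid in zip(ids, nodes["parent_id"].to_numpy()):
        if pid == -1:
            continue
        d = float(np.linalg.norm(xyz[pos[int(nid)]] - xyz[pos[int(pid)]]))
        adj[int(nid)].append((int(pid), d))
        adj[int(pid)].append((int(nid), d))
    # iterative DFS tracking the best (longest) path to any node
    best_len = -1.0
    best_path: list[int] = [entry_node]
    stack = [(entry_node, -1, 0.0, [entry_node])]
    while stack:
        cur, prev, dist, path = stack.pop()
        extended = False
        for nxt, d in adj[cur]:
            if nxt != prev:
                stack.append((nxt, cur, dist + d, path + [nxt]))
                extended = True
        if not extended and dist > best_len:
            best_len = dist
            best_path = path
    return np.array([xyz[pos[n]] for n in best_path])


def assign_tract(
    skeleton: Skeleton,
    entry_point: np.ndarray,
    tracts: TractSet,
    entry_tol: float = 5000.0,
    sample_step: float = 1000.0,
) -> tuple[str, float]:
    """Assign a longitudinal tract to a neuron.

    The skeleton is simplified to its longest neurite from the node nearest
    the VNC entry point; the assignment is the tract whose (densely
    resampled) centerline lies at minimal mean closest-point distance to
    that path.  Returns (tract name, mean distance in nm).
    """
    if not tracts.tracts:
        raise ValueError("no tracts supplied")
    entry_point = np.asarray(entry_point, float)
    xyz = skeleton.xyz()
    d_entry = np.linalg.norm(xyz - entry_point, axis=1)
    i_entry = int(np.argmin(d_entry))
    if d_entry[i_entry] > entry_tol:
        raise ValueError(
            f"entry point is {d_entry[i_entry]:.0f} nm from the nearest node (> {entry_tol:.0f})"
        )
    entry_node = int(skeleton.nodes["node_id"].iloc[i_entry])
    path = longest_neurite(skeleton, entry_node)
    best_name, best_dist = "", np.inf
    for name, line in tracts.tracts:
        dense = _resample_polyline(line, sample_step)
        tree = cKDTree(dense)
        dist, _ = tree.query(path, k=1)
        mean_d = float(np.mean(dist))
        if mean_d < best_dist:
            best_name, best_dist = name, mean_d
    return best_name, best_dist


def _resample_polyline(line: np.ndarray, step: float) -> np.ndarray:
    segs = np.diff(line, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    out = [line[0]]
    for a, seg, L in zip(line[:-1], segs, lens):
        n = max(1, int(np.ceil(L / step)))
        ts = np.arange(1, n + 1) / n
        out.extend(a + t * seg for t in ts)
    return np.asarray(out)
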