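"""Neuron matching: left-right pairing, cross-dataset homologues,
confidence scoring and sex-specific / sexually dimorphic classification.

Within a dataset, left neurons are mirrored about the midline and scored
against the right cohort with mean-normalized NBLAST; mutual best hits
above a threshold become pairs, and neurons whose top candidates are
nearly tied are merged into larger groups (populations that cannot be
resolved into pairs).

Across datasets, one dataset's morphologies are carried into the other's
space by a landmark thin-plate-spline, and candidates are scored by a
weighted combination of morphology (mean-normalized NBLAST) and
connectivity similarity (cosine over partner-type fingerprints).  A greedy
mutual-best assignment by descending combined score yields homologue
matches with a 1-5 confidence (high is > 3).

Types that confidently match but differ strongly in morphology are called
sexually dimorphic; well-reconstructed types with a left-right partner that
cannot be matched across datasets are called sex-specific.  Neurons
presumed neuropeptidergic, ascending histaminergic neurons and neurons
innervating the abdominal ganglion are excluded from these calls, and a
difference in member count of a matched type is recorded as biological
variation, not dimorphism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neckconn.model import Dataset, parse_flags
from neckconn.morpho import (
    Dotprops,
    GaussScoreFunction,
    nblast_pairwise,
    skeleton_to_dotprops,
)

EXCLUSION_FLAGS = ("neuropeptidergic", "ahn", "abdominal_innervation")

#: label for an unmatched type awaiting a new systematic name; numbering
#: counts down from 999 to avoid clashing with established type numbers
NEW_TYPE_START = 999


@dataclass
class MatchRecord:
    id_a: str
    id_b: str | None
    morph_score: float
    conn_score: float
    combined: float
    confidence: int | None
    status: str  # matched | unmatched

    def __post_init__(self) -> None:
        if (self.status == "matched") != (self.confidence is not None):
            raise ValueError("confidence must be present iff matched")


@dataclass
class PairingResult:
    pairs: list[tuple[str, str, float]]
    groups: list[set[str]]
    unpaired: list[str]
    scores: pd.DataFrame


@dataclass
class DimorphismLabel:
    entity: str  # neuron_id or type_label
    label: str
    rationale: str = ""


def new_type_namer(prefix: str = "DNxn", start: int = NEW_TYPE_START):
    """Generator of systematic names for unmatched types: 999 counting down."""
    n = start
    while n > 0:
        yield f"{prefix}{n:03d}"
        n -= 1


# ---------------------------------------------------------------------------
# dotprops cache


def cohort_dotprops(
    dataset: Dataset,
    neuron_ids: list[str],
    resample_step: float = 1000.0,
    k: int = 5,
) -> dict[str, Dotprops]:
    out = {}
    for nid in neuron_ids:
        skel = dataset.skeletons.get(nid)
        if skel is not None and skel.n_nodes >= 2:
            out[nid] = skeleton_to_dotprops(skel, resample_step=resample_step, k=k)
    return out


# ---------------------------------------------------------------------------
# Left-right pairing


def pair_left_right(
    dataset: Dataset,
    neuron_ids: list[str] | None = None,
    score_fn=None,
    theta_pair: float = 0.4,
    delta_group: float = 0.05,
    resample_step: float = 1000.0,
    k: int = 5,
    dotprops: dict[str, Dotprops] | None = None,
) -> PairingResult:
    """Pair left against mirrored right homologues within one dataset.

    Mutual best NBLAST hits with score ≥ ``theta_pair`` become pairs; a
    neuron whose top two candidate scores differ by less than
    ``delta_group`` is ambiguous and is merged with its candidates into a
    larger group.  Everything else is flagged unpaired.
    """
    if score_fn is None:
        score_fn = GaussScoreFunction()
    neurons = dataset.neurons
    if neuron_ids is not None:
        neurons = neurons[neurons["neuron_id"].isin(neuron_ids)]
    left_ids = neurons.loc[neurons["side"] == "left", "neuron_id"].tolist()
    right_ids = neurons.loc[neurons["side"] == "right", "neuron_id"].tolist()
    if not left_ids or not right_ids:
        raise ValueError("need neurons on both sides to pair")
    if dotprops is None:
        dotprops = cohort_dotprops(dataset, left_ids + right_ids, resample_step, k)
    midline = dataset.atlas.midline_x
    left_dp = {n: dotprops[n].mirror(midline) for n in left_ids if n in dotprops}
    right_dp = {n: dotprops[n] for n in right_ids if n in dotprops}
    if not left_dp or not right_dp:
        raise ValueError("no skeletons available on one side")

    sm = nblast_pairwise(left_dp, right_dp, score_fn)
    S = sm.data  # rows: left, cols: right

    ambiguous: set[str] = set()
    group_links: list[tuple[str, str]] = []

    def top_two(scores: pd.Series) -> tuple[list[str], list[float]]:
        order = scores.sort_values(ascending=False)
        return list(order.index[:2]), list(order.values[:2])

    for lid in S.index:
        cands, vals = top_two(S.loc[lid])
        if len(vals) > 1 and vals[0] - vals[1] < delta_group and vals[1] >= theta_pair:
            ambiguous.add(lid)
            group_links += [(lid, c) for c, v in zip(cands, vals) if v >= theta_pair]
    for rid in S.columns:
        cands, vals = top_two(S[rid])
        if len(vals) > 1 and vals[0] - vals[1] < delta_group and vals[1] >= theta_pair:
            ambiguous.add(rid)
            group_links += [(rid, c) for c, v in zip(cands, vals) if v >= theta_pair]

    pairs: list[tuple[str, str, float]] = []
    paired: set[str] = set()
    for lid in S.index:
        rid = S.loc[lid].idxmax()
        if S[rid].idxmax() != lid:
            continue
        score = float(S.at[lid, rid])
        if score < theta_pair:
            continue
        if lid in ambiguous or rid in ambiguous:
            group_links.append((lid, rid))
            continue
        pairs.append((lid, rid, score))
        paired.update((lid, rid))

    groups = _union_groups(group_links)
    grouped = {m for g in groups for m in g}
    unpaired = [n for n in list(S.index) + list(S.columns) if n not in paired and n not in grouped]
    return PairingResult(pairs=pairs, groups=groups, unpaired=unpaired, scores=S)


def _union_groups(links: list[tuple[str, str]]) -> list[set[str]]:
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in links:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, set[str]] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    return sorted((g for g in groups.values() if len(g) > 1), key=lambda g: sorted(g)[0])


# ---------------------------------------------------------------------------
# Connectivity fingerprints


def connectivity_fingerprint(
    neuron_id: str,
    edges: pd.DataFrame,
    type_map: dict[str, str],
    direction: str = "both",
) -> pd.Series:
    """Partner-type weight profile of one neuron, normalized per direction.

    For each partner type, the summed synapse weight divided by the
    neuron's total weight in that direction; "both" concatenates the input
    and output profiles (keys prefixed ``in:`` / ``out:``).  An isolated
    neuron yields an all-zero vector.
    """
    if direction not in ("in", "out", "both"):
        raise ValueError(f"invalid direction {direction!r}")
    parts = []
    if direction in ("in", "both"):
        sub = edges[edges["post_id"] == neuron_id]
        parts.append(("in:", sub, "pre_id"))
    if direction in ("out", "both"):
        sub = edges[edges["pre_id"] == neuron_id]
        parts.append(("out:", sub, "post_id"))
    chunks = []
    for prefix, sub, col in parts:
        typed = sub[sub[col].map(type_map).notna()]
        total = typed["weight"].sum()
        if total > 0:
            s = typed.groupby(typed[col].map(type_map))["weight"].sum() / total
        else:
            s = pd.Series(dtype=float)
        s.index = [f"{prefix}{t}" if direction == "both" else t for t in s.index]
        chunks.append(s)
    if not chunks:
        return pd.Series(dtype=float)
    return pd.concat(chunks)


def cosine(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> float:
    """Cosine similarity in [0, 1] for non-negative vectors; 0 for zero vectors."""
    if isinstance(a, pd.Series) or isinstance(b, pd.Series):
        a = pd.Series(a, dtype=float)
        b = pd.Series(b, dtype=float)
        idx = a.index.union(b.index)
        a = a.reindex(idx, fill_value=0.0).to_numpy()
        b = b.reindex(idx, fill_value=0.0).to_numpy()
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# Cross-dataset matching


def confidence_bin(combined: float, edges: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)) -> int:
    """Map a combined score to the 1-5 confidence scale (high is > 3)."""
    return 1 + int(np.searchsorted(np.asarray(edges), combined, side="right"))


def cross_dataset_match(
    ds_a: Dataset,
    ds_b: Dataset,
    tps,
    weights: tuple[float, float] = (0.7, 0.3),
    theta_match: float = 0.4,
    score_fn=None,
    resample_step: float = 1000.0,
    k: int = 5,
    confidence_edges: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    classes: tuple[str, ...] = ("DN", "AN", "SA"),
    dotprops_a: dict[str, Dotprops] | None = None,
    dotprops_b: dict[str, Dotprops] | None = None,
) -> list[MatchRecord]:
    """Match neurons of ``ds_a`` to homologues in ``ds_b``.

    ds_a morphologies are transformed into ds_b space via ``tps`` before
    NBLAST; connectivity fingerprints are compared over shared partner-type
    labels.  Candidates are restricted to the same neuron class.  Greedy
    mutual-best assignment by descending combined score; candidates below
    ``theta_match`` stay unmatched.
    """
    w_m, w_c = weights
    if not math.isclose(w_m + w_c, 1.0, abs_tol=1e-9):
        raise ValueError(f"weights must sum to 1, got {w_m} + {w_c}")
    if tps is None:
        raise ValueError("missing landmark transform")
    if score_fn is None:
        score_fn = GaussScoreFunction()

    meta_a = ds_a.neurons[ds_a.neurons["neuron_class"].isin(classes)]
    meta_b = ds_b.neurons[ds_b.neurons["neuron_class"].isin(classes)]
    ids_a = meta_a["neuron_id"].tolist()
    ids_b = meta_b["neuron_id"].tolist()
    class_a = dict(zip(meta_a["neuron_id"], meta_a["neuron_class"]))
    class_b = dict(zip(meta_b["neuron_id"], meta_b["neuron_class"]))

    if dotprops_a is None:
        dotprops_a = cohort_dotprops(ds_a, ids_a, resample_step, k)
    if dotprops_b is None:
        dotprops_b = cohort_dotprops(ds_b, ids_b, resample_step, k)
    dp_a = {n: dotprops_a[n].transform(tps) for n in ids_a if n in dotprops_a}
    dp_b = {n: dotprops_b[n] for n in ids_b if n in dotprops_b}

    type_map_a = dict(zip(ds_a.neurons["neuron_id"], ds_a.neurons["type_label"]))
    type_map_b = dict(zip(ds_b.neurons["neuron_id"], ds_b.neurons["type_label"]))
    fp_a = {n: connectivity_fingerprint(n, ds_a.edges, type_map_a) for n in dp_a}
    fp_b = {n: connectivity_fingerprint(n, ds_b.edges, type_map_b) for n in dp_b}

    candidates: list[tuple[float, float, float, str, str]] = []
    morph_cache: dict[tuple[str, str], tuple[float, float]] = {}
    for cls in classes:
        sub_a = {n: dp_a[n] for n in dp_a if class_a.get(n) == cls}
        sub_b = {n: dp_b[n] for n in dp_b if class_b.get(n) == cls}
        if not sub_a or not sub_b:
            continue
        sm = nblast_pairwise(sub_a, sub_b, score_fn)
        for a in sm.data.index:
            for b in sm.data.columns:
                morph = float(sm.data.at[a, b])
                conn = cosine(fp_a[a], fp_b[b])
                combined = w_m * morph + w_c * conn
                morph_cache[(a, b)] = (morph, conn)
                candidates.append((combined, morph, conn, a, b))

    candidates.sort(key=lambda t: (-t[0], t[3], t[4]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    records: list[MatchRecord] = []
    best_unmatched_a: dict[str, tuple[float, float, float]] = {}
    best_unmatched_b: dict[str, tuple[float, float, float]] = {}
    for combined, morph, conn, a, b in candidates:
        if a in used_a or b in used_b:
            continue
        if combined >= theta_match:
            used_a.add(a)
            used_b.add(b)
            records.append(
                MatchRecord(
                    id_a=a,
                    id_b=b,
                    morph_score=morph,
                    conn_score=conn,
                    combined=combined,
                    confidence=confidence_bin(combined, confidence_edges),
                    status="matched",
                )
            )
        else:
            best_unmatched_a.setdefault(a, (combined, morph, conn))
            best_unmatched_b.setdefault(b, (combined, morph, conn))
    for a in dp_a:
        if a not in used_a:
            combined, morph, conn = best_unmatched_a.get(a, (0.0, 0.0, 0.0))
            records.append(
                MatchRecord(a, None, morph, conn, combined, None, "unmatched")
            )
    for b in dp_b:
        if b not in used_b:
            combined, morph, conn = best_unmatched_b.get(b, (0.0, 0.0, 0.0))
            records.append(
                MatchRecord(b, None, morph, conn, combined, None, "unmatched")
            )
    return records


# ---------------------------------------------------------------------------
# Dimorphism classification


@dataclass
class TypeContext:
    """Per-type evidence assembled for the dimorphism decision cascade."""

    type_label: str
    members_a: list[str] = field(default_factory=list)
    members_b: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    well_reconstructed: bool = True
    has_lr_partner: bool = False
    matched_morphs: list[float] = field(default_factory=list)


def classify_dimorphism(
    records: list[MatchRecord],
    ds_a: Dataset,
    ds_b: Dataset,
    pairing_a: PairingResult | None = None,
    pairing_b: PairingResult | None = None,
    tau_d: float = 0.5,
    min_nodes: int = 50,
    classes: tuple[str, ...] = ("DN", "AN", "SA"),
) -> list[DimorphismLabel]:
    """Classify every type (and by extension every neuron) for sex differences.

    Decision cascade, in order:

    1. any member flagged neuropeptidergic / AHN / abdominal → ``excluded``
    2. type unmatched across datasets and not well reconstructed →
       ``reconstruction_issue``
    3. type unmatched, well reconstructed, with a left-right partner →
       ``sex_specific``
    4. matched but mean morphology score < tau_d → ``sexually_dimorphic``
    5. matched with unequal member counts across datasets →
       ``biological_variation``
    6. otherwise ``matched_monomorphic``

    "Well reconstructed" means no ``truncated`` flag and a skeleton of at
    least ``min_nodes`` nodes.  Returns one label per neuron; the per-type
    call is carried in the rationale.
    """
    matched_ids = {r.id_a for r in records if r.status == "matched"} | {
        r.id_b for r in records if r.status == "matched"
    }

    paired_ids: set[str] = set()
    for pr in (pairing_a, pairing_b):
        if pr is not None:
            paired_ids |= {n for p in pr.pairs for n in p[:2]}
            paired_ids |= {n for g in pr.groups for n in g}

    contexts: dict[str, TypeContext] = {}

    def well_reconstructed(ds: Dataset, nid: str) -> bool:
        if "truncated" in parse_flags(
            ds.neurons.set_index("neuron_id").at[nid, "flags"]
        ):
            return False
        skel = ds.skeletons.get(nid)
        return skel is not None and skel.n_nodes >= min_nodes

    for ds, attr in ((ds_a, "members_a"), (ds_b, "members_b")):
        for row in ds.neurons.itertuples(index=False):
            t = row.type_label
            if row.neuron_class not in classes:
                continue
            if t is None or (isinstance(t, float) and np.isnan(t)):
                continue
            ctx = contexts.setdefault(t, TypeContext(type_label=t))
            getattr(ctx, attr).append(row.neuron_id)
            ctx.flags |= set(parse_flags(row.flags)) & set(EXCLUSION_FLAGS)
            if not well_reconstructed(ds, row.neuron_id):
                ctx.well_reconstructed = False
            if row.neuron_id in paired_ids:
                ctx.has_lr_partner = True

    type_of: dict[str, str] = {}
    for ds in (ds_a, ds_b):
        for row in ds.neurons.itertuples(index=False):
            type_of[row.neuron_id] = row.type_label
    for r in records:
        if r.status == "matched":
            t = type_of.get(r.id_a)
            if t is not None and t in contexts:
                contexts[t].matched_morphs.append(r.morph_score)

    type_label_of: dict[str, tuple[str, str]] = {}
    for ctx in contexts.values():
        n_matched = len(ctx.matched_morphs)
        if ctx.flags:
            call = ("excluded", f"flag:{';'.join(sorted(ctx.flags))}")
        elif n_matched == 0 and not ctx.well_reconstructed:
            call = ("reconstruction_issue", "unmatched_and_not_well_reconstructed")
        elif n_matched == 0 and ctx.has_lr_partner:
            call = ("sex_specific", "unmatched_well_reconstructed_with_lr_partner")
        elif n_matched == 0:
            call = ("reconstruction_issue", "unmatched_without_lr_partner")
        elif float(np.mean(ctx.matched_morphs)) < tau_d:
            call = ("sexually_dimorphic", f"mean_morph={np.mean(ctx.matched_morphs):.3f}<{tau_d}")
        elif ctx.members_a and ctx.members_b and len(ctx.members_a) != len(ctx.members_b):
            call = (
                "biological_variation",
                f"member_counts={len(ctx.members_a)}vs{len(ctx.members_b)}",
            )
        else:
            call = ("matched_monomorphic", "")
        type_label_of[ctx.type_label] = call

    labels: list[DimorphismLabel] = []
    seen: set[str] = set()
    for ds in (ds_a, ds_b):
        for row in ds.neurons.itertuples(index=False):
            if row.neuron_class not in classes or row.neuron_id in seen:
                continue
            seen.add(row.neuron_id)
            t = row.type_label
            if t in type_label_of:
                label, why = type_label_of[t]
                labels.append(
                    DimorphismLabel(entity=row.neuron_id, label=label, rationale=f"type={t};{why}")
                )
    return labels
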