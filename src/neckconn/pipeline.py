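"""End-to-end orchestration of the comparative-connectomics analysis.

``run_pipeline`` chains annotation (sides, neuropil codes, tracts),
left-right pairing, cross-dataset homologue matching, dimorphism
classification, information-flow ranking and connectivity summaries, and
returns every stage's table.  ``evaluate`` scores a run against the
synthetic generator's planted ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neckconn import annotate as ann
from neckconn import connectivity as conn
from neckconn import flowrank as fr
from neckconn import matchpipe as mp
from neckconn.model import Dataset
from neckconn.morpho import GaussScoreFunction, fit_tps
from neckconn.synthgen import GroundTruth, make_tracts

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters in one validated block."""

    # morphology
    resample_step: float = 1000.0
    k: int = 5
    score_sigma: float = 3000.0
    score_c: float = 0.1
    # pairing
    theta_pair: float = 0.4
    delta_group: float = 0.05
    # cross-dataset matching
    w_m: float = 0.7
    w_c: float = 0.3
    theta_match: float = 0.4
    confidence_edges: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    # dimorphism
    tau_d: float = 0.5
    min_nodes: int = 50
    # annotation
    side_delta: float = 2000.0
    # flow ranking
    f_max: float = 0.3
    runs: int = 100
    max_step: int = 20
    # connectivity
    theta_w: int = 10
    theta_pct: float = 0.5
    theta_sens: int = 5
    voxel: float = 5000.0
    cleft_min: float | None = 50.0
    # clustering
    linkage: str = "ward"
    cut_height: float = 5.0
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if abs(self.w_m + self.w_c - 1.0) > 1e-9:
            raise ValueError(f"w_m + w_c must equal 1, got {self.w_m} + {self.w_c}")
        if not 0 < self.f_max <= 1:
            raise ValueError("f_max must be in (0, 1]")
        if self.runs < 1 or self.max_step < 1:
            raise ValueError("runs and max_step must be >= 1")
        for name in ("theta_pair", "theta_match", "tau_d"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [-1, 1], got {v}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


FOCAL_CLASSES = ("DN", "AN")


@dataclass
class RunResult:
    config: RunConfig
    annotations: dict[str, pd.DataFrame]
    pairings: dict[str, mp.PairingResult]
    matches: list[mp.MatchRecord]
    dimorphism: pd.DataFrame
    ranks: dict[str, pd.DataFrame]
    type_ranks: dict[str, pd.DataFrame]
    rank_clusters: dict[str, pd.Series]
    stereotypy: dict[str, dict[str, float]]
    density: dict[str, conn.DensityGrid]
    summary: dict = field(default_factory=dict)

    def match_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id_a": r.id_a,
                    "id_b": r.id_b if r.id_b is not None else "",
                    "morph_score": r.morph_score,
                    "conn_score": r.conn_score,
                    "combined": r.combined,
                    "confidence": r.confidence if r.confidence is not None else "",
                    "status": r.status,
                }
                for r in self.matches
            ]
        )


def annotate_dataset(ds: Dataset, config: RunConfig, tracts=None) -> pd.DataFrame:
    """Per-neuron side, VNC neuropil code and tract for the focal classes."""
    if tracts is None:
        tracts = make_tracts()
    rows = []
    focal = ds.neurons[ds.neurons["neuron_class"].isin(FOCAL_CLASSES)]
    for row in focal.itertuples(index=False):
        nid = row.neuron_id
        skel = ds.skeletons.get(nid)
        soma = None
        if not (isinstance(row.soma_x, float) and np.isnan(row.soma_x)):
            soma = np.array([row.soma_x, row.soma_y, row.soma_z])
        crossing = None
        if skel is not None and skel.n_nodes:
            root = skel.nodes.loc[skel.nodes["parent_id"] == -1]
            if len(root):
                crossing = root.iloc[0][["x", "y", "z"]].to_numpy(float)
        side = ann.assign_soma_side(
            soma, ds.atlas.midline_x, delta=config.side_delta, crossing_xyz=crossing
        )
        profile = ann.profile_neuron(
            ds.synapses,
            nid,
            cns_region="vnc",
            neuron_class=row.neuron_class,
            region_sets=ds.atlas.region_sets,
        )
        tract_name, tract_dist = "", float("nan")
        if skel is not None and crossing is not None:
            try:
                tract_name, tract_dist = ann.assign_tract(skel, crossing, tracts)
            except ValueError:
                pass
        rows.append(
            {
                "neuron_id": nid,
                "side": side,
                "neuropil_code": profile.assigned_code,
                "tract": tract_name,
                "tract_dist_nm": tract_dist,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    ds_a: Dataset,
    ds_b: Dataset,
    config: RunConfig | None = None,
    tracts=None,
) -> RunResult:
    """Execute all stages on a dataset pair (A is registered into B space)."""
    if config is None:
        config = RunConfig()
    config.validate()
    score_fn = GaussScoreFunction(sigma=config.score_sigma, c=config.score_c)
    if tracts is None:
        tracts = make_tracts()

    annotations: dict[str, pd.DataFrame] = {}
    pairings: dict[str, mp.PairingResult] = {}
    dotprops: dict[str, dict] = {}
    for ds in (ds_a, ds_b):
        logger.info("annotating dataset %s", ds.dataset_id)
        anno = annotate_dataset(ds, config, tracts)
        annotations[ds.dataset_id] = anno
        # apply freshly derived sides before pairing
        side_map = dict(zip(anno["neuron_id"], anno["side"]))
        ds.neurons["side"] = [
            side_map.get(n, s) for n, s in zip(ds.neurons["neuron_id"], ds.neurons["side"])
        ]
        focal_ids = ds.neurons.loc[
            ds.neurons["neuron_class"].isin(FOCAL_CLASSES), "neuron_id"
        ].tolist()
        dps = mp.cohort_dotprops(ds, focal_ids, config.resample_step, config.k)
        dotprops[ds.dataset_id] = dps
        logger.info("pairing dataset %s (theta_pair=%s)", ds.dataset_id, config.theta_pair)
        pairings[ds.dataset_id] = mp.pair_left_right(
            ds,
            neuron_ids=focal_ids,
            score_fn=score_fn,
            theta_pair=config.theta_pair,
            delta_group=config.delta_group,
            dotprops=dps,
        )

    if ds_a.landmarks is None:
        raise ValueError("dataset A carries no landmark table; cannot register")
    src = ds_a.landmarks[["x_src", "y_src", "z_src"]].to_numpy(float)
    dst = ds_a.landmarks[["x_dst", "y_dst", "z_dst"]].to_numpy(float)
    tps = fit_tps(src, dst)
    logger.info("matching %s -> %s (theta_match=%s)", ds_a.dataset_id, ds_b.dataset_id, config.theta_match)
    matches = mp.cross_dataset_match(
        ds_a,
        ds_b,
        tps,
        weights=(config.w_m, config.w_c),
        theta_match=config.theta_match,
        score_fn=score_fn,
        confidence_edges=config.confidence_edges,
        classes=FOCAL_CLASSES,
        dotprops_a=dotprops[ds_a.dataset_id],
        dotprops_b=dotprops[ds_b.dataset_id],
    )
    labels = mp.classify_dimorphism(
        matches,
        ds_a,
        ds_b,
        pairing_a=pairings[ds_a.dataset_id],
        pairing_b=pairings[ds_b.dataset_id],
        tau_d=config.tau_d,
        min_nodes=config.min_nodes,
    )
    dimorphism = pd.DataFrame(
        [{"neuron_id": l.entity, "label": l.label, "rationale": l.rationale} for l in labels]
    )

    ranks: dict[str, pd.DataFrame] = {}
    type_ranks: dict[str, pd.DataFrame] = {}
    rank_clusters: dict[str, pd.Series] = {}
    for ds in (ds_a, ds_b):
        if ds.seeds is None or ds.seeds.empty:
            continue
        seeds = {m: set(g["neuron_id"]) for m, g in ds.seeds.groupby("modality")}
        r = fr.information_flow_rank(
            ds.edges,
            seeds,
            f_max=config.f_max,
            runs=config.runs,
            max_step=config.max_step,
            seed=config.seed,
        )
        ranks[ds.dataset_id] = r
        type_map = dict(zip(ds.neurons["neuron_id"], ds.neurons["type_label"]))
        focal = [n for n in r.index if n in type_map and type_map[n] is not None]
        tr = fr.average_rank_by_type(r.loc[focal], type_map)
        type_ranks[ds.dataset_id] = tr
        if len(tr) > 1:
            rank_clusters[ds.dataset_id] = fr.cluster_by_rank(
                tr, height=config.cut_height, method=config.linkage
            )

    stereotypy: dict[str, dict[str, float]] = {}
    for ds, pairing in ((ds_a, pairings[ds_a.dataset_id]), (ds_b, pairings[ds_b.dataset_id])):
        a, b = _paired_output_weights(ds, pairing)
        if len(a) >= 2:
            stereotypy[ds.dataset_id] = conn.stereotypy_stats(a, b)

    density: dict[str, conn.DensityGrid] = {}
    for ds in (ds_a, ds_b):
        if len(ds.synapses):
            density[ds.dataset_id] = conn.synapse_density(
                ds.synapses, voxel=config.voxel, cleft_min=config.cleft_min
            )

    summary = {
        "config_hash": config.hash(),
        "n_pairs": {d: len(p.pairs) for d, p in pairings.items()},
        "n_groups": {d: len(p.groups) for d, p in pairings.items()},
        "n_matched": sum(1 for r in matches if r.status == "matched"),
        "n_unmatched": sum(1 for r in matches if r.status == "unmatched"),
        "dimorphism_counts": dimorphism["label"].value_counts().to_dict(),
        "stereotypy": stereotypy,
    }
    return RunResult(
        config=config,
        annotations=annotations,
        pairings=pairings,
        matches=matches,
        dimorphism=dimorphism,
        ranks=ranks,
        type_ranks=type_ranks,
        rank_clusters=rank_clusters,
        stereotypy=stereotypy,
        density=density,
        summary=summary,
    )


def _paired_output_weights(ds: Dataset, pairing: mp.PairingResult):
    """Paired left/right output weights onto shared partner types."""
    type_map = dict(zip(ds.neurons["neuron_id"], ds.neurons["type_label"]))
    a_vals, b_vals = [], []
    out = ds.edges.groupby(["pre_id", ds.edges["post_id"].map(type_map)])["weight"].sum()
    for left, right, _ in pairing.pairs:
        wl = out.loc[left] if left in out.index.get_level_values(0) else pd.Series(dtype=float)
        wr = out.loc[right] if right in out.index.get_level_values(0) else pd.Series(dtype=float)
        partners = wl.index.union(wr.index)
        for p in partners:
            a_vals.append(float(wl.get(p, 0.0)))
            b_vals.append(float(wr.get(p, 0.0)))
    return np.array(a_vals), np.array(b_vals)


def write_outputs(result: RunResult, out_dir: str | Path) -> None:
    """Write every stage table to ``out_dir`` as TSV plus a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ds_id, anno in result.annotations.items():
        anno.to_csv(out_dir / f"annotations_{ds_id}.tsv", sep="\t", index=False)
    for ds_id, pairing in result.pairings.items():
        pd.DataFrame(pairing.pairs, columns=["left_id", "right_id", "score"]).to_csv(
            out_dir / f"pairs_{ds_id}.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [{"group": i, "members": ";".join(sorted(g))} for i, g in enumerate(pairing.groups)]
        ).to_csv(out_dir / f"groups_{ds_id}.tsv", sep="\t", index=False)
    result.match_table().to_csv(out_dir / "matches.tsv", sep="\t", index=False)
    result.dimorphism.to_csv(out_dir / "dimorphism.tsv", sep="\t", index=False)
    for ds_id, r in result.ranks.items():
        r.to_csv(out_dir / f"ranks_{ds_id}.tsv", sep="\t")
    for ds_id, tr in result.type_ranks.items():
        tr.to_csv(out_dir / f"type_ranks_{ds_id}.tsv", sep="\t")
    for ds_id, cl in result.rank_clusters.items():
        cl.to_csv(out_dir / f"rank_clusters_{ds_id}.tsv", sep="\t")
    for ds_id, grid in result.density.items():
        grid.save(out_dir / f"density_{ds_id}.txt")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Evaluation against planted truth


def evaluate(result: RunResult, truth: GroundTruth, ds_a: Dataset, ds_b: Dataset) -> dict:
    """Score a pipeline run against the generator's planted ground truth.

    A predicted left-right pair is correct if it appears in the truth pair
    table; it is a *false pair* only if its two members belong to different
    planted types (pairing identically generated members of a population
    type is not an error — the planted truth for those is a group).
    Homologue recall is the fraction of planted cross-dataset homologues
    whose dataset-A member was matched to a dataset-B neuron of the same
    planted type; precision is the fraction of predicted matches linking
    equal types.
    """
    metrics: dict = {}
    truth_type = dict(zip(truth.neurons["neuron_id"], truth.neurons["type"]))

    # --- left-right pairing
    truth_pairs = {
        (r.left_id, r.right_id) for r in truth.pairs.itertuples(index=False)
    }
    predicted = set()
    for pairing in result.pairings.values():
        predicted |= {(l, r) for l, r, _ in pairing.pairs}
    hit = truth_pairs & predicted
    metrics["pair_recall"] = len(hit) / len(truth_pairs) if truth_pairs else float("nan")
    false_pairs = [
        (l, r) for (l, r) in predicted if truth_type.get(l) != truth_type.get(r)
    ]
    metrics["false_pairs"] = len(false_pairs)
    metrics["pair_precision"] = (
        1.0 - len(false_pairs) / len(predicted) if predicted else float("nan")
    )

    # --- cross-dataset homologues (type-capped: members of a population
    # type generated from the same template are interchangeable)
    n_truth_by_type = truth.homologues["type"].value_counts().to_dict()
    n_good_by_type: dict[str, int] = {}
    for r in result.matches:
        if r.status == "matched" and truth_type.get(r.id_a) == truth_type.get(r.id_b):
            t = truth_type.get(r.id_a)
            if t in n_truth_by_type:
                n_good_by_type[t] = n_good_by_type.get(t, 0) + 1
    n_hom = sum(n_truth_by_type.values())
    hom_hits = sum(
        min(n_good_by_type.get(t, 0), n) for t, n in n_truth_by_type.items()
    )
    metrics["homologue_recall"] = hom_hits / n_hom if n_hom else float("nan")
    n_matched = sum(1 for r in result.matches if r.status == "matched")
    good = sum(
        1
        for r in result.matches
        if r.status == "matched" and truth_type.get(r.id_a) == truth_type.get(r.id_b)
    )
    metrics["homologue_precision"] = good / n_matched if n_matched else float("nan")

    # --- dimorphism labels (type level)
    truth_labels = dict(zip(truth.type_labels["type"], truth.type_labels["dimorphism_label"]))
    pred_by_neuron = dict(zip(result.dimorphism["neuron_id"], result.dimorphism["label"]))
    type_votes: dict[str, str] = {}
    for nid, lab in pred_by_neuron.items():
        t = truth_type.get(nid)
        if t in truth_labels and t not in type_votes:
            type_votes[t] = lab
    confusion: dict[tuple[str, str], int] = {}
    n_ok = 0
    per_label_hits: dict[str, list[int]] = {}
    for t, expected in truth_labels.items():
        got = type_votes.get(t, "missing")
        confusion[(expected, got)] = confusion.get((expected, got), 0) + 1
        per_label_hits.setdefault(expected, []).append(int(got == expected))
        n_ok += int(got == expected)
    metrics["dimorphism_accuracy"] = n_ok / len(truth_labels) if truth_labels else float("nan")
    metrics["dimorphism_recall_by_label"] = {
        k: float(np.mean(v)) for k, v in per_label_hits.items()
    }
    metrics["dimorphism_confusion"] = {f"{e}->{g}": c for (e, g), c in confusion.items()}

    # --- annotation accuracy
    anno = pd.concat(result.annotations.values(), ignore_index=True)
    tr = truth.neurons.set_index("neuron_id")
    focal = anno[anno["neuron_id"].isin(tr.index)]
    sub = tr.loc[focal["neuron_id"]]
    has_code = sub["neuropil_code"] != ""
    metrics["neuropil_accuracy"] = float(
        np.mean(
            focal.loc[has_code.to_numpy(), "neuropil_code"].to_numpy()
            == sub.loc[has_code, "neuropil_code"].to_numpy()
        )
    )
    has_tract = (sub["tract"] != "") & (focal["tract"] != "").to_numpy()
    metrics["tract_accuracy"] = float(
        np.mean(
            focal.loc[has_tract.to_numpy(), "tract"].to_numpy()
            == sub.loc[has_tract, "tract"].to_numpy()
        )
    )
    metrics["side_accuracy"] = float(
        np.mean(focal["side"].to_numpy() == sub["side"].to_numpy())
    )

    # --- information flow vs planted depth
    corrs = []
    for ds_id, tr_ranks in result.type_ranks.items():
        depth = truth.neurons.drop_duplicates("type").set_index("type")["depth"]
        common = [t for t in tr_ranks.index if t in depth.index and depth[t] > 0]
        if len(common) < 3:
            continue
        # each type's rank in its own planted modality
        modality = truth.neurons.drop_duplicates("type").set_index("type")["modality"]
        got = np.array(
            [tr_ranks.at[t, modality[t]] for t in common if modality[t] in tr_ranks.columns]
        )
        want = np.array([depth[t] for t in common if modality[t] in tr_ranks.columns])
        if len(got) >= 3 and np.std(got) > 0 and np.std(want) > 0:
            corrs.append(float(np.corrcoef(got, want)[0, 1]))
    metrics["rank_depth_correlation"] = float(np.mean(corrs)) if corrs else float("nan")
    return metrics
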