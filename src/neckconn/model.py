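"""Domain types, file I/O and dataset assembly.

All coordinates are nanometres.  Skeletons travel as SWC files; neuron
metadata, synapse records, edge lists and landmark pairs travel as
tab-separated tables with a header row; the neuropil atlas and the dataset
manifest are YAML.  ``load_dataset`` assembles the bundle and validates
referential integrity before anything downstream touches it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SIDES = ("left", "right", "center", "unknown")
CNS_REGIONS = ("brain", "vnc")
NEURON_CLASSES = ("DN", "AN", "SA", "MN", "SN", "IN")
#: neuron flags mirroring the exclusion and QC vocabulary of the analysis
FLAGS = (
    "truncated",
    "well_reconstructed",
    "neuropeptidergic",
    "ahn",
    "abdominal_innervation",
)

NEURON_COLUMNS = [
    "neuron_id",
    "dataset_id",
    "side",
    "cns_region",
    "neuron_class",
    "type_label",
    "group_id",
    "soma_x",
    "soma_y",
    "soma_z",
    "flags",
]
SYNAPSE_COLUMNS = ["synapse_id", "neuron_id", "role", "x", "y", "z", "cleft_score", "neuropil"]
EDGE_COLUMNS = ["pre_id", "post_id", "weight"]
LANDMARK_COLUMNS = ["x_src", "y_src", "z_src", "x_dst", "y_dst", "z_dst"]


class SWCError(ValueError):
    """Malformed SWC content (non-numeric field, dangling parent, cycle)."""


class IntegrityError(ValueError):
    """A dataset bundle violates referential integrity."""


@dataclass
class Neuron:
    """A single reconstructed neuron with identity and anatomy metadata."""

    neuron_id: str
    dataset_id: str
    side: str = "unknown"
    cns_region: str = "vnc"
    neuron_class: str = "IN"
    type_label: str | None = None
    group_id: str | None = None
    soma_xyz: np.ndarray | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"invalid side {self.side!r} for {self.neuron_id}")
        if self.neuron_class not in NEURON_CLASSES:
            raise ValueError(f"invalid class {self.neuron_class!r} for {self.neuron_id}")
        if self.cns_region not in CNS_REGIONS:
            raise ValueError(f"invalid cns_region {self.cns_region!r} for {self.neuron_id}")
        unknown = set(self.flags) - set(FLAGS)
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)} for {self.neuron_id}")
        if self.soma_xyz is not None:
            self.soma_xyz = np.asarray(self.soma_xyz, dtype=float)
            if self.soma_xyz.shape != (3,):
                raise ValueError("soma_xyz must be a 3-vector")


@dataclass
class Skeleton:
    """A neuron skeleton: a rooted tree (or forest) of labelled points.

    ``nodes`` has columns node_id, structure, x, y, z, radius, parent_id.
    parent_id −1 marks a root; radius −1 means unknown.
    """

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        self.nodes = self.nodes.reset_index(drop=True)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def xyz(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def root_ids(self) -> list[int]:
        return self.nodes.loc[self.nodes["parent_id"] == -1, "node_id"].tolist()

    def validate(self) -> None:
        ids = self.nodes["node_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise SWCError("duplicate node ids")
        id_set = set(ids.tolist())
        parents = self.nodes["parent_id"].to_numpy()
        for nid, pid in zip(ids, parents):
            if pid != -1 and pid not in id_set:
                raise SWCError(f"node {nid} has dangling parent {pid}")
        # cycle check: walk each node to a root, marking the visit epoch
        parent_of = dict(zip(ids.tolist(), parents.tolist()))
        state: dict[int, int] = {}
        for start in ids.tolist():
            trail = []
            cur = start
            while cur != -1 and cur not in state:
                state[cur] = 0
                trail.append(cur)
                cur = parent_of[cur]
                if cur in trail:
                    raise SWCError(f"cycle detected through node {cur}")
            for t in trail:
                state[t] = 1

    def cable_length(self) -> float:
        """Total length of all parent-child segments, nm."""
        idx = pd.Index(self.nodes["node_id"])
        has_parent = self.nodes["parent_id"] != -1
        child = self.nodes.loc[has_parent, ["x", "y", "z"]].to_numpy(float)
        ppos = idx.get_indexer(self.nodes.loc[has_parent, "parent_id"])
        parent = self.nodes.iloc[ppos][["x", "y", "z"]].to_numpy(float)
        return float(np.linalg.norm(child - parent, axis=1).sum())


@dataclass
class NeuropilAtlas:
    """Axis-aligned neuropil boxes plus named region sets and the midline.

    ``regions`` maps label -> (min_xyz, max_xyz) in nm; boxes are treated as
    half-open so tiled boxes never double-count.  ``region_sets`` must at
    least define ``upper_tectulum`` and ``leg_neuropils`` for the VNC
    annotation rule.
    """

    regions: dict[str, tuple[np.ndarray, np.ndarray]]
    region_sets: dict[str, set[str]]
    midline_x: float

    def __post_init__(self) -> None:
        self.regions = {
            k: (np.asarray(lo, float), np.asarray(hi, float)) for k, (lo, hi) in self.regions.items()
        }
        labels = list(self.regions)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                lo_a, hi_a = self.regions[a]
                lo_b, hi_b = self.regions[b]
                if np.all(np.maximum(lo_a, lo_b) < np.minimum(hi_a, hi_b)):
                    raise ValueError(f"atlas regions {a} and {b} overlap")
        for name, members in self.region_sets.items():
            missing = set(members) - set(self.regions)
            if missing:
                raise ValueError(f"region set {name} references undefined labels {sorted(missing)}")

    def label_points(self, points: np.ndarray) -> np.ndarray:
        """Label each xyz point with its containing region ('' outside)."""
        points = np.atleast_2d(np.asarray(points, float))
        out = np.full(len(points), "", dtype=object)
        for label, (lo, hi) in self.regions.items():
            inside = np.all((points >= lo) & (points < hi), axis=1)
            out[inside] = label
        return out

    @classmethod
    def from_dict(cls, spec: dict) -> "NeuropilAtlas":
        regions = {r["label"]: (r["min"], r["max"]) for r in spec["regions"]}
        sets = {k: set(v) for k, v in spec.get("region_sets", {}).items()}
        return cls(regions=regions, region_sets=sets, midline_x=float(spec["midline_x"]))

    def to_dict(self) -> dict:
        return {
            "midline_x": float(self.midline_x),
            "regions": [
                {"label": k, "min": lo.tolist(), "max": hi.tolist()}
                for k, (lo, hi) in self.regions.items()
            ],
            "region_sets": {k: sorted(v) for k, v in self.region_sets.items()},
        }


@dataclass
class ValidationReport:
    counts_by_class: dict[str, int]
    counts_by_side: dict[str, int]
    n_neurons: int
    n_edges: int
    n_synapses: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class Dataset:
    """One connectome dataset bundle: metadata, geometry and connectivity."""

    dataset_id: str
    neurons: pd.DataFrame
    skeletons: dict[str, Skeleton]
    synapses: pd.DataFrame
    edges: pd.DataFrame
    atlas: NeuropilAtlas
    landmarks: pd.DataFrame | None = None
    seeds: pd.DataFrame | None = None  # sensory seed table: neuron_id, modality
    report: ValidationReport | None = None

    def neuron_ids(self) -> list[str]:
        return self.neurons["neuron_id"].tolist()

    def flags_of(self, neuron_id: str) -> frozenset[str]:
        row = self.neurons.loc[self.neurons["neuron_id"] == neuron_id]
        if row.empty:
            raise KeyError(neuron_id)
        return parse_flags(row.iloc[0]["flags"])

    def validate(self) -> ValidationReport:
        """Check referential integrity; returns the tabulation report.

        Validation never mutates the bundle, so it is idempotent.
        """
        problems: list[str] = []
        warn: list[str] = []
        ids = self.neurons["neuron_id"]
        dupes = ids[ids.duplicated()].unique().tolist()
        if dupes:
            problems.append(f"duplicate neuron_id: {dupes}")
        known = set(ids)
        for col in ("pre_id", "post_id"):
            bad = sorted(set(self.edges[col]) - known)
            if bad:
                problems.append(f"edge {col} references unknown neurons: {bad}")
        bad_syn = sorted(set(self.synapses["neuron_id"]) - known)
        if bad_syn:
            problems.append(f"synapse records reference unknown neurons: {bad_syn}")
        bad_skel = sorted(set(self.skeletons) - known)
        if bad_skel:
            problems.append(f"skeletons for unknown neurons: {bad_skel}")
        for nid, skel in self.skeletons.items():
            if skel.n_nodes < 1:
                problems.append(f"skeleton {nid} has no nodes")
        if len(self.edges) and (self.edges["weight"] < 1).any():
            problems.append("edge weights below 1")
        if problems:
            raise IntegrityError("; ".join(problems))
        if not len(self.edges):
            warn.append("dataset has zero edges")
            logger.warning("dataset %s has zero edges", self.dataset_id)
        report = ValidationReport(
            counts_by_class=self.neurons["neuron_class"].value_counts().to_dict(),
            counts_by_side=self.neurons["side"].value_counts().to_dict(),
            n_neurons=len(self.neurons),
            n_edges=len(self.edges),
            n_synapses=len(self.synapses),
            warnings=warn,
        )
        self.report = report
        return report


def parse_flags(value) -> frozenset[str]:
    """Parse a semicolon-joined flag field; NaN/empty means no flags."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return frozenset()
    return frozenset(str(value).split(";"))


def format_flags(flags) -> str:
    return ";".join(sorted(flags))


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path: str | Path) -> Skeleton:
    """Read an SWC skeleton (7 whitespace-separated columns, ``#`` comments).

    Node ids need not be contiguous; parent −1 marks a root.  Raises
    :class:`SWCError` naming the offending line for non-numeric fields,
    dangling parents or cycles.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                struct = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCError(f"{path.name}:{lineno}: non-numeric field ({exc})") from None
            rows.append((nid, struct, x, y, z, radius, parent))
    nodes = pd.DataFrame(
        rows, columns=["node_id", "structure", "x", "y", "z", "radius", "parent_id"]
    )
    skel = Skeleton(nodes)
    skel.validate()
    return skel


def write_swc(skeleton: Skeleton, path: str | Path) -> None:
    """Write canonical SWC: nodes sorted by id, '#' provenance header.

    Coordinates and radii are printed with fixed 3-decimal precision
    (sub-picometre at nm units), which makes read→write a byte-stable
    round trip.  Unknown radii are the conventional −1.
    """
    if skeleton.n_nodes == 0:
        raise ValueError("no nodes: refusing to write an empty skeleton")
    skeleton.validate()
    nodes = skeleton.nodes.sort_values("node_id")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# SWC written by neckconn\n")
        fh.write("# node_id structure x y z radius parent_id (coordinates in nm)\n")
        for row in nodes.itertuples(index=False):
            fh.write(
                f"{int(row.node_id)} {int(row.structure)} "
                f"{row.x:.3f} {row.y:.3f} {row.z:.3f} {row.radius:.3f} "
                f"{int(row.parent_id)}\n"
            )


# ---------------------------------------------------------------------------
# Dataset assembly


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path.name}: missing columns {missing}")
    return df


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load and validate a dataset bundle described by a YAML/JSON manifest.

    The manifest lists the component files (paths relative to the manifest):
    ``neurons``, ``synapses``, ``edges``, ``atlas``, ``skeleton_dir`` and
    optionally ``landmarks``.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent

    neurons = _read_table(base / manifest["neurons"], NEURON_COLUMNS[:5])
    for col in NEURON_COLUMNS:
        if col not in neurons.columns:
            neurons[col] = np.nan
    synapses = (
        _read_table(base / manifest["synapses"], SYNAPSE_COLUMNS[:7])
        if manifest.get("synapses")
        else pd.DataFrame(columns=SYNAPSE_COLUMNS)
    )
    edges = (
        _read_table(base / manifest["edges"], EDGE_COLUMNS)
        if manifest.get("edges")
        else pd.DataFrame(columns=EDGE_COLUMNS)
    )
    landmarks = None
    if manifest.get("landmarks"):
        landmarks = _read_table(base / manifest["landmarks"], LANDMARK_COLUMNS)
    seeds = None
    if manifest.get("seeds"):
        seeds = _read_table(base / manifest["seeds"], ["neuron_id", "modality"])
    with open(base / manifest["atlas"]) as fh:
        atlas = NeuropilAtlas.from_dict(yaml.safe_load(fh))

    skeletons: dict[str, Skeleton] = {}
    skel_dir = base / manifest.get("skeleton_dir", "skeletons")
    if skel_dir.is_dir():
        for swc in sorted(skel_dir.glob("*.swc")):
            skeletons[swc.stem] = read_swc(swc)

    ds = Dataset(
        dataset_id=str(manifest.get("dataset_id", manifest_path.stem)),
        neurons=neurons,
        skeletons=skeletons,
        synapses=synapses,
        edges=edges,
        atlas=atlas,
        landmarks=landmarks,
        seeds=seeds,
    )
    ds.validate()
    return ds


def write_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    """Write a Dataset as an on-disk bundle; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds.neurons.to_csv(out_dir / "neurons.tsv", sep="\t", index=False)
    ds.synapses.to_csv(out_dir / "synapses.tsv", sep="\t", index=False)
    ds.edges.to_csv(out_dir / "edges.tsv", sep="\t", index=False)
    manifest = {
        "dataset_id": ds.dataset_id,
        "neurons": "neurons.tsv",
        "synapses": "synapses.tsv",
        "edges": "edges.tsv",
        "atlas": "atlas.yaml",
        "skeleton_dir": "skeletons",
    }
    if ds.landmarks is not None:
        ds.landmarks.to_csv(out_dir / "landmarks.tsv", sep="\t", index=False)
        manifest["landmarks"] = "landmarks.tsv"
    if ds.seeds is not None:
        ds.seeds.to_csv(out_dir / "seeds.tsv", sep="\t", index=False)
        manifest["seeds"] = "seeds.tsv"
    with open(out_dir / "atlas.yaml", "w") as fh:
        yaml.safe_dump(ds.atlas.to_dict(), fh, sort_keys=True)
    skel_dir = out_dir / "skeletons"
    skel_dir.mkdir(exist_ok=True)
    for nid, skel in ds.skeletons.items():
        write_swc(skel, skel_dir / f"{nid}.swc")
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
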