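"""Deterministic synthetic two-dataset connectome with planted ground truth.

The generator emulates the statistical structure the comparative analysis
relies on, not biophysics: two sexed datasets ("F" and "M") containing
bilateral neuron types whose right member is a template skeleton grown
along a planted longitudinal tract into designated neuropil boxes, whose
left member is the mirrored template, and whose cross-dataset homologue is
the template carried through a smooth mirror-symmetric warp (affine plus
low-frequency sinusoidal displacement) — all with per-node Gaussian jitter.

Planted truths cover every pipeline stage: left-right pairs and ambiguous
groups, cross-dataset homologues, a dimorphism category per type
(monomorphic, sexually dimorphic, sex-specific, biological variation,
excluded, reconstruction issue), per-neuron tract and neuropil codes, and
per-type sensory modality and layer depth realised as layered feed-forward
wiring from sensory seed neurons.

All randomness flows from one root seed through named substreams so the
morphology, connectivity and flag draws can be varied independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from neckconn.annotate import DEFAULT_VNC_CODE_MAP, TractSet
from neckconn.model import Dataset, NeuropilAtlas, Skeleton, format_flags

# canonical volume (nm): a VNC-shaped box with the midline at x = 150 um
X_MAX = 300_000.0
MIDLINE_X = 150_000.0
Y_MAX = 150_000.0
Z_MAX = 400_000.0

TRACT_NAMES = ("MDA", "DLT", "DLV", "VLT", "ITD")
TRACT_X_OFFSETS = (10_000.0, 25_000.0, 40_000.0, 55_000.0, 70_000.0)

#: z-stacked neuropil slabs tiling the volume (labels follow VNC convention)
NEUROPIL_SLABS = [
    ("NTct", 10_000.0, 50_000.0),
    ("WTct", 50_000.0, 90_000.0),
    ("HTct", 90_000.0, 130_000.0),
    ("IntTct", 130_000.0, 170_000.0),
    ("LTct", 170_000.0, 210_000.0),
    ("LegNpT1", 210_000.0, 250_000.0),
    ("LegNpT2", 250_000.0, 290_000.0),
    ("LegNpT3", 290_000.0, 330_000.0),
    ("ANm", 330_000.0, 370_000.0),
    ("mVAC", 370_000.0, 385_000.0),
    ("Ov", 385_000.0, 400_000.0),
]
UPPER_TECTULUM = {"NTct", "WTct", "HTct"}
LEG_NEUROPILS = {"LegNpT1", "LegNpT2", "LegNpT3"}

#: neuropil target schemes cycled over types: 7 single-box schemes, then the
#: combination categories the VNC rule must recover
_SINGLE_SCHEME_LABELS = ["NTct", "WTct", "HTct", "IntTct", "LTct", "LegNpT1", "LegNpT2"]


def _scheme_for(index: int) -> tuple[dict[str, float], str]:
    s = index % 10
    if s < 7:
        label = _SINGLE_SCHEME_LABELS[s]
        return {label: 1.0}, DEFAULT_VNC_CODE_MAP[label]
    if s == 7:
        return {"NTct": 0.4, "WTct": 0.3, "HTct": 0.3}, "ut"
    if s == 8:
        return {"LegNpT1": 0.4, "LegNpT2": 0.3, "LegNpT3": 0.3}, "xl"
    return {"NTct": 0.5, "LegNpT1": 0.5}, "xn"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic two-dataset connectome."""

    n_types: int = 60
    members_per_side: int = 1
    frac_sex_specific: float = 0.10
    frac_dimorphic: float = 0.10
    n_population_types: int = 2  # types with extra members in F -> biological variation
    n_excluded_types: int = 2  # neuropeptidergic flag -> excluded from dimorphism calls
    n_truncated_types: int = 2  # truncated, single-dataset -> reconstruction issue
    population_extra: int = 1  # extra members per side in dataset F

    # skeleton morphology
    step: float = 1000.0
    wobble_amp: float = 3000.0  # per-type smooth lateral deviation of the main neurite
    jitter_sigma: float = 400.0  # per-node reconstruction noise (sigma_m)
    arbor_main_ratio: float = 1.0  # arbor cable relative to the main neurite
    branch_steps: int = 25
    branch_persistence: float = 0.5
    dimorphic_arbor_shift: tuple[float, float, float] = (0.0, 15_000.0, 25_000.0)
    truncated_keep_nodes: int = 30

    # cross-dataset warp: affine + low-frequency sinusoid, mirror-symmetric
    warp_scale: tuple[float, float, float] = (1.03, 0.98, 1.02)
    warp_shift: tuple[float, float, float] = (0.0, 3_000.0, -4_000.0)
    warp_amp: tuple[float, float, float] = (5_000.0, 5_000.0, 4_000.0)
    warp_wavelength: tuple[float, float, float] = (250_000.0, 200_000.0, 150_000.0)
    lattice_shape: tuple[int, int, int] = (6, 4, 7)

    # connectivity
    modalities: tuple[str, ...] = ("mechanosensory", "proprioceptive", "chemosensory", "visual")
    n_seeds_per_modality: int = 3
    layer_width: int = 3
    max_depth: int = 3
    sensory_weight: float = 50.0
    weight_range: tuple[float, float] = (20.0, 60.0)
    mn_weight_range: tuple[float, float] = (15.0, 40.0)
    dedicated_in_weight: float = 30.0
    sigma_w: float = 5.0
    n_motor_neurons: int = 8
    cross_type_edges: bool = False

    # synapses
    n_synapses: int = 60
    cleft_mean: float = 100.0
    cleft_sd: float = 25.0

    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.frac_sex_specific <= 1 and 0 <= self.frac_dimorphic <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.frac_sex_specific + self.frac_dimorphic > 1:
            raise ValueError("frac_sex_specific + frac_dimorphic must be <= 1")
        for name in ("jitter_sigma", "sigma_w", "wobble_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_types < 1 or self.members_per_side < 1:
            raise ValueError("need at least one type and one member per side")


TINY = dict(
    n_types=8,
    n_population_types=1,
    n_excluded_types=1,
    n_truncated_types=1,
    branch_steps=10,
    modalities=("mechanosensory", "proprioceptive"),
    n_seeds_per_modality=2,
    layer_width=2,
    n_motor_neurons=4,
    n_synapses=40,
)


@dataclass
class GroundTruth:
    """Planted correspondences and labels: the acceptance surface."""

    pairs: pd.DataFrame  # dataset_id, left_id, right_id, type
    groups: pd.DataFrame  # dataset_id, type, members (;-joined)
    homologues: pd.DataFrame  # id_f, id_m, type
    type_labels: pd.DataFrame  # type, dimorphism_label
    neurons: pd.DataFrame  # neuron_id, dataset_id, side, type, tract, neuropil_code, modality, depth

    def seeds_for(self, dataset_id: str) -> dict[str, set[str]]:
        sub = self.neurons[
            (self.neurons["dataset_id"] == dataset_id) & (self.neurons["is_seed"])
        ]
        return {m: set(g["neuron_id"]) for m, g in sub.groupby("modality")}


@dataclass
class _TypeSpec:
    index: int
    name: str
    klass: str  # DN or AN
    tract: str  # right-side tract name (without side suffix)
    tract_x: float
    y_offset: float
    fractions: dict[str, float]
    neuropil_code: str
    modality: str
    depth: int
    role: str  # mono | dimorphic | sex_specific_f | sex_specific_m | population | excluded | truncated_f | truncated_m
    weight: float
    out_weight: float
    mn_targets: tuple[int, int]
    wobble_phase: tuple[float, float] = (0.0, 0.0)
    wobble_wavelength: float = 120_000.0


def make_atlas() -> NeuropilAtlas:
    regions = {
        label: (np.array([0.0, 0.0, z0]), np.array([X_MAX, Y_MAX, z1]))
        for label, z0, z1 in NEUROPIL_SLABS
    }
    return NeuropilAtlas(
        regions=regions,
        region_sets={"upper_tectulum": set(UPPER_TECTULUM), "leg_neuropils": set(LEG_NEUROPILS)},
        midline_x=MIDLINE_X,
    )


def make_tracts() -> TractSet:
    tracts = []
    for name, dx in zip(TRACT_NAMES, TRACT_X_OFFSETS):
        for side, sign in (("R", 1.0), ("L", -1.0)):
            x = MIDLINE_X + sign * dx
            line = np.array([[x, Y_MAX / 2, 0.0], [x, Y_MAX / 2, 350_000.0]])
            tracts.append((f"{name}_{side}", line))
    return TractSet(tracts=tracts)


def make_warp(config: SynthConfig):
    """Smooth deformation carrying canonical (F) space into M space.

    Mirror-symmetric about the midline (the x displacement is odd in
    x − midline, the y/z displacements even), so left-right pairing inside
    the warped dataset behaves like in the canonical one.
    """
    sx, sy, sz = config.warp_scale
    tx, ty, tz = config.warp_shift
    ax, ay, az = config.warp_amp
    lx, ly, lz = config.warp_wavelength

    def warp(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        u = x - MIDLINE_X
        out = np.empty_like(p)
        out[:, 0] = MIDLINE_X + sx * u + tx + ax * np.sin(2 * np.pi * z / lx) * (u / MIDLINE_X)
        out[:, 1] = sy * y + ty + ay * np.cos(2 * np.pi * u / ly) * np.sin(2 * np.pi * z / lx)
        out[:, 2] = sz * z + tz + az * np.sin(2 * np.pi * y / lz)
        return out

    return warp


def make_landmarks(config: SynthConfig, warp) -> pd.DataFrame:
    nx, ny, nz = config.lattice_shape
    gx = np.linspace(0, X_MAX, nx)
    gy = np.linspace(0, Y_MAX, ny)
    gz = np.linspace(0, Z_MAX, nz)
    src = np.array([[x, y, z] for x in gx for y in gy for z in gz])
    dst = warp(src)
    return pd.DataFrame(
        np.hstack([src, dst]),
        columns=["x_src", "y_src", "z_src", "x_dst", "y_dst", "z_dst"],
    )


# ---------------------------------------------------------------------------
# type plan


def _plan_types(config: SynthConfig, rng: np.random.Generator) -> list[_TypeSpec]:
    n = config.n_types
    n_ss = int(round(n * config.frac_sex_specific))
    n_dim = int(round(n * config.frac_dimorphic))
    order = rng.permutation(n)
    roles = ["mono"] * n
    cursor = 0
    for i in range(n_ss):
        roles[order[cursor]] = "sex_specific_f" if i % 2 == 0 else "sex_specific_m"
        cursor += 1
    for _ in range(n_dim):
        roles[order[cursor]] = "dimorphic"
        cursor += 1
    for _ in range(min(config.n_population_types, n - cursor)):
        roles[order[cursor]] = "population"
        cursor += 1
    for _ in range(min(config.n_excluded_types, n - cursor)):
        roles[order[cursor]] = "excluded"
        cursor += 1
    for i in range(min(config.n_truncated_types, n - cursor)):
        roles[order[cursor]] = "truncated_f" if i % 2 == 0 else "truncated_m"
        cursor += 1

    specs = []
    n_offsets = max(1, int(np.ceil(n / len(TRACT_NAMES))))
    for t in range(n):
        tract_i = t % len(TRACT_NAMES)
        offset_i = t // len(TRACT_NAMES)
        y_off = -30_000.0 + 60_000.0 * (offset_i / max(1, n_offsets - 1))
        fractions, code = _scheme_for(t)
        specs.append(
            _TypeSpec(
                index=t,
                name=f"T{t:03d}",
                klass="DN" if t % 2 == 0 else "AN",
                tract=TRACT_NAMES[tract_i],
                tract_x=MIDLINE_X + TRACT_X_OFFSETS[tract_i],
                y_offset=y_off,
                fractions=fractions,
                neuropil_code=code,
                modality=config.modalities[t % len(config.modalities)],
                depth=1 + t % config.max_depth,
                role=roles[t],
                weight=float(rng.uniform(*config.weight_range)),
                out_weight=float(rng.uniform(*config.mn_weight_range)),
                mn_targets=(t % config.n_motor_neurons, (t // 2 + 3) % config.n_motor_neurons),
                wobble_phase=(float(rng.uniform(0, 2 * np.pi)), float(rng.uniform(0, 2 * np.pi))),
                wobble_wavelength=float(rng.uniform(80_000.0, 160_000.0)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# skeleton growth


def _box_center_z(label: str) -> float:
    for lab, z0, z1 in NEUROPIL_SLABS:
        if lab == label:
            return 0.5 * (z0 + z1)
    raise KeyError(label)


def _grow_template(
    spec: _TypeSpec, config: SynthConfig, rng: np.random.Generator, arbor_shift=None
) -> tuple[np.ndarray, np.ndarray]:
    """Grow a right-side template; returns (xyz, parent_index) arrays.

    The main neurite descends along the type's tract (with a smooth
    per-type wobble and a per-type y offset) to the deepest target
    neuropil; momentum-random-walk branches sprout near each target box
    centre, in numbers proportional to the planted synapse fractions.
    """
    step = config.step
    z_targets = {lab: _box_center_z(lab) for lab in spec.fractions}
    z_deep = max(z_targets.values())
    n_main = max(4, int(round(z_deep / step)))
    z = np.arange(n_main + 1) * (z_deep / n_main)
    px, py = spec.wobble_phase
    lam = spec.wobble_wavelength
    x = spec.tract_x + config.wobble_amp * np.sin(2 * np.pi * z / lam + px)
    y = Y_MAX / 2 + spec.y_offset + config.wobble_amp * np.sin(2 * np.pi * z / lam + py)
    main = np.column_stack([x, y, z])
    xyz = [main]
    parents = list(range(-1, n_main))  # main path chain

    shift = np.zeros(3) if arbor_shift is None else np.asarray(arbor_shift, float)
    total_frac = sum(spec.fractions.values())
    # arbor size tracks the main neurite so the arbor is always a comparable
    # share of the morphology, whatever the target depth
    n_branches = max(1, int(round(config.arbor_main_ratio * n_main / config.branch_steps)))
    for lab in sorted(spec.fractions):
        frac = spec.fractions[lab]
        nb = max(1, int(round(n_branches * frac / total_frac)))
        attach = int(np.clip(round(z_targets[lab] / (z_deep / n_main)), 1, n_main))
        for _ in range(nb):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pos = main[attach] + shift
            parent = attach
            pts = []
            for _ in range(config.branch_steps):
                d = d + config.branch_persistence * rng.normal(size=3)
                d /= np.linalg.norm(d)
                pos = pos + step * d
                pts.append(pos.copy())
            start_idx = sum(len(a) for a in xyz)
            xyz.append(np.array(pts))
            parents.extend([parent] + list(range(start_idx, start_idx + len(pts) - 1)))
    return np.concatenate(xyz), np.asarray(parents, int)


def _to_skeleton(xyz: np.ndarray, parents: np.ndarray) -> Skeleton:
    n = len(xyz)
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(1, n + 1),
            "structure": np.zeros(n, int),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "radius": np.full(n, -1.0),
            "parent_id": np.where(parents < 0, -1, parents + 1),
        }
    )
    return Skeleton(nodes)


def _mirror_xyz(xyz: np.ndarray) -> np.ndarray:
    out = xyz.copy()
    out[:, 0] = 2 * MIDLINE_X - out[:, 0]
    return out


# ---------------------------------------------------------------------------
# main generator


def generate(config: SynthConfig) -> tuple[Dataset, Dataset, GroundTruth, pd.DataFrame]:
    """Generate the female/male dataset pair, ground truth and landmarks."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(5)
    rng_roles = np.random.default_rng(streams[0])
    rng_morph = np.random.default_rng(streams[1])
    rng_conn = np.random.default_rng(streams[2])
    rng_syn = np.random.default_rng(streams[3])

    specs = _plan_types(config, rng_roles)
    atlas = make_atlas()
    warp = make_warp(config)
    landmarks = make_landmarks(config, warp)

    presence = {
        "mono": ("F", "M"),
        "dimorphic": ("F", "M"),
        "population": ("F", "M"),
        "excluded": ("F", "M"),
        "sex_specific_f": ("F",),
        "sex_specific_m": ("M",),
        "truncated_f": ("F",),
        "truncated_m": ("M",),
    }
    truth_label = {
        "mono": "matched_monomorphic",
        "dimorphic": "sexually_dimorphic",
        "population": "biological_variation",
        "excluded": "excluded",
        "sex_specific_f": "sex_specific",
        "sex_specific_m": "sex_specific",
        "truncated_f": "reconstruction_issue",
        "truncated_m": "reconstruction_issue",
    }

    neurons: dict[str, list[dict]] = {"F": [], "M": []}
    skeletons: dict[str, dict[str, Skeleton]] = {"F": {}, "M": {}}
    synapses: dict[str, list[dict]] = {"F": [], "M": []}
    edges: dict[str, list[dict]] = {"F": [], "M": []}
    truth_rows: list[dict] = []
    pair_rows: list[dict] = []
    group_rows: list[dict] = []
    homologue_rows: list[dict] = []

    members_of: dict[tuple[str, str], list[str]] = {}

    for spec in specs:
        template = _grow_template(spec, config, rng_morph)
        if spec.role == "dimorphic":
            template_m = _grow_template_variant(spec, config, template)
        else:
            template_m = template
        for ds in presence[spec.role]:
            tmpl = template_m if ds == "M" else template
            n_members = config.members_per_side + (
                config.population_extra if (spec.role == "population" and ds == "F") else 0
            )
            member_ids: dict[str, list[str]] = {"L": [], "R": []}
            for i in range(n_members):
                for side_code, side in (("R", "right"), ("L", "left")):
                    xyz, parents = tmpl
                    pts = xyz if side_code == "R" else _mirror_xyz(xyz)
                    pts = pts + rng_morph.normal(0, config.jitter_sigma, pts.shape)
                    if spec.role.startswith("truncated"):
                        keep = min(config.truncated_keep_nodes, len(pts))
                        pts, parents = pts[:keep], parents[:keep]
                    if ds == "M":
                        pts = warp(pts)
                    nid = f"{ds}:{spec.name}:{side_code}{i}"
                    skeletons[ds][nid] = _to_skeleton(pts, parents)
                    flags = []
                    if spec.role == "excluded":
                        flags.append("neuropeptidergic")
                    if spec.role.startswith("truncated"):
                        flags.append("truncated")
                    soma = pts[0]
                    neurons[ds].append(
                        {
                            "neuron_id": nid,
                            "dataset_id": ds,
                            "side": side,
                            "cns_region": "vnc",
                            "neuron_class": spec.klass,
                            "type_label": spec.name,
                            "group_id": spec.name,
                            "soma_x": float(soma[0]) if spec.klass == "AN" else np.nan,
                            "soma_y": float(soma[1]) if spec.klass == "AN" else np.nan,
                            "soma_z": float(soma[2]) if spec.klass == "AN" else np.nan,
                            "flags": format_flags(flags),
                        }
                    )
                    member_ids[side_code].append(nid)
                    truth_rows.append(
                        {
                            "neuron_id": nid,
                            "dataset_id": ds,
                            "side": side,
                            "type": spec.name,
                            "neuron_class": spec.klass,
                            "tract": f"{spec.tract}_{side_code}",
                            "neuropil_code": spec.neuropil_code,
                            "modality": spec.modality,
                            "depth": spec.depth,
                            "is_seed": False,
                        }
                    )
                    # synapses planted inside the designated neuropil boxes
                    role = "pre" if spec.klass == "DN" else "post"
                    labels = sorted(spec.fractions)
                    probs = np.array([spec.fractions[lab] for lab in labels])
                    counts = rng_syn.multinomial(config.n_synapses, probs / probs.sum())
                    for lab, cnt in zip(labels, counts):
                        lo, hi = atlas.regions[lab]
                        pos = rng_syn.uniform(lo, hi, size=(cnt, 3))
                        cleft = rng_syn.normal(config.cleft_mean, config.cleft_sd, cnt)
                        for j in range(cnt):
                            synapses[ds].append(
                                {
                                    "synapse_id": f"{nid}:s{lab}{j}",
                                    "neuron_id": nid,
                                    "role": role,
                                    "x": pos[j, 0],
                                    "y": pos[j, 1],
                                    "z": pos[j, 2],
                                    "cleft_score": cleft[j],
                                    "neuropil": lab,
                                }
                            )
            members_of[(ds, spec.name)] = member_ids["L"] + member_ids["R"]
            if n_members == 1 and not spec.role.startswith("truncated"):
                pair_rows.append(
                    {
                        "dataset_id": ds,
                        "left_id": member_ids["L"][0],
                        "right_id": member_ids["R"][0],
                        "type": spec.name,
                    }
                )
            elif n_members > 1:
                group_rows.append(
                    {
                        "dataset_id": ds,
                        "type": spec.name,
                        "members": ";".join(member_ids["L"] + member_ids["R"]),
                    }
                )
        if set(presence[spec.role]) == {"F", "M"}:
            for side_code in ("L", "R"):
                n_common = config.members_per_side
                for i in range(n_common):
                    homologue_rows.append(
                        {
                            "id_f": f"F:{spec.name}:{side_code}{i}",
                            "id_m": f"M:{spec.name}:{side_code}{i}",
                            "type": spec.name,
                        }
                    )

    # --- scaffold: sensory seeds, interneuron layers, motor neurons -------
    scaffold_types: list[tuple[str, str, str, int | None]] = []  # (type, class, modality, layer)
    for m in config.modalities:
        for i in range(config.n_seeds_per_modality):
            scaffold_types.append((f"SN_{m}_{i}", "SN", m, 0))
        for layer in range(1, config.max_depth):
            for i in range(config.layer_width):
                scaffold_types.append((f"IN_{m}_{layer}_{i}", "IN", m, layer))
    for i in range(config.n_motor_neurons):
        scaffold_types.append((f"MN_{i:02d}", "MN", "", None))
    for spec in specs:
        scaffold_types.append((f"IN_dedicated_{spec.name}", "IN", "", None))

    for ds in ("F", "M"):
        for tname, klass, modality, layer in scaffold_types:
            nid = f"{ds}:{tname}"
            neurons[ds].append(
                {
                    "neuron_id": nid,
                    "dataset_id": ds,
                    "side": "center",
                    "cns_region": "vnc",
                    "neuron_class": klass,
                    "type_label": tname,
                    "group_id": tname,
                    "soma_x": MIDLINE_X,
                    "soma_y": Y_MAX / 2,
                    "soma_z": Z_MAX / 2,
                    "flags": "",
                }
            )
            truth_rows.append(
                {
                    "neuron_id": nid,
                    "dataset_id": ds,
                    "side": "center",
                    "type": tname,
                    "neuron_class": klass,
                    "tract": "",
                    "neuropil_code": "",
                    "modality": modality,
                    "depth": layer if layer is not None else -1,
                    "is_seed": layer == 0,
                }
            )

    def _w(mean: float) -> int:
        return max(1, int(round(mean + rng_conn.normal(0, config.sigma_w))))

    for ds in ("F", "M"):
        for m in config.modalities:
            seeds = [f"{ds}:SN_{m}_{i}" for i in range(config.n_seeds_per_modality)]
            layers = [seeds]
            for layer in range(1, config.max_depth):
                layers.append([f"{ds}:IN_{m}_{layer}_{i}" for i in range(config.layer_width)])
            for k in range(1, len(layers)):
                for pre in layers[k - 1]:
                    for post in layers[k]:
                        edges[ds].append(
                            {"pre_id": pre, "post_id": post, "weight": _w(config.sensory_weight)}
                        )
        for spec in specs:
            if ds not in presence[spec.role]:
                continue
            members = members_of[(ds, spec.name)]
            m = spec.modality
            if spec.depth == 1:
                pres = [f"{ds}:SN_{m}_{i}" for i in range(config.n_seeds_per_modality)]
            else:
                pres = [f"{ds}:IN_{m}_{spec.depth - 1}_{i}" for i in range(config.layer_width)]
            for member in members:
                for pre in pres:
                    edges[ds].append({"pre_id": pre, "post_id": member, "weight": _w(spec.weight)})
                for mn in spec.mn_targets:
                    edges[ds].append(
                        {
                            "pre_id": member,
                            "post_id": f"{ds}:MN_{mn:02d}",
                            "weight": _w(spec.out_weight),
                        }
                    )
                edges[ds].append(
                    {
                        "pre_id": member,
                        "post_id": f"{ds}:IN_dedicated_{spec.name}",
                        "weight": _w(config.dedicated_in_weight),
                    }
                )
        if config.cross_type_edges:
            present = [s for s in specs if ds in presence[s.role]]
            for a, b in zip(present, present[1:]):
                edges[ds].append(
                    {
                        "pre_id": members_of[(ds, a.name)][0],
                        "post_id": members_of[(ds, b.name)][0],
                        "weight": _w(12.0),
                    }
                )

    datasets = {}
    for ds in ("F", "M"):
        seed_rows = [
            {"neuron_id": f"{ds}:SN_{m}_{i}", "modality": m}
            for m in config.modalities
            for i in range(config.n_seeds_per_modality)
        ]
        datasets[ds] = Dataset(
            dataset_id=ds,
            neurons=pd.DataFrame(neurons[ds]),
            skeletons=skeletons[ds],
            synapses=pd.DataFrame(synapses[ds]),
            edges=pd.DataFrame(edges[ds]),
            atlas=atlas,
            landmarks=landmarks if ds == "F" else None,
            seeds=pd.DataFrame(seed_rows),
        )
        datasets[ds].validate()

    truth = GroundTruth(
        pairs=pd.DataFrame(pair_rows),
        groups=pd.DataFrame(group_rows, columns=["dataset_id", "type", "members"]),
        homologues=pd.DataFrame(homologue_rows),
        type_labels=pd.DataFrame(
            [{"type": s.name, "dimorphism_label": truth_label[s.role]} for s in specs]
        ),
        neurons=pd.DataFrame(truth_rows),
    )
    return datasets["F"], datasets["M"], truth, landmarks


def _grow_template_variant(
    spec: _TypeSpec, config: SynthConfig, template: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Dimorphic variant: same main neurite, arbor displaced beyond tau_d."""
    xyz, parents = template
    z_deep = max(_box_center_z(lab) for lab in spec.fractions)
    n_main = max(4, int(round(z_deep / config.step))) + 1
    out = xyz.copy()
    out[n_main:] += np.asarray(config.dimorphic_arbor_shift, float)
    return out, parents


def tiny_config(seed: int = 0, **overrides) -> SynthConfig:
    """Small, fast configuration for unit tests (8 types, ~40 matched neurons)."""
    kwargs = dict(TINY)
    kwargs.update(overrides)
    return SynthConfig(seed=seed, **kwargs)


def emit_fixture(size: str, out_dir, seed: int = 0) -> dict:
    """Write an on-disk bundle (datasets F and M plus truth tables).

    ``size`` is "tiny" (unit tests) or "default" (the full study
    conditions).  Returns the manifest dict with all written paths.
    """
    from pathlib import Path

    from neckconn.model import write_dataset

    if size == "tiny":
        config = tiny_config(seed=seed)
    elif size == "default":
        config = SynthConfig(seed=seed)
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds_f, ds_m, truth, landmarks = generate(config)
    manifest_f = write_dataset(ds_f, out_dir / "dataset_f")
    manifest_m = write_dataset(ds_m, out_dir / "dataset_m")
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.pairs.to_csv(truth_dir / "pairs.tsv", sep="\t", index=False)
    truth.groups.to_csv(truth_dir / "groups.tsv", sep="\t", index=False)
    truth.homologues.to_csv(truth_dir / "homologues.tsv", sep="\t", index=False)
    truth.type_labels.to_csv(truth_dir / "type_labels.tsv", sep="\t", index=False)
    truth.neurons.to_csv(truth_dir / "neurons.tsv", sep="\t", index=False)
    manifest = {
        "size": size,
        "seed": seed,
        "dataset_f": str(manifest_f.relative_to(out_dir)),
        "dataset_m": str(manifest_m.relative_to(out_dir)),
        "truth_dir": "truth",
    }
    import yaml

    with open(out_dir / "bundle.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
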