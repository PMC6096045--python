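"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* **SWC** — standard 7-column neuron reconstructions
  (``id type x y z radius parent``, '#' comments).  Structure codes:
  1 = soma, 2 = axon, 3 = dendrite; unknown codes are mapped to dendrite
  with a warning (only dendrites are analysed downstream).
* **Context sidecar** — JSON carrying the GL–EPL border plane, the traced
  soma outline area and the glomerulus spheres::

      {"border_plane": {"point": [x, y, z], "normal": [x, y, z]},
       "soma_area_um2": 42.2,
       "glomeruli": [{"center": [x, y, z], "radius": 50.0, "label": "g1"}]}

* **Sweep sets** — one HDF5 file per cell (groups ``/sweep_k`` with datasets
  ``voltage`` [mV] and ``current`` [pA]; group attrs ``step_pa``, ``onset_s``,
  ``offset_s``; root attr ``sampling_rate_hz``), or a long-format CSV
  fallback with columns ``sweep, t_s, v_mv, i_pa`` plus a header comment
  carrying the step metadata.
* **Pair-recording bundles** — one HDF5 file per ordered direction
  (groups ``/trial_k`` with ``pre_v`` [mV] and ``post_i`` [pA]).
* **Parameter sheets** — delimited tables, one row per cell, columns mapped
  onto the canonical parameter names through a user-extensible alias table.

All coordinates are in μm (right-handed), voltages in mV, currents in pA and
times in s.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SwcNode",
    "NeuronMorphology",
    "GlomerularContext",
    "Sweep",
    "SweepSet",
    "PairRecording",
    "FeatureTable",
    "SwcParseError",
    "StructureError",
    "ValidationError",
    "MORPHOLOGICAL_PARAMETERS",
    "PHYSIOLOGICAL_PARAMETERS",
    "COLUMN_ALIASES",
    "read_swc",
    "write_swc",
    "read_context",
    "write_context",
    "read_sweeps",
    "write_sweeps",
    "read_sweeps_csv",
    "write_sweeps_csv",
    "read_pairs",
    "write_pairs",
    "read_parameter_sheet",
    "write_feature_table",
]


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class StructureError(ValueError):
    """The node graph violates a structural invariant (root count, cycles)."""


class ValidationError(ValueError):
    """A value-level invariant is violated."""


SOMA, AXON, DENDRITE = "soma", "axon", "dendrite"

_SWC_CODE_TO_STRUCT = {1: SOMA, 2: AXON, 3: DENDRITE}
_STRUCT_TO_SWC_CODE = {SOMA: 1, AXON: 2, DENDRITE: 3}


@dataclass(frozen=True)
class SwcNode:
    node_id: int
    structure: str          # soma | axon | dendrite
    x: float
    y: float
    z: float
    radius: float
    parent_id: int | None   # None for the root

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class NeuronMorphology:
    """A rooted tree of 3D nodes with radii plus the traced soma outline area.

    Invariants: exactly one root, unique ids, acyclic and connected graph,
    all radii > 0.  ``soma_area`` is the area enclosed by the traced soma
    boundary (μm²); when no sidecar provides it, π·(mean soma radius)² is
    used as a fallback.
    """

    nodes: list[SwcNode]
    soma_area: float = 0.0
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- structure helpers -------------------------------------------------
    def validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise StructureError("duplicate node ids")
        roots = [n for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        by_id = {n.node_id: n for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None and n.parent_id not in by_id:
                raise StructureError(f"node {n.node_id} references missing parent {n.parent_id}")
            if n.radius <= 0:
                raise ValidationError(f"node {n.node_id} has non-positive radius")
        # cycle/connectivity check by walking to the root from every node
        for n in self.nodes:
            seen = set()
            cur = n
            while cur.parent_id is not None:
                if cur.node_id in seen:
                    raise StructureError("cyclic parent references")
                seen.add(cur.node_id)
                cur = by_id[cur.parent_id]

    @property
    def root(self) -> SwcNode:
        return next(n for n in self.nodes if n.parent_id is None)

    def node(self, node_id: int) -> SwcNode:
        return next(n for n in self.nodes if n.node_id == node_id)

    def children(self, node_id: int) -> list[SwcNode]:
        return [n for n in self.nodes if n.parent_id == node_id]

    @property
    def soma_nodes(self) -> list[SwcNode]:
        return [n for n in self.nodes if n.structure == SOMA]

    def effective_soma_area(self) -> float:
        """Traced outline area if present, else π·(mean soma-node radius)²."""
        if self.soma_area > 0:
            return self.soma_area
        soma = self.soma_nodes
        if not soma:
            return 0.0
        r = float(np.mean([n.radius for n in soma]))
        return math.pi * r * r


@dataclass
class GlomerularContext:
    """GL–EPL border plane and glomerulus spheres.

    ``normal`` is stored unit length and points from the EPL into the GL, so
    the signed distance of a point to the plane is positive on the GL side.
    """

    plane_point: np.ndarray
    plane_normal: np.ndarray
    glomeruli: list[tuple[np.ndarray, float, str]] = field(default_factory=list)
    soma_area: float | None = None

    def __post_init__(self) -> None:
        self.plane_point = np.asarray(self.plane_point, dtype=float)
        n = np.asarray(self.plane_normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if norm == 0.0:
            raise ValidationError("border-plane normal has zero length")
        self.plane_normal = n / norm
        cleaned = []
        for center, radius, label in self.glomeruli:
            if radius <= 0:
                raise ValidationError(f"glomerulus {label!r} has non-positive radius")
            cleaned.append((np.asarray(center, dtype=float), float(radius), str(label)))
        self.glomeruli = cleaned

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the border plane; > 0 on the GL side."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.plane_point) @ self.plane_normal


@dataclass
class Sweep:
    voltage: np.ndarray        # mV
    current_command: np.ndarray  # pA
    step_amplitude: float      # pA
    step_onset: float          # s
    step_offset: float         # s

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current_command = np.asarray(self.current_command, dtype=float)
        if self.voltage.shape != self.current_command.shape:
            raise ValidationError("voltage and current series differ in length")


@dataclass
class SweepSet:
    """A cell's current-clamp step sweeps (default digitisation 33 kHz)."""

    sampling_rate: float = 33000.0
    sweeps: list[Sweep] = field(default_factory=list)
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling rate must be positive")
        lengths = {len(s.voltage) for s in self.sweeps}
        if len(lengths) > 1:
            raise ValidationError("sweeps differ in length")
        dur = (lengths.pop() / self.sampling_rate) if lengths else 0.0
        for s in self.sweeps:
            if not (0 <= s.step_onset < s.step_offset <= dur + 1e-9):
                raise ValidationError("step window outside sweep duration")

    @property
    def duration(self) -> float:
        return len(self.sweeps[0].voltage) / self.sampling_rate if self.sweeps else 0.0

    def time(self) -> np.ndarray:
        return np.arange(len(self.sweeps[0].voltage)) / self.sampling_rate


@dataclass
class PairRecording:
    """Trials of one ordered direction of a paired recording.

    The presynaptic cell is spiked in current clamp while the postsynaptic
    cell is held in voltage clamp at −50 mV; inward (excitatory) currents
    are negative.
    """

    pair_id: str
    pre_cell_id: str
    post_cell_id: str
    trials: list[tuple[np.ndarray, np.ndarray]]   # (pre mV, post pA)
    sampling_rate: float
    holding_potential: float = -50.0

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValidationError("a pair recording needs at least one trial")
        coerced = []
        for pre, post in self.trials:
            pre = np.asarray(pre, dtype=float)
            post = np.asarray(post, dtype=float)
            if pre.shape != post.shape:
                raise ValidationError("pre and post series differ in length")
            coerced.append((pre, post))
        self.trials = coerced

    @property
    def direction(self) -> tuple[str, str]:
        return (self.pre_cell_id, self.post_cell_id)


# ---------------------------------------------------------------------------
# canonical parameter names and aliases
# ---------------------------------------------------------------------------

#: the nine clustered morphological parameters
MORPHOLOGICAL_PARAMETERS = (
    "process_volume",
    "convex_hull",
    "lateral_dendritic_volume",
    "vertical_dendritic_volume",
    "n_glomeruli",
    "soma_x_dendritic_volume",
    "dendritic_length",
    "dendritic_density",
    "furthest_sholl",
)

#: the nine clustered physiological parameters
PHYSIOLOGICAL_PARAMETERS = (
    "early_ahp",
    "late_ahp",
    "intermediate_ahp",
    "half_width",
    "time_constant",
    "input_resistance",
    "speed_ratio",
    "cv_isi",
    "amplitude",
)

#: built-in column aliases (normalised: lower-case, alphanumerics only)
COLUMN_ALIASES: dict[str, str] = {
    "processvolume": "process_volume",
    "processvolumeum3": "process_volume",
    "volumeofallprocesses": "process_volume",
    "convexhull": "convex_hull",
    "convexhullum3": "convex_hull",
    "convexhullvolume": "convex_hull",
    "lateraldendriticvolume": "lateral_dendritic_volume",
    "verticaldendriticvolume": "vertical_dendritic_volume",
    "noofglomeruli": "n_glomeruli",
    "numberofglomeruli": "n_glomeruli",
    "nglomeruli": "n_glomeruli",
    "somaxdendriticvolume": "soma_x_dendritic_volume",
    "somadendriticvolume": "soma_x_dendritic_volume",
    "dendriticlength": "dendritic_length",
    "totaldendriticlength": "dendritic_length",
    "dendriticdensity": "dendritic_density",
    "furthestsholl": "furthest_sholl",
    "shollintercept": "furthest_sholl",
    "furthestshollintercept": "furthest_sholl",
    "earlyahp": "early_ahp",
    "lateahp": "late_ahp",
    "intermediateahp": "intermediate_ahp",
    "middleahp": "intermediate_ahp",
    "aphalfwidth": "half_width",
    "halfwidth": "half_width",
    "aphalfwidthms": "half_width",
    "timeconstant": "time_constant",
    "timeconstantms": "time_constant",
    "tau": "time_constant",
    "inputresistance": "input_resistance",
    "inputresistancegohm": "input_resistance",
    "rin": "input_resistance",
    "apspeedratio": "speed_ratio",
    "speedratio": "speed_ratio",
    "cvoftheisidistribution": "cv_isi",
    "cvisi": "cv_isi",
    "cvoftheisi": "cv_isi",
    "apamplitude": "amplitude",
    "amplitude": "amplitude",
    "apamplitudemv": "amplitude",
    "surface": "hull2d_area",
    "hull2darea": "hull2d_area",
    "2dconvexhull": "hull2d_area",
    "cluster": "cluster",
    "clusterlabel": "cluster",
    "cellid": "cell_id",
    "cell": "cell_id",
}

_KIND_BY_PARAM = (
    {p: "morphological" for p in MORPHOLOGICAL_PARAMETERS}
    | {p: "physiological" for p in PHYSIOLOGICAL_PARAMETERS}
    | {"hull2d_area": "morphological", "cluster": "label"}
)


def _normalise_column(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


@dataclass
class FeatureTable:
    """Cells × named-parameter matrix with per-column provenance tags.

    ``kinds`` maps every column to one of ``morphological``,
    ``physiological``, ``label`` or ``other``.
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicated cell ids")
        for col in self.data.columns:
            self.kinds.setdefault(col, _KIND_BY_PARAM.get(col, "other"))

    @property
    def cell_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def columns_of_kind(self, kind: str) -> list[str]:
        return [c for c in self.data.columns if self.kinds.get(c) == kind]

    def matrix(self, columns: list[str] | tuple[str, ...]) -> np.ndarray:
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise ValidationError(f"missing feature columns: {missing}")
        return self.data.loc[:, list(columns)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path, context_path=None) -> NeuronMorphology:
    """Read a 7-column SWC reconstruction (optionally with a JSON sidecar).

    ``soma_area`` is taken from the sidecar when present, else falls back to
    π·(mean soma-node radius)².  Raises :class:`SwcParseError` with the line
    number on malformed lines and :class:`StructureError` on multiple roots
    or cyclic parent references.
    """
    nodes: list[SwcNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                code = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from exc
            struct = _SWC_CODE_TO_STRUCT.get(code)
            if struct is None:
                logger.warning("%s:%d: unknown structure code %d mapped to dendrite", path, lineno, code)
                struct = DENDRITE
            nodes.append(SwcNode(nid, struct, x, y, z, radius, None if parent == -1 else parent))
    soma_area = 0.0
    cell_id = _stem(path)
    if context_path is not None:
        with open(context_path) as fh:
            soma_area = float(json.load(fh).get("soma_area_um2", 0.0))
    morph = NeuronMorphology(nodes=nodes, soma_area=soma_area, cell_id=cell_id)
    if morph.soma_area == 0.0:
        morph.soma_area = morph.effective_soma_area()
    return morph


def write_swc(morph: NeuronMorphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in morph.nodes:
            parent = -1 if n.parent_id is None else n.parent_id
            fh.write(
                f"{n.node_id} {_STRUCT_TO_SWC_CODE[n.structure]} "
                f"{n.x:.6f} {n.y:.6f} {n.z:.6f} {n.radius:.6f} {parent}\n"
            )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# context sidecar
# ---------------------------------------------------------------------------

def read_context(path) -> GlomerularContext:
    """Read the JSON sidecar (border plane, soma area, glomerulus spheres)."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        plane = doc["border_plane"]
        point, normal = plane["point"], plane["normal"]
    except KeyError as exc:
        raise ValidationError(f"{path}: missing border_plane/{exc}") from exc
    if "glomeruli" not in doc:
        logger.warning("%s: no 'glomeruli' key; assuming empty glomerulus list", path)
    glomeruli = [
        (g["center"], g["radius"], g.get("label", f"g{i}"))
        for i, g in enumerate(doc.get("glomeruli", []), start=1)
    ]
    return GlomerularContext(
        plane_point=point,
        plane_normal=normal,
        glomeruli=glomeruli,
        soma_area=doc.get("soma_area_um2"),
    )


def write_context(ctx: GlomerularContext, path) -> None:
    doc = {
        "border_plane": {
            "point": [float(v) for v in ctx.plane_point],
            "normal": [float(v) for v in ctx.plane_normal],
        },
        "glomeruli": [
            {"center": [float(v) for v in c], "radius": float(r), "label": label}
            for c, r, label in ctx.glomeruli
        ],
    }
    if ctx.soma_area is not None:
        doc["soma_area_um2"] = float(ctx.soma_area)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# sweep sets (HDF5 + CSV fallback)
# ---------------------------------------------------------------------------

def write_sweeps(sweeps: SweepSet, path) -> None:
    with h5py.File(path, "w", track_order=True) as fh:
        fh.attrs["sampling_rate_hz"] = float(sweeps.sampling_rate)
        fh.attrs["cell_id"] = sweeps.cell_id
        for k, s in enumerate(sweeps.sweeps):
            grp = fh.create_group(f"sweep_{k}")
            grp.create_dataset("voltage", data=s.voltage, track_times=False)
            grp.create_dataset("current", data=s.current_command, track_times=False)
            grp.attrs["step_pa"] = float(s.step_amplitude)
            grp.attrs["onset_s"] = float(s.step_onset)
            grp.attrs["offset_s"] = float(s.step_offset)


def read_sweeps(path) -> SweepSet:
    """Read a cell's sweep set from the HDF5 dialect."""
    sweeps = []
    with h5py.File(path, "r") as fh:
        if "sampling_rate_hz" not in fh.attrs:
            raise ValidationError(f"{path}: missing sampling_rate_hz attribute")
        rate = float(fh.attrs["sampling_rate_hz"])
        cell_id = str(fh.attrs.get("cell_id", _stem(path)))
        keys = sorted((k for k in fh if k.startswith("sweep_")), key=lambda k: int(k.split("_")[1]))
        for k in keys:
            grp = fh[k]
            sweeps.append(
                Sweep(
                    voltage=grp["voltage"][()],
                    current_command=grp["current"][()],
                    step_amplitude=float(grp.attrs["step_pa"]),
                    step_onset=float(grp.attrs["onset_s"]),
                    step_offset=float(grp.attrs["offset_s"]),
                )
            )
    return SweepSet(sampling_rate=rate, sweeps=sweeps, cell_id=cell_id)


def write_sweeps_csv(sweeps: SweepSet, path) -> None:
    """CSV fallback: long format ``sweep, t_s, v_mv, i_pa`` with a metadata header."""
    meta = ";".join(
        f"{k}:{s.step_amplitude!r}:{s.step_onset!r}:{s.step_offset!r}"
        for k, s in enumerate(sweeps.sweeps)
    )
    t = sweeps.time()
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={sweeps.sampling_rate!r} cell_id={sweeps.cell_id} steps={meta}\n")
        fh.write("sweep,t_s,v_mv,i_pa\n")
        for k, s in enumerate(sweeps.sweeps):
            for ti, v, i in zip(t, s.voltage, s.current_command):
                fh.write(f"{k},{float(ti)!r},{float(v)!r},{float(i)!r}\n")


def read_sweeps_csv(path) -> SweepSet:
    with open(path) as fh:
        header = fh.readline().strip()
    m = re.match(r"#\s*sampling_rate_hz=(\S+)\s+cell_id=(\S*)\s+steps=(\S*)", header)
    if not m:
        raise ValidationError(f"{path}: missing sampling-rate header line")
    rate, cell_id = float(m.group(1)), m.group(2)
    steps = {}
    for entry in filter(None, m.group(3).split(";")):
        k, amp, onset, offset = entry.split(":")
        steps[int(k)] = (float(amp), float(onset), float(offset))
    df = pd.read_csv(path, comment="#")
    sweeps = []
    for k, sub in df.groupby("sweep", sort=True):
        amp, onset, offset = steps[int(k)]
        sweeps.append(
            Sweep(
                voltage=sub["v_mv"].to_numpy(),
                current_command=sub["i_pa"].to_numpy(),
                step_amplitude=amp,
                step_onset=onset,
                step_offset=offset,
            )
        )
    return SweepSet(sampling_rate=rate, sweeps=sweeps, cell_id=cell_id)


# ---------------------------------------------------------------------------
# pair recordings
# ---------------------------------------------------------------------------

def write_pairs(pairs: list[PairRecording], path) -> None:
    with h5py.File(path, "w", track_order=True) as fh:
        for j, pr in enumerate(pairs):
            grp = fh.create_group(f"direction_{j}")
            grp.attrs["pair_id"] = pr.pair_id
            grp.attrs["pre_cell_id"] = pr.pre_cell_id
            grp.attrs["post_cell_id"] = pr.post_cell_id
            grp.attrs["sampling_rate_hz"] = float(pr.sampling_rate)
            grp.attrs["holding_potential_mv"] = float(pr.holding_potential)
            for k, (pre, post) in enumerate(pr.trials):
                t = grp.create_group(f"trial_{k}")
                t.create_dataset("pre_v", data=pre, track_times=False)
                t.create_dataset("post_i", data=post, track_times=False)


def read_pairs(path) -> list[PairRecording]:
    """Read every ordered pair direction stored in one HDF5 bundle."""
    out: list[PairRecording] = []
    with h5py.File(path, "r") as fh:
        dirs = sorted((k for k in fh if k.startswith("direction_")), key=lambda k: int(k.split("_")[1]))
        for d in dirs:
            grp = fh[d]
            if "sampling_rate_hz" not in grp.attrs:
                raise ValidationError(f"{path}/{d}: missing sampling_rate_hz")
            keys = sorted((k for k in grp if k.startswith("trial_")), key=lambda k: int(k.split("_")[1]))
            trials = [(grp[k]["pre_v"][()], grp[k]["post_i"][()]) for k in keys]
            out.append(
                PairRecording(
                    pair_id=str(grp.attrs["pair_id"]),
                    pre_cell_id=str(grp.attrs["pre_cell_id"]),
                    post_cell_id=str(grp.attrs["post_cell_id"]),
                    trials=trials,
                    sampling_rate=float(grp.attrs["sampling_rate_hz"]),
                    holding_potential=float(grp.attrs.get("holding_potential_mv", -50.0)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# parameter sheets
# ---------------------------------------------------------------------------

def read_parameter_sheet(path, extra_aliases: dict[str, str] | None = None,
                         require: tuple[str, ...] = ()) -> FeatureTable:
    """Read a delimited per-cell parameter sheet into a :class:`FeatureTable`.

    Column headers are matched case/punctuation-insensitively against the
    built-in alias table (extendable through ``extra_aliases``).  Unmapped
    columns are kept and tagged ``other`` (``label`` if non-numeric).
    ``require`` lists canonical names that must resolve; missing ones raise
    a :class:`ValidationError` naming them.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty parameter sheet")
    aliases = dict(COLUMN_ALIASES)
    if extra_aliases:
        aliases.update({_normalise_column(k): v for k, v in extra_aliases.items()})
    rename = {}
    for col in df.columns:
        canonical = aliases.get(_normalise_column(col))
        if canonical:
            rename[col] = canonical
    df = df.rename(columns=rename)
    missing = [name for name in require if name not in df.columns]
    if missing:
        raise ValidationError(f"{path}: required columns missing: {missing}")
    if "cell_id" in df.columns:
        df = df.set_index("cell_id")
    else:
        df.index = [f"cell_{i}" for i in range(len(df))]
    kinds = {}
    for col in df.columns:
        kind = _KIND_BY_PARAM.get(col)
        if kind is None:
            kind = "other" if pd.api.types.is_numeric_dtype(df[col]) else "label"
        kinds[col] = kind
    return FeatureTable(data=df, kinds=kinds)


def write_feature_table(table: FeatureTable, path) -> None:
    table.data.to_csv(path, index_label="cell_id")
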