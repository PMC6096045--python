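"""Morphological feature extraction from 3D neuron reconstructions.

Nine parameters enter the morphological clustering: process volume, 3D
convex-hull volume, lateral and vertical dendritic volume (relative to the
GL–EPL border), number of contacted glomeruli, soma × dendritic volume,
total dendritic length, dendritic density and the furthest Sholl intercept.
A tenth parameter, the 2D convex-hull area of the slice-plane projection,
is used only by the cell-class predictor.

Geometric conventions
---------------------
* Segments are conical frusta between parent and child nodes; where the
  parent is a soma node the child's radius is used at both ends so that a
  fat soma sphere does not inflate the first dendritic segment.
* A "dendrite" is the maximal subtree hanging off a single soma-attached
  stem node; the per-dendrite lateral/vertical criteria are evaluated on
  these stem subtrees.
* The border normal points from the EPL into the GL, so a stem lies in the
  EPL when every node has a strictly negative signed distance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .io_formats import SOMA, DENDRITE, GlomerularContext, NeuronMorphology

logger = logging.getLogger(__name__)

__all__ = [
    "MorphoFeatures",
    "process_volume",
    "dendritic_length",
    "convex_hull_volume",
    "hull2d_area",
    "furthest_sholl",
    "lateral_dendritic_volume",
    "vertical_dendritic_volume",
    "count_glomeruli",
    "dendritic_density",
    "soma_x_dendritic_volume",
    "soma_equivalent_diameter",
    "compute_morpho_features",
]

#: chord angle to the border plane below which an EPL dendrite counts as lateral
LATERAL_MAX_ANGLE_DEG = 30.0
#: half-angle of the vertical cone (full aperture 60°)
VERTICAL_CONE_HALF_ANGLE_DEG = 30.0
#: minimum volume fraction inside the cone for a vertical dendrite
VERTICAL_MIN_FRACTION = 0.85


@dataclass(frozen=True)
class MorphoFeatures:
    process_volume: float             # μm³
    convex_hull: float                # μm³
    lateral_dendritic_volume: float   # μm³
    vertical_dendritic_volume: float  # μm³
    n_glomeruli: float
    soma_x_dendritic_volume: float    # μm⁵
    dendritic_length: float           # μm
    dendritic_density: float
    furthest_sholl: float             # μm
    hull2d_area: float                # μm² (classifier-only)

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


# ---------------------------------------------------------------------------
# segment machinery
# ---------------------------------------------------------------------------

def _segments(morph: NeuronMorphology, structures=(DENDRITE, "axon")):
    """Yield (p0, p1, r0, r1) per parent→child edge with a non-soma child."""
    by_id = {n.node_id: n for n in morph.nodes}
    for n in morph.nodes:
        if n.parent_id is None or n.structure == SOMA:
            continue
        if n.structure not in structures:
            continue
        p = by_id[n.parent_id]
        r0 = n.radius if p.structure == SOMA else p.radius
        yield p.xyz, n.xyz, r0, n.radius


def _frustum_volume(p0, p1, r0, r1) -> float:
    length = float(np.linalg.norm(p1 - p0))
    return math.pi * length / 3.0 * (r0 * r0 + r0 * r1 + r1 * r1)


def _stems(morph: NeuronMorphology) -> list[list[int]]:
    """Node-id lists of the maximal non-soma subtrees attached to the soma."""
    children: dict[int, list[int]] = {}
    for n in morph.nodes:
        if n.parent_id is not None:
            children.setdefault(n.parent_id, []).append(n.node_id)
    by_id = {n.node_id: n for n in morph.nodes}
    stems = []
    for n in morph.nodes:
        if n.structure == SOMA or n.parent_id is None:
            continue
        if by_id[n.parent_id].structure == SOMA:
            # collect the whole subtree rooted at this stem node
            stack, subtree = [n.node_id], []
            while stack:
                nid = stack.pop()
                subtree.append(nid)
                stack.extend(children.get(nid, []))
            stems.append(subtree)
    return stems


def _stem_volume(morph: NeuronMorphology, stem: set[int]) -> float:
    by_id = {n.node_id: n for n in morph.nodes}
    total = 0.0
    for n in morph.nodes:
        if n.node_id in stem and n.parent_id is not None:
            p = by_id[n.parent_id]
            r0 = n.radius if p.structure == SOMA else p.radius
            total += _frustum_volume(p.xyz, n.xyz, r0, n.radius)
    return total


# ---------------------------------------------------------------------------
# the nine parameters
# ---------------------------------------------------------------------------

def process_volume(morph: NeuronMorphology) -> float:
    """Total volume of all processes as a sum of conical frusta (μm³)."""
    vol = sum(_frustum_volume(*seg) for seg in _segments(morph))
    if vol == 0.0:
        logger.warning("cell %s has no non-soma segments; process volume 0", morph.cell_id)
    return vol


def dendritic_length(morph: NeuronMorphology) -> float:
    """Total dendritic path length (μm); axon segments are excluded."""
    return sum(float(np.linalg.norm(p1 - p0)) for p0, p1, _, _ in _segments(morph, (DENDRITE,)))


def _all_points(morph: NeuronMorphology) -> np.ndarray:
    return np.array([[n.x, n.y, n.z] for n in morph.nodes])


def convex_hull_volume(morph: NeuronMorphology) -> float:
    """Volume of the smallest convex 3D shape around all nodes (μm³)."""
    pts = _all_points(morph)
    if len(pts) < 4:
        warnings.warn("fewer than 4 points; hull volume set to 0")
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate point set; hull volume set to 0")
        return 0.0


def hull2d_area(morph: NeuronMorphology) -> float:
    """Area of the smallest convex 2D shape around the x–y projection (μm²)."""
    pts = _all_points(morph)[:, :2]
    if len(pts) < 3:
        warnings.warn("fewer than 3 points; 2D hull area set to 0")
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2D hull: .volume is the area
    except QhullError:
        warnings.warn("collinear point set; 2D hull area set to 0")
        return 0.0


def furthest_sholl(morph: NeuronMorphology) -> float:
    """Largest Euclidean (sphere) distance from the soma root to a dendritic node."""
    root = morph.root.xyz
    dists = [
        float(np.linalg.norm(n.xyz - root))
        for n in morph.nodes
        if n.structure == DENDRITE
    ]
    return max(dists, default=0.0)


def _stem_chord(morph: NeuronMorphology, stem: list[int]) -> np.ndarray:
    """Chord from the soma-attachment node to the farthest-by-path tip."""
    by_id = {n.node_id: n for n in morph.nodes}
    stem_set = set(stem)
    root_id = stem[0]
    # path lengths from the stem root
    dist = {root_id: 0.0}
    order = [root_id]
    children: dict[int, list[int]] = {}
    for nid in stem:
        n = by_id[nid]
        if n.parent_id in stem_set:
            children.setdefault(n.parent_id, []).append(nid)
    while order:
        nid = order.pop()
        for c in children.get(nid, []):
            dist[c] = dist[nid] + float(np.linalg.norm(by_id[c].xyz - by_id[nid].xyz))
            order.append(c)
    tip = max(dist, key=dist.get)
    return by_id[tip].xyz - by_id[root_id].xyz


def _epl_stems(morph: NeuronMorphology, ctx: GlomerularContext) -> list[list[int]]:
    """Stems whose nodes all lie strictly on the EPL side of the border."""
    by_id = {n.node_id: n for n in morph.nodes}
    out = []
    for stem in _stems(morph):
        sd = ctx.signed_distance(np.array([by_id[nid].xyz for nid in stem]))
        if np.all(sd < 0):
            out.append(stem)
    return out


def lateral_dendritic_volume(morph: NeuronMorphology, ctx: GlomerularContext) -> float:
    """Summed volume of EPL dendrites whose chord runs <30° to the border (μm³)."""
    total = 0.0
    for stem in _epl_stems(morph, ctx):
        chord = _stem_chord(morph, stem)
        norm = float(np.linalg.norm(chord))
        if norm == 0.0:
            continue
        angle_to_plane = math.degrees(math.asin(abs(float(chord @ ctx.plane_normal)) / norm))
        if angle_to_plane < LATERAL_MAX_ANGLE_DEG:
            total += _stem_volume(morph, set(stem))
    return total


def vertical_dendritic_volume(morph: NeuronMorphology, ctx: GlomerularContext) -> float:
    """Summed volume of EPL dendrites with ≥85% of their volume in the 60° cone (μm³).

    The cone apex sits at the stem's soma-attachment node, its axis points
    from the GL into the EPL (−normal) and its half-angle is 30°.  The
    volume fraction is evaluated per segment at the midpoint, weighted by
    frustum volume.
    """
    by_id = {n.node_id: n for n in morph.nodes}
    cos_half = math.cos(math.radians(VERTICAL_CONE_HALF_ANGLE_DEG))
    axis = -ctx.plane_normal
    total = 0.0
    for stem in _epl_stems(morph, ctx):
        stem_set = set(stem)
        apex = by_id[stem[0]].xyz
        vol_in, vol_all = 0.0, 0.0
        for n in morph.nodes:
            if n.node_id not in stem_set or n.parent_id is None:
                continue
            p = by_id[n.parent_id]
            r0 = n.radius if p.structure == SOMA else p.radius
            v = _frustum_volume(p.xyz, n.xyz, r0, n.radius)
            mid = 0.5 * (p.xyz + n.xyz) - apex
            norm = float(np.linalg.norm(mid))
            inside = norm == 0.0 or (float(mid @ axis) / norm) >= cos_half
            vol_all += v
            if inside:
                vol_in += v
        if vol_all > 0 and vol_in / vol_all >= VERTICAL_MIN_FRACTION:
            total += vol_all
    return total


def count_glomeruli(morph: NeuronMorphology, ctx: GlomerularContext) -> int:
    """Number of glomerulus spheres passed through by any process.

    A sphere counts when the closest approach of any segment's axis to the
    sphere centre is smaller than the sphere radius (process radii ignored).
    """
    if not ctx.glomeruli:
        return 0
    segs = list(_segments(morph))
    if not segs:
        return 0
    p0 = np.array([s[0] for s in segs])
    p1 = np.array([s[1] for s in segs])
    d = p1 - p0
    dd = np.einsum("ij,ij->i", d, d)
    count = 0
    for center, radius, _ in ctx.glomeruli:
        w = center - p0
        t = np.clip(np.divide(np.einsum("ij,ij->i", w, d), dd, where=dd > 0,
                              out=np.zeros(len(segs))), 0.0, 1.0)
        closest = p0 + t[:, None] * d
        dist = np.linalg.norm(closest - center, axis=1)
        if np.any(dist < radius):
            count += 1
    return count


def dendritic_density(morph: NeuronMorphology, ctx: GlomerularContext | None = None,
                      variant: str = "process") -> float:
    """Dendritic density (dimensionless).

    ``variant='process'`` (default): process volume / convex-hull volume.
    ``variant='largest'``: volume of the largest dendrite / hull volume.
    """
    hull = convex_hull_volume(morph)
    if hull == 0.0:
        warnings.warn("zero hull volume; dendritic density undefined, returning 0")
        return 0.0
    if variant == "largest":
        numerator = max((_stem_volume(morph, set(s)) for s in _stems(morph)), default=0.0)
    elif variant == "process":
        numerator = process_volume(morph)
    else:
        raise ValueError(f"unknown density variant {variant!r}")
    return numerator / hull


def soma_x_dendritic_volume(morph: NeuronMorphology) -> float:
    """Soma outline area × volume of the largest single dendritic subtree (μm⁵)."""
    largest = max((_stem_volume(morph, set(s)) for s in _stems(morph)), default=0.0)
    return morph.effective_soma_area() * largest


def soma_equivalent_diameter(soma_area: float, aspect_ratio: float = 1.3) -> float:
    """Shorter diameter of an ellipse with the given aspect ratio and area.

    d = 2·√(area / (aspect_ratio·π)); the default aspect ratio is 1.3.
    """
    if soma_area <= 0:
        raise ValueError("soma area must be positive")
    return 2.0 * math.sqrt(soma_area / (aspect_ratio * math.pi))


def compute_morpho_features(morph: NeuronMorphology, ctx: GlomerularContext,
                            density_variant: str = "process") -> MorphoFeatures:
    """All nine clustering parameters plus the classifier's 2D hull area."""
    if ctx.soma_area and morph.soma_area == 0.0:
        morph.soma_area = float(ctx.soma_area)
    lateral = lateral_dendritic_volume(morph, ctx)
    vertical = vertical_dendritic_volume(morph, ctx)
    return MorphoFeatures(
        process_volume=process_volume(morph),
        convex_hull=convex_hull_volume(morph),
        lateral_dendritic_volume=lateral,
        vertical_dendritic_volume=vertical,
        n_glomeruli=float(count_glomeruli(morph, ctx)),
        soma_x_dendritic_volume=soma_x_dendritic_volume(morph),
        dendritic_length=dendritic_length(morph),
        dendritic_density=dendritic_density(morph, ctx, variant=density_variant),
        furthest_sholl=furthest_sholl(morph),
        hull2d_area=hull2d_area(morph),
    )


def lateral_vertical_overlap(morph: NeuronMorphology, ctx: GlomerularContext) -> int:
    """Number of stems matching both the lateral and the vertical criterion.

    The two criteria are mutually exclusive by construction (a chord within
    30° of the border cannot anchor a ≥85% in-cone subtree of the 60° cone);
    this helper exists so that cohorts can assert it.
    """
    by_id = {n.node_id: n for n in morph.nodes}
    cos_half = math.cos(math.radians(VERTICAL_CONE_HALF_ANGLE_DEG))
    axis = -ctx.plane_normal
    overlap = 0
    for stem in _epl_stems(morph, ctx):
        chord = _stem_chord(morph, stem)
        norm = float(np.linalg.norm(chord))
        is_lat = norm > 0 and math.degrees(
            math.asin(abs(float(chord @ ctx.plane_normal)) / norm)) < LATERAL_MAX_ANGLE_DEG
        stem_set = set(stem)
        apex = by_id[stem[0]].xyz
        vol_in, vol_all = 0.0, 0.0
        for n in morph.nodes:
            if n.node_id not in stem_set or n.parent_id is None:
                continue
            p = by_id[n.parent_id]
            r0 = n.radius if p.structure == SOMA else p.radius
            v = _frustum_volume(p.xyz, n.xyz, r0, n.radius)
            mid = 0.5 * (p.xyz + n.xyz) - apex
            nn = float(np.linalg.norm(mid))
            vol_all += v
            if nn == 0.0 or (float(mid @ axis) / nn) >= cos_half:
                vol_in += v
        is_vert = vol_all > 0 and vol_in / vol_all >= VERTICAL_MIN_FRACTION
        if is_lat and is_vert:
            overlap += 1
    return overlap
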