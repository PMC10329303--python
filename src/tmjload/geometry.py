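"""Parametric, bilaterally symmetric masticatory geometry.

The original study geometry was cadaver-derived and is not available, so
this module generates an idealized stand-in: a spherical-cap condyle under
a congruent spherical-cap fossa on each side, with the articular disc as a
thin lens riding between them, dental contact points engaged in the
closed-jaw reference pose, and twelve named masticatory muscle groups per
side with skull-fixed origins and mandible-fixed insertions.

Coordinate convention (all lengths in mm): right-handed, midsagittal plane
x = 0, +x toward the anatomical right, +y anterior, +z superior.  The world
origin is the midpoint between the two fossa centres; the closed-jaw pose
is the reference pose in which mandible-frame and world coordinates agree.

The unilateral ramus-shortening perturbation translates the condylar
fragment (condyle centre, condylar contact patch, disc patches) along the
fixed unit axis from mid-condyle toward gonion, leaving every contralateral
and midline entity untouched.  This mimics proximal-fragment displacement
by lateral pterygoid traction after a condylar fracture.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryParams",
    "SurfacePatch",
    "MasticatoryGeometry",
    "ShorteningSpec",
    "build_geometry",
    "shorten_ramus",
    "classify_displacement",
    "mirror_geometry",
    "MUSCLE_TABLE",
]

SIDES = ("right", "left")

# unit axis from condyle centre toward gonion: the ramus long axis, modeled
# as straight inferior (gonion directly below the condyle centre)
_RAMUS_AXIS = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the idealized masticatory geometry (adult range).

    The fossa-condyle radial gap must equal the resting soft-tissue stack
    (two cartilage layers plus the disc), which is the thickness the
    elastic-foundation contact compresses through.
    """

    intercondylar_width: float = 100.0   # mm, fossa centre to fossa centre
    ramus_height: float = 45.0           # mm, condyle centre to gonion
    mandible_body_length: float = 80.0   # mm, gonion to incisal point
    cartilage_thickness: float = 1.5     # mm per layer (fossa and condyle)
    disc_thickness: float = 3.0          # mm
    fossa_radius: float = 16.0           # mm (bony fossa sphere)
    condyle_radius: float = 10.0         # mm (bony condyle sphere)
    occlusal_precompression: float = 0.8  # mm, stack preload of the seated condyle at occlusion
    surface_resolution: int = 12         # polar rings per contact patch
    mandible_mass: float = 0.44          # kg
    mandible_inertia: tuple[float, float, float] = (800.0, 1200.0, 900.0)  # kg mm^2, principal

    def __post_init__(self) -> None:
        for name in (
            "intercondylar_width", "ramus_height", "mandible_body_length",
            "cartilage_thickness", "disc_thickness", "fossa_radius",
            "condyle_radius", "mandible_mass",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.condyle_radius >= self.fossa_radius:
            raise ValueError(
                "condyle_radius must be smaller than fossa_radius "
                f"(got condyle_radius={self.condyle_radius}, fossa_radius={self.fossa_radius})"
            )
        if self.surface_resolution < 4:
            raise ValueError(f"surface_resolution must be >= 4, got {self.surface_resolution}")
        if any(i <= 0 for i in self.mandible_inertia):
            raise ValueError(f"mandible_inertia entries must be positive, got {self.mandible_inertia}")
        if not 0 <= self.occlusal_precompression < self.disc_thickness:
            raise ValueError("occlusal_precompression must be in [0, disc_thickness)")
        gap = self.fossa_radius - self.condyle_radius
        stack = 2.0 * self.cartilage_thickness + self.disc_thickness
        if abs(gap - stack) > 1e-9:
            raise ValueError(
                f"fossa_radius - condyle_radius ({gap}) must equal the soft-tissue stack "
                f"2*cartilage_thickness + disc_thickness ({stack})"
            )

    @property
    def stack_thickness(self) -> float:
        """Resting thickness (mm) of the compressible fossa-disc-condyle stack."""
        return self.fossa_radius - self.condyle_radius


@dataclass
class SurfacePatch:
    """Triangulated spherical-cap contact surface.

    ``vertices`` (nv, 3) and ``faces`` (nf, 3) define the mesh; ``centers``,
    ``normals`` (outward, unit) and ``areas`` are per-face.  ``sphere_center``
    and ``sphere_radius`` record the generating sphere; ``cap_axis`` (unit)
    and ``cap_angle`` (rad) its angular extent, needed by the reduced-order
    contact queries.
    """

    vertices: np.ndarray
    faces: np.ndarray
    centers: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    sphere_center: np.ndarray
    sphere_radius: float
    cap_axis: np.ndarray
    cap_angle: float

    def translated(self, delta: np.ndarray) -> "SurfacePatch":
        return SurfacePatch(
            vertices=self.vertices + delta,
            faces=self.faces.copy(),
            centers=self.centers + delta,
            normals=self.normals.copy(),
            areas=self.areas.copy(),
            sphere_center=self.sphere_center + delta,
            sphere_radius=self.sphere_radius,
            cap_axis=self.cap_axis.copy(),
            cap_angle=self.cap_angle,
        )


def _spherical_cap(center, radius, cap_angle, n_rings, outward=True, axis=None) -> SurfacePatch:
    """Triangulate a spherical cap about ``axis`` (default +z) with ``n_rings``
    polar rings."""
    center = np.asarray(center, dtype=float)
    thetas = np.linspace(0.0, cap_angle, n_rings + 1)
    verts = [np.array([0.0, 0.0, radius])]
    rings: list[np.ndarray] = []
    for th in thetas[1:]:
        n_az = max(6, int(round(2.0 * np.pi * np.sin(th) / (cap_angle / n_rings))))
        phi = 2.0 * np.pi * np.arange(n_az) / n_az
        ring = np.stack(
            [radius * np.sin(th) * np.cos(phi),
             radius * np.sin(th) * np.sin(phi),
             radius * np.cos(th) * np.ones_like(phi)], axis=1)
        rings.append(np.arange(len(verts), len(verts) + n_az))
        verts.extend(ring)
    verts = np.asarray(verts)

    faces: list[tuple[int, int, int]] = []
    first = rings[0]
    for j in range(len(first)):
        faces.append((0, first[j], first[(j + 1) % len(first)]))
    for a, b in zip(rings[:-1], rings[1:]):
        # stitch two rings of (possibly) different azimuthal counts
        na, nb = len(a), len(b)
        i = j = 0
        while i < na or j < nb:
            ai, aj = a[i % na], a[(i + 1) % na]
            bi, bj = b[j % nb], b[(j + 1) % nb]
            # advance the ring whose next azimuth is smaller
            if (i + 1) / na <= (j + 1) / nb and i < na:
                faces.append((ai, bi, aj))
                i += 1
            elif j < nb:
                faces.append((aj, bi, bj))
                j += 1
            else:
                break
    faces_arr = np.asarray(faces, dtype=int)

    tri = verts[faces_arr]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    keep = areas > 1e-12
    faces_arr, areas, cross = faces_arr[keep], areas[keep], cross[keep]
    centers = verts[faces_arr].mean(axis=1)
    # radial outward normals (exact for the generating sphere)
    normals = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    sign = 1.0 if outward else -1.0

    cap_axis = np.array([0.0, 0.0, 1.0])
    if axis is not None:
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        # rotate +z onto the requested cap axis (rotation in the y-z plane for
        # a midsagittally symmetric axis; general axis handled via Rodrigues)
        v = np.cross(cap_axis, axis)
        s, c = np.linalg.norm(v), float(cap_axis @ axis)
        if s > 1e-12:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
            verts = verts @ rot.T
            centers = centers @ rot.T
            normals = normals @ rot.T
            cap_axis = axis
        elif c < 0:
            verts, centers, normals = -verts, -centers, -normals
            cap_axis = axis

    return SurfacePatch(
        vertices=verts + center,
        faces=faces_arr,
        centers=centers + center,
        normals=sign * normals,
        areas=areas,
        sphere_center=center.copy(),
        sphere_radius=float(radius),
        cap_axis=cap_axis,
        cap_angle=float(cap_angle),
    )


def _mirror_x(v: np.ndarray) -> np.ndarray:
    out = np.array(v, dtype=float, copy=True)
    out[..., 0] = -out[..., 0]
    return out


def _mirror_patch(p: SurfacePatch) -> SurfacePatch:
    return SurfacePatch(
        vertices=_mirror_x(p.vertices),
        faces=p.faces[:, ::-1].copy(),  # restore outward winding
        centers=_mirror_x(p.centers),
        normals=_mirror_x(p.normals),
        areas=p.areas.copy(),
        sphere_center=_mirror_x(p.sphere_center),
        sphere_radius=p.sphere_radius,
        cap_axis=_mirror_x(p.cap_axis),
        cap_angle=p.cap_angle,
    )


# muscle table: name -> (origin (skull), insertion (mandible), peak force N, role)
# Right-side coordinates; the left side is the exact x-mirror.  Positions are
# idealized adult values in the coordinate convention above; peak forces are
# physiological-cross-section-scale values (only relative loads are
# interpreted downstream).
MUSCLE_TABLE: dict[str, dict] = {
    "superficial masseter":      {"origin": (50.0, 30.0, -5.0),  "insertion": (45.0, 15.0, -40.0), "peak": 104.5, "role": "closer"},
    "deep posterior masseter":   {"origin": (50.0, 12.0, -3.0),  "insertion": (46.0, 8.0, -30.0),  "peak": 44.0,  "role": "closer"},
    "deep anterior masseter":    {"origin": (50.0, 25.0, -4.0),  "insertion": (45.0, 18.0, -32.0), "peak": 44.0,  "role": "closer"},
    "posterior temporalis":      {"origin": (52.0, -25.0, 35.0), "insertion": (48.0, 10.0, -8.0),  "peak": 41.2,  "role": "closer"},
    "anterior temporalis":       {"origin": (50.0, 5.0, 45.0),   "insertion": (48.0, 14.0, -6.0),  "peak": 88.0, "role": "closer"},
    "medial pterygoid":          {"origin": (28.0, 22.0, -5.0),  "insertion": (43.0, 12.0, -40.0), "peak": 93.5, "role": "closer"},
    "inferior lateral pterygoid": {"origin": (36.0, 30.0, -4.0), "insertion": (47.0, 4.0, -5.0),   "peak": 82.5, "role": "opener"},
    "posterior lateral pterygoid": {"origin": (38.0, 27.0, 0.0), "insertion": (47.0, 3.0, -2.0),   "peak": 37.9,  "role": "opener"},
    "digastric":                 {"origin": (10.0, 35.0, -75.0), "insertion": (8.0, 64.0, -46.0),  "peak": 31.0,  "role": "opener"},
    "geniohyoid":                {"origin": (5.0, 38.0, -72.0),  "insertion": (3.0, 66.0, -44.0),  "peak": 24.0,  "role": "opener"},
    "posterior mylohyoid":       {"origin": (8.0, 36.0, -73.0),  "insertion": (25.0, 45.0, -42.0), "peak": 13.8,  "role": "opener"},
    "anterior mylohyoid":        {"origin": (6.0, 37.0, -73.0),  "insertion": (12.0, 58.0, -44.0), "peak": 20.6,  "role": "opener"},
}


@dataclass
class MasticatoryGeometry:
    """Landmarks, contact surfaces, dental contacts and muscle attachments.

    ``landmarks[side]`` holds condyle_center / gonion / coronoid per side and
    the midline incisal_point / menton; ``fossa_center[side]`` is skull-fixed.
    ``surfaces[side]`` holds the fossa patch, disc superior/inferior patches
    and the condyle patch.  ``dental_points`` are mandibular contact points
    whose maxillary counterparts coincide in the closed reference pose.
    ``shortening_axis[side]`` is the frozen mid-condyle -> gonion unit axis of
    the unshortened geometry.  ``applied_shortening[side]`` (mm) records the
    perturbation already applied.
    """

    params: GeometryParams
    landmarks: dict
    fossa_center: dict[str, np.ndarray]
    surfaces: dict[str, dict[str, SurfacePatch]]
    dental_points: dict[str, np.ndarray]
    maxillary_points: dict[str, np.ndarray]
    muscles: dict[str, dict[str, dict]]
    shortening_axis: dict[str, np.ndarray]
    applied_shortening: dict[str, float] = field(default_factory=lambda: {"right": 0.0, "left": 0.0})
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))


def build_geometry(params: GeometryParams | None = None) -> MasticatoryGeometry:
    """Construct the baseline (mirror-symmetric, closed-pose) geometry."""
    p = params or GeometryParams()
    w2 = p.intercondylar_width / 2.0

    cond_r = np.array([w2, 0.0, 0.0])
    gonion_r = cond_r + p.ramus_height * _RAMUS_AXIS
    coronoid_r = np.array([w2 - 2.0, 12.0, -6.0])

    # incisal point on the midsagittal plane at |incisal - gonion| = body length
    dz = 15.0
    dy2 = p.mandible_body_length**2 - gonion_r[0] ** 2 - dz**2
    if dy2 <= 0:
        raise ValueError(
            "mandible_body_length too short for the given intercondylar_width "
            f"(need > {np.hypot(gonion_r[0], dz):.1f} mm)"
        )
    incisal = np.array([0.0, gonion_r[1] + np.sqrt(dy2), gonion_r[2] + dz])
    menton = incisal + np.array([0.0, -2.0, -16.0])

    landmarks = {
        "right": {"condyle_center": cond_r, "gonion": gonion_r, "coronoid": coronoid_r},
        "left": {
            "condyle_center": _mirror_x(cond_r),
            "gonion": _mirror_x(gonion_r),
            "coronoid": _mirror_x(coronoid_r),
        },
        "incisal_point": incisal,
        "menton": menton,
    }

    n = p.surface_resolution
    cart, disc = p.cartilage_thickness, p.disc_thickness
    # The articular cap is tilted anteriorly but kept entirely above the
    # equator (tilt + extent <= 90 deg): its anterior part plays the role of
    # the eminence slope loaded when the condyle is pulled forward at wide
    # opening, while an inferiorly displaced (shortened-ramus) condyle drops
    # clear of the cap instead of wedging into a sub-equatorial lip.
    tilt = np.deg2rad(30.0)
    cap_axis = np.array([0.0, np.sin(tilt), np.cos(tilt)])
    fossa_cap = np.deg2rad(60.0)
    condyle_cap = np.deg2rad(75.0)
    disc_cap = np.deg2rad(65.0)

    # the seated condyle is precompressed into the soft-tissue stack at
    # occlusion: the fossa sphere centre sits slightly below the condyle
    # centre along the cap axis, giving a nonzero closed-mouth joint load
    fossa_center_r = cond_r - p.occlusal_precompression * cap_axis
    fossa_r = _spherical_cap(fossa_center_r, p.fossa_radius, fossa_cap, n, outward=False, axis=cap_axis)
    disc_sup_r = _spherical_cap(cond_r, p.fossa_radius - cart, disc_cap, n, outward=True, axis=cap_axis)
    disc_inf_r = _spherical_cap(cond_r, p.condyle_radius + cart, disc_cap, n, outward=False, axis=cap_axis)
    condyle_r = _spherical_cap(cond_r, p.condyle_radius, condyle_cap, n, outward=True, axis=cap_axis)

    surfaces = {
        "right": {"fossa": fossa_r, "disc_superior": disc_sup_r,
                  "disc_inferior": disc_inf_r, "condyle": condyle_r},
        "left": {"fossa": _mirror_patch(fossa_r), "disc_superior": _mirror_patch(disc_sup_r),
                 "disc_inferior": _mirror_patch(disc_inf_r), "condyle": _mirror_patch(condyle_r)},
    }

    # full-arch occlusal contacts: incisor, premolar and two molar pairs;
    # the second molars sit nearly beneath the elevator resultant so closed-
    # mouth load redistributes within the tooth row
    occl_z = incisal[2] + 1.0
    premolar_r = np.array([36.0, 45.0, occl_z])
    molar1_r = np.array([32.0, 30.0, occl_z])
    molar2_r = np.array([28.0, 18.0, occl_z])
    dental_points = {
        "incisal": incisal.copy(),
        "right_premolar": premolar_r,
        "left_premolar": _mirror_x(premolar_r),
        "right_molar": molar1_r,
        "left_molar": _mirror_x(molar1_r),
        "right_second_molar": molar2_r,
        "left_second_molar": _mirror_x(molar2_r),
    }
    maxillary_points = {k: v.copy() for k, v in dental_points.items()}

    muscles: dict[str, dict[str, dict]] = {"right": {}, "left": {}}
    for name, m in MUSCLE_TABLE.items():
        o = np.asarray(m["origin"], dtype=float)
        i = np.asarray(m["insertion"], dtype=float)
        muscles["right"][name] = {"origin": o, "insertion": i, "peak": m["peak"], "role": m["role"]}
        muscles["left"][name] = {"origin": _mirror_x(o), "insertion": _mirror_x(i),
                                 "peak": m["peak"], "role": m["role"]}

    axis = {
        "right": (gonion_r - cond_r) / np.linalg.norm(gonion_r - cond_r),
        "left": _mirror_x((gonion_r - cond_r) / np.linalg.norm(gonion_r - cond_r)),
    }

    com = np.array([0.0, 0.55 * incisal[1], 0.7 * gonion_r[2]])

    return MasticatoryGeometry(
        params=p,
        landmarks=landmarks,
        fossa_center={"right": fossa_center_r.copy(), "left": _mirror_x(fossa_center_r)},
        surfaces=surfaces,
        dental_points=dental_points,
        maxillary_points=maxillary_points,
        muscles=muscles,
        shortening_axis=axis,
        com=com,
    )


@dataclass(frozen=True)
class ShorteningSpec:
    """Unilateral ramus shortening: which side, and by how much (mm)."""

    side: str = "right"
    distance_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.distance_mm < 0:
            raise ValueError(f"distance_mm must be >= 0, got {self.distance_mm}")
        if self.distance_mm > 20:
            raise ValueError(f"distance_mm must be <= 20 mm, got {self.distance_mm}")


def shorten_ramus(geom: MasticatoryGeometry, spec: ShorteningSpec) -> MasticatoryGeometry:
    """Translate the condylar fragment of ``spec.side`` toward gonion.

    The translation axis is the frozen mid-condyle -> gonion unit axis stored
    on the unshortened geometry, so repeated applications are additive.  The
    condyle centre, condylar contact patch and both disc patches move with
    the fragment; the fossa, all contralateral and all midline entities are
    untouched.  Returns a new geometry; the input is not mutated.
    """
    if spec.side not in geom.surfaces:
        raise ValueError(f"side {spec.side!r} not present in geometry")
    out = copy.deepcopy(geom)
    if spec.distance_mm == 0.0:
        return out
    delta = spec.distance_mm * geom.shortening_axis[spec.side]
    side = spec.side
    out.landmarks[side]["condyle_center"] = geom.landmarks[side]["condyle_center"] + delta
    for patch_name in ("condyle", "disc_superior", "disc_inferior"):
        out.surfaces[side][patch_name] = geom.surfaces[side][patch_name].translated(delta)
    out.applied_shortening[side] = geom.applied_shortening[side] + spec.distance_mm
    return out


def classify_displacement(distance_mm: float) -> str:
    """Severity category: minimal (< 2 mm), moderate (2-15 mm), severe (> 15 mm)."""
    if distance_mm < 0:
        raise ValueError(f"distance_mm must be >= 0, got {distance_mm}")
    if distance_mm < 2.0:
        return "minimal"
    if distance_mm <= 15.0:
        return "moderate"
    return "severe"


def mirror_geometry(geom: MasticatoryGeometry) -> MasticatoryGeometry:
    """Reflect the whole geometry about the midsagittal plane (x -> -x)."""
    out = copy.deepcopy(geom)
    for side_from, side_to in (("right", "left"), ("left", "right")):
        out.landmarks[side_to] = {k: _mirror_x(v) for k, v in geom.landmarks[side_from].items()}
        out.fossa_center[side_to] = _mirror_x(geom.fossa_center[side_from])
        out.surfaces[side_to] = {k: _mirror_patch(v) for k, v in geom.surfaces[side_from].items()}
        out.muscles[side_to] = {
            name: {"origin": _mirror_x(m["origin"]), "insertion": _mirror_x(m["insertion"]),
                   "peak": m["peak"], "role": m["role"]}
            for name, m in geom.muscles[side_from].items()
        }
        out.shortening_axis[side_to] = _mirror_x(geom.shortening_axis[side_from])
        out.applied_shortening[side_to] = geom.applied_shortening[side_from]
    out.landmarks["incisal_point"] = _mirror_x(geom.landmarks["incisal_point"])
    out.landmarks["menton"] = _mirror_x(geom.landmarks["menton"])
    def _swap(name):
        if name.startswith("right_"):
            return "left_" + name[6:]
        if name.startswith("left_"):
            return "right_" + name[5:]
        return name

    out.dental_points = {k: _mirror_x(geom.dental_points[_swap(k)]) for k in geom.dental_points}
    out.maxillary_points = {k: _mirror_x(geom.maxillary_points[_swap(k)]) for k in geom.maxillary_points}
    out.com = _mirror_x(geom.com)
    return out


def geometry_manifest(geom: MasticatoryGeometry) -> dict:
    """JSON-serializable landmark / attachment / dental manifest."""
    def arr(v):
        return [float(x) for x in np.asarray(v)]

    return {
        "landmarks": {
            "right": {k: arr(v) for k, v in geom.landmarks["right"].items()},
            "left": {k: arr(v) for k, v in geom.landmarks["left"].items()},
            "incisal_point": arr(geom.landmarks["incisal_point"]),
            "menton": arr(geom.landmarks["menton"]),
        },
        "fossa_center": {s: arr(c) for s, c in geom.fossa_center.items()},
        "dental_points": {k: arr(v) for k, v in geom.dental_points.items()},
        "muscles": {
            side: {
                name: {"origin": arr(m["origin"]), "insertion": arr(m["insertion"]),
                       "peak_force_N": m["peak"], "role": m["role"]}
                for name, m in geom.muscles[side].items()
            }
            for side in SIDES
        },
        "applied_shortening_mm": dict(geom.applied_shortening),
        "center_of_mass": arr(geom.com),
    }


def export_geometry(geom: MasticatoryGeometry, outdir) -> list[str]:
    """Write contact patches as PLY meshes plus a JSON manifest; returns paths."""
    import pathlib

    import trimesh

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for side in SIDES:
        for name, patch in geom.surfaces[side].items():
            mesh = trimesh.Trimesh(vertices=patch.vertices, faces=patch.faces, process=False)
            path = outdir / f"{side}_{name}.ply"
            mesh.export(path, file_type="ply", encoding="ascii")
            written.append(str(path))
    manifest_path = outdir / "geometry_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(geometry_manifest(geom), fh, indent=2)
    written.append(str(manifest_path))
    return written
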