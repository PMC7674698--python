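"""Stylized voxel phantom of a 5-year-old child.

The phantom is a trunk-only anthropomorphic model built from geometric
primitives (MIRD-style): an elliptical-cylinder soft-tissue body containing
ellipsoidal organs whose voxelized volumes are calibrated to the published
reference volumes within 1%.  Anatomical constraints follow the qualitative
statements the analysis relies on: the kidneys sit posteriorly with the right
kidney's superior pole abutting the inferior liver surface, the testes lie
inferior to the bladder, and the ovaries flank the bladder symmetrically.

Coordinates are right-handed with +x toward the patient's left, +y posterior
and +z superior; "left kidney" means the patient's left.  Voxels are isotropic
(default 2 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import Material, material_from_table

__all__ = [
    "Ellipsoid", "OrganSpec", "Phantom", "build_reference_phantom",
    "organ_mass", "mirror", "write_phantom", "read_phantom",
]

BODY_LABEL = 1

# volume-calibration tolerances (fraction of target volume)
_CAL_PREFERRED = 0.005
_CAL_REQUIRED = 0.010


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid primitive (cm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def scaled(self, s: float) -> "Ellipsoid":
        return Ellipsoid(self.center, tuple(a * s for a in self.semi_axes))

    def shifted(self, dz: float) -> "Ellipsoid":
        cx, cy, cz = self.center
        return Ellipsoid((cx, cy, cz + dz), self.semi_axes)


@dataclass(frozen=True)
class OrganSpec:
    """One labelled organ region: shape(s), side and material."""

    name: str
    side: str  # left | right | none
    target_volume_cc: float
    material: Material = field(hash=False)
    shapes: tuple[Ellipsoid, ...] = field(hash=False)


@dataclass
class Phantom:
    """3-D organ-label grid plus organ and material bookkeeping."""

    labels: np.ndarray                 # (nx, ny, nz) uint16, 0 = background
    voxel_cm: float
    origin_cm: tuple[float, float, float]
    organs: dict[int, OrganSpec]       # includes the soft-tissue body
    sex: str

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_cm ** 3

    def id_of(self, name: str) -> int:
        for oid, spec in self.organs.items():
            if spec.name == name:
                return oid
        raise KeyError(f"no organ named {name!r}")

    def organ_names(self) -> tuple[str, ...]:
        return tuple(spec.name for spec in self.organs.values())

    def voxel_count(self, organ_id: int) -> int:
        return int(np.count_nonzero(self.labels == organ_id))

    def organ_volume_cc(self, organ_id: int) -> float:
        return self.voxel_count(organ_id) * self.voxel_volume_cc

    def voxel_centers(self, organ_id: int) -> np.ndarray:
        """(n, 3) centre coordinates (cm) of the organ's voxels."""
        idx = np.argwhere(self.labels == organ_id)
        return (idx + 0.5) * self.voxel_cm + np.asarray(self.origin_cm)


# ---------------------------------------------------------------------------
# reference anatomy
#
# Centres/semi-axes in cm, tuned once so that all organs fit inside the body
# envelope without mutual overlap at voxel sizes down to 1 mm.  Volumes are
# re-calibrated to the reference targets at build time, so the semi-axes
# below only fix shape proportions and location.
# ---------------------------------------------------------------------------

_BODY_HALF_AXES = (10.2, 7.2)     # x, y
_BODY_Z = (0.0, 49.0)

_ANATOMY: dict[str, dict] = {
    "lung": dict(side_pair=True, material="lung", volume=980.0, shapes=[
        Ellipsoid((5.4, 0.3, 41.8), (3.4, 4.5, 6.2))]),
    "heart": dict(side_pair=False, material="heart", volume=218.0, shapes=[
        Ellipsoid((0.3, -2.0, 37.5), (2.7, 2.8, 4.2))]),
    "liver": dict(side_pair=False, material="liver", volume=562.0, shapes=[
        Ellipsoid((-3.0, -0.8, 29.6), (6.5, 5.0, 4.1))]),
    "kidney": dict(side_pair=True, material="kidney", volume=104.76, shapes=[
        Ellipsoid((4.6, 2.8, 22.5), (1.95, 1.35, 4.75))]),
    "stomach": dict(side_pair=False, material="stomach", volume=119.4, shapes=[
        Ellipsoid((5.2, -2.6, 26.5), (2.6, 2.3, 4.0))]),
    "small_intestine": dict(side_pair=False, material="small_intestine", volume=265.0,
                            shapes=[Ellipsoid((0.0, -1.8, 19.0), (6.5, 3.2, 3.0))]),
    "colon": dict(side_pair=False, material="colon", volume=149.7, shapes=[
        Ellipsoid((0.0, -2.8, 13.0), (6.3, 2.2, 2.6))]),
    "testis": dict(side_pair=True, material="testis", volume=1.57, shapes=[
        Ellipsoid((1.0, -2.5, 2.8), (0.55, 0.55, 0.62))]),
    "ovary": dict(side_pair=True, material="ovary", volume=1.66, shapes=[
        Ellipsoid((4.0, -2.0, 8.0), (0.55, 0.58, 0.62))]),
}

# bladder: sphere-in-sphere; urine content volume is a stylized half-full
# paediatric bladder, wall mass 25 g (see docs/methods.md)
_BLADDER_CENTER = (0.0, -2.47, 7.03)  # off-lattice in y/z to decorrelate voxel radii
_URINE_VOLUME_CC = 70.0
_BLADDER_WALL_MASS_G = 25.0

# placement order: each organ conforms to the ones already placed;
# the liver, placed after the kidneys, wraps the right kidney superior pole
_BUILD_ORDER = ("lung", "heart", "kidney", "liver", "stomach",
                "small_intestine", "colon", "bladder", "gonads")


def _mirrored(e: Ellipsoid) -> Ellipsoid:
    (cx, cy, cz) = e.center
    return Ellipsoid((-cx, cy, cz), e.semi_axes)


class _Grid:
    def __init__(self, voxel_cm: float):
        self.voxel = voxel_cm
        # symmetric x-extent so mirror flips map voxel centres onto centres
        self.origin = (-10.6, -7.6, -0.4)
        self.shape = (int(round(21.2 / voxel_cm)),
                      int(round(15.2 / voxel_cm)),
                      int(round(50.0 / voxel_cm)))

    def centers_1d(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.voxel

    def ellipsoid_indices(self, e: Ellipsoid) -> tuple[np.ndarray, ...]:
        """Index arrays of voxels whose centres fall inside the ellipsoid."""
        lo, hi = [], []
        for ax in range(3):
            lo.append(max(0, int((e.center[ax] - e.semi_axes[ax] - self.origin[ax])
                                 / self.voxel) - 1))
            hi.append(min(self.shape[ax],
                          int((e.center[ax] + e.semi_axes[ax] - self.origin[ax])
                              / self.voxel) + 2))
        xs = self.origin[0] + (np.arange(lo[0], hi[0]) + 0.5) * self.voxel
        ys = self.origin[1] + (np.arange(lo[1], hi[1]) + 0.5) * self.voxel
        zs = self.origin[2] + (np.arange(lo[2], hi[2]) + 0.5) * self.voxel
        dx = ((xs - e.center[0]) / e.semi_axes[0]) ** 2
        dy = ((ys - e.center[1]) / e.semi_axes[1]) ** 2
        dz = ((zs - e.center[2]) / e.semi_axes[2]) ** 2
        mask = dx[:, None, None] + dy[None, :, None] + dz[None, None, :] <= 1.0
        ii, jj, kk = np.nonzero(mask)
        return ii + lo[0], jj + lo[1], kk + lo[2]

    def shapes_indices(self, shapes) -> tuple[np.ndarray, ...]:
        parts = [self.ellipsoid_indices(e) for e in shapes]
        flat = [np.ravel_multi_index(p, self.shape) for p in parts]
        uni = np.unique(np.concatenate(flat)) if flat else np.array([], dtype=int)
        return np.unravel_index(uni, self.shape)


def _calibrate(grid: _Grid, shapes: list[Ellipsoid], target_cc: float,
               name: str, labels: np.ndarray | None = None
               ) -> tuple[list[Ellipsoid], tuple[np.ndarray, ...]]:
    """Scale the shape set so the voxelized volume hits the target within 1%.

    When ``labels`` is given, only free soft-tissue voxels count (and are
    claimed): an organ placed against an already-labelled neighbour conforms
    to it instead of overlapping, the way segmented anatomy does.
    """
    vvol = grid.voxel ** 3

    def realized(s: float):
        idx = grid.shapes_indices([e.scaled(s) for e in shapes])
        if labels is not None:
            free = labels[idx] == BODY_LABEL
            idx = tuple(a[free] for a in idx)
        return idx[0].size * vvol, idx

    lo, hi = 0.7, 1.4
    best = (np.inf, None, None)
    for _ in range(48):
        s = 0.5 * (lo + hi)
        vol, idx = realized(s)
        err = abs(vol - target_cc) / target_cc
        if err < best[0]:
            best = (err, s, idx)
        if err <= _CAL_PREFERRED:
            break
        if vol < target_cc:
            lo = s
        else:
            hi = s
    err, s, idx = best
    if err > _CAL_REQUIRED:
        raise ValueError(
            f"voxel size {grid.voxel * 10:.1f} mm too coarse to realize organ "
            f"{name!r} ({target_cc} cc) within 1%; use a finer voxel")
    return [e.scaled(s) for e in shapes], idx


def _claim(labels: np.ndarray, idx, oid: int, name: str) -> None:
    occupied = labels[idx]
    if np.any(occupied == 0):
        raise ValueError(f"organ {name!r} extends outside the body envelope")
    if np.any((occupied != BODY_LABEL) & (occupied != oid)):
        clash = int(occupied[(occupied != BODY_LABEL) & (occupied != oid)][0])
        raise ValueError(f"organ {name!r} overlaps organ id {clash}")
    labels[idx] = oid


def build_reference_phantom(sex: str = "male", voxel_mm: float = 2.0) -> Phantom:
    """Build the stylized 5-year-old phantom.

    Parameters
    ----------
    sex : "male" or "female" (selects testes or ovaries).
    voxel_mm : isotropic voxel size, 1-10 mm.  Voxels coarser than ~2 mm
        cannot realize the gonads within 1% and raise ``ValueError``.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if not 1.0 <= voxel_mm <= 10.0:
        raise ValueError("voxel_mm must lie in [1, 10]")

    grid = _Grid(voxel_mm / 10.0)
    labels = np.zeros(grid.shape, dtype=np.uint16)

    # soft-tissue body envelope: elliptical cylinder
    xs, ys, zs = (grid.centers_1d(a) for a in range(3))
    body = ((xs[:, None] / _BODY_HALF_AXES[0]) ** 2
            + (ys[None, :] / _BODY_HALF_AXES[1]) ** 2) <= 1.0
    zmask = (zs >= _BODY_Z[0]) & (zs <= _BODY_Z[1])
    labels[np.ix_(np.arange(grid.shape[0]), np.arange(grid.shape[1]), np.nonzero(zmask)[0])] \
        = np.where(body, BODY_LABEL, 0)[:, :, None]

    organs: dict[int, OrganSpec] = {
        BODY_LABEL: OrganSpec("body", "none", float("nan"),
                              material_from_table("soft_tissue"), ()),
    }
    next_id = 2

    def add(name: str, side: str, mat: str, target: float,
            shapes: list[Ellipsoid], idx) -> None:
        nonlocal next_id
        _claim(labels, idx, next_id, name)
        organs[next_id] = OrganSpec(name, side, target,
                                    material_from_table(mat), tuple(shapes))
        next_id += 1

    def add_pair(base: str, mat: str, pair_volume: float, proto: Ellipsoid) -> None:
        """Calibrate left+right jointly, then label each side (+x is patient-left)."""
        shapes, _ = _calibrate(grid, [proto, _mirrored(proto)], pair_volume, base,
                               labels)
        for shape in shapes:
            side = "left" if shape.center[0] > 0 else "right"
            idx = grid.shapes_indices([shape])
            free = labels[idx] == BODY_LABEL
            idx = tuple(a[free] for a in idx)
            add(f"{base}_{'L' if side == 'left' else 'R'}", side, mat,
                pair_volume / 2.0, [shape], idx)

    def add_single(name: str, mat: str, target: float, shapes: list[Ellipsoid]) -> None:
        cal, idx = _calibrate(grid, shapes, target, name, labels)
        add(name, "none", mat, target, cal, idx)

    for step in _BUILD_ORDER:
        if step == "lung":
            add_pair("lung", "lung", _ANATOMY["lung"]["volume"],
                     _ANATOMY["lung"]["shapes"][0])
        elif step == "kidney":
            add_pair("kidney", "kidney", _ANATOMY["kidney"]["volume"],
                     _ANATOMY["kidney"]["shapes"][0])
        elif step == "bladder":
            _add_bladder(grid, labels, add)
        elif step == "gonads":
            base = "testis" if sex == "male" else "ovary"
            add_pair(base, base, _ANATOMY[base]["volume"],
                     _ANATOMY[base]["shapes"][0])
        else:
            spec = _ANATOMY[step]
            add_single(step, spec["material"], spec["volume"], list(spec["shapes"]))

    return Phantom(labels, grid.voxel, grid.origin, organs, sex)


def _add_bladder(grid: _Grid, labels: np.ndarray, add) -> None:
    """Urine sphere inside a wall shell, both volume-calibrated."""
    r_urine = (3.0 * _URINE_VOLUME_CC / (4.0 * np.pi)) ** (1.0 / 3.0)
    urine_proto = Ellipsoid(_BLADDER_CENTER, (r_urine, r_urine, r_urine))
    urine, uidx = _calibrate(grid, [urine_proto], _URINE_VOLUME_CC,
                             "bladder_content", labels)
    uset = set(np.ravel_multi_index(uidx, grid.shape).tolist())

    wall_target = _BLADDER_WALL_MASS_G / material_from_table("bladder_wall").density
    vvol = grid.voxel ** 3
    r_in = urine[0].semi_axes[0]

    def shell(r_out: float):
        oidx = grid.ellipsoid_indices(Ellipsoid(_BLADDER_CENTER, (r_out,) * 3))
        flat = np.ravel_multi_index(oidx, grid.shape)
        keep = ~np.isin(flat, list(uset)) & (labels[oidx] == BODY_LABEL)
        return tuple(a[keep] for a in oidx)

    lo, hi = r_in, r_in + 1.5
    best = (np.inf, None, None)
    for _ in range(48):
        r = 0.5 * (lo + hi)
        sidx = shell(r)
        vol = sidx[0].size * vvol
        err = abs(vol - wall_target) / wall_target
        if err < best[0]:
            best = (err, r, sidx)
        if err <= _CAL_PREFERRED:
            break
        if vol < wall_target:
            lo = r
        else:
            hi = r
    err, r, sidx = best
    if err > _CAL_REQUIRED:
        raise ValueError(
            f"voxel size {grid.voxel * 10:.1f} mm too coarse to realize the "
            f"bladder wall within 1%; use a finer voxel")
    add("bladder_wall", "none", "bladder_wall", wall_target,
        [Ellipsoid(_BLADDER_CENTER, (r,) * 3)], sidx)
    add("bladder_content", "none", "urine", _URINE_VOLUME_CC, urine, uidx)


# ---------------------------------------------------------------------------
# mass, mirroring, serialization
# ---------------------------------------------------------------------------

def organ_mass(phantom: Phantom, organ) -> float:
    """Realized organ mass in grams (voxel count x voxel volume x density).

    ``organ`` may be a label id, an organ name (``kidney_L``) or a paired base
    name (``testis`` sums both sides).  Unknown or empty organs raise.
    """
    if isinstance(organ, (int, np.integer)):
        ids = [int(organ)]
        if ids[0] not in phantom.organs:
            raise KeyError(f"unknown organ id {organ}")
    else:
        ids = [oid for oid, s in phantom.organs.items()
               if s.name == organ or s.name in (f"{organ}_L", f"{organ}_R")]
        if not ids:
            raise KeyError(f"unknown organ {organ!r}")
    total = 0.0
    for oid in ids:
        n = phantom.voxel_count(oid)
        if n == 0:
            raise ValueError(f"organ id {oid} has no voxels")
        total += n * phantom.voxel_volume_cc * phantom.organs[oid].material.density
    return total


def mirror(phantom: Phantom) -> Phantom:
    """Mirror about the midsagittal plane, swapping left/right organ labels."""
    flipped = phantom.labels[::-1, :, :].copy()
    swaps = {}
    for oid, spec in phantom.organs.items():
        if spec.name.endswith("_L"):
            partner = phantom.id_of(spec.name[:-2] + "_R")
            swaps[oid], swaps[partner] = partner, oid
    out = flipped.copy()
    for a, b in swaps.items():
        out[flipped == a] = b
    organs = {}
    for oid, spec in phantom.organs.items():
        src = phantom.organs[swaps.get(oid, oid)]
        organs[oid] = replace(
            src,
            name=spec.name,
            side=spec.side,
            shapes=tuple(_mirrored(e) for e in src.shapes),
        )
    return Phantom(out, phantom.voxel_cm, phantom.origin_cm, organs, phantom.sex)


def write_phantom(phantom: Phantom, basepath: str) -> None:
    """Write ``<basepath>.lbl`` (raw LE uint16, x-fastest) + ``<basepath>.hdr.json``."""
    labels = np.ascontiguousarray(phantom.labels.astype("<u2"))
    with open(f"{basepath}.lbl", "wb") as fh:
        fh.write(labels.ravel(order="F").tobytes())
    header = {
        "shape": list(phantom.labels.shape),
        "voxel_cm": phantom.voxel_cm,
        "origin_cm": list(phantom.origin_cm),
        "sex": phantom.sex,
        "organs": {
            str(oid): {
                "name": s.name, "side": s.side,
                "target_volume_cc": s.target_volume_cc,
                "material": {"name": s.material.name,
                             "density": s.material.density,
                             "mass_fractions": s.material.mass_fractions},
                "shapes": [{"center": list(e.center), "semi_axes": list(e.semi_axes)}
                           for e in s.shapes],
            } for oid, s in phantom.organs.items()
        },
    }
    with open(f"{basepath}.hdr.json", "w") as fh:
        json.dump(header, fh, indent=1)


def read_phantom(basepath: str) -> Phantom:
    """Round-trip counterpart of :func:`write_phantom`; validates consistency."""
    with open(f"{basepath}.hdr.json") as fh:
        header = json.load(fh)
    shape = tuple(header["shape"])
    n_expect = shape[0] * shape[1] * shape[2] * 2
    with open(f"{basepath}.lbl", "rb") as fh:
        raw = fh.read()
    if len(raw) != n_expect:
        raise ValueError(
            f"label file size {len(raw)} does not match header "
            f"({n_expect} bytes expected)")
    labels = np.frombuffer(raw, dtype="<u2").reshape(shape, order="F").copy()
    organs = {}
    for oid_s, rec in header["organs"].items():
        mat = Material(rec["material"]["name"],
                       dict(rec["material"]["mass_fractions"]),
                       rec["material"]["density"])
        shapes = tuple(Ellipsoid(tuple(sh["center"]), tuple(sh["semi_axes"]))
                       for sh in rec["shapes"])
        organs[int(oid_s)] = OrganSpec(rec["name"], rec["side"],
                                       rec["target_volume_cc"], mat, shapes)
    present = set(np.unique(labels).tolist()) - {0}
    if not present <= set(organs):
        raise ValueError("label grid contains organ ids absent from the header")
    return Phantom(labels, header["voxel_cm"], tuple(header["origin_cm"]),
                   organs, header["sex"])
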