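"""Synthetic voxelized head-and-neck phantoms.

This module stands in for the clinical front end of an adaptive proton
therapy workflow: a contoured planning CT.  It generates voxel grids with
binary structure masks for up to three clinical target volumes (CTV1-3,
with descending prescription doses) and twelve organs at risk (OARs),
and simulates inter-fractional anatomical change by morphologically
expanding (tumor progression) or shrinking (regression) the CTV contours
by a physical margin.

The default phantom is a single axial slice -- a (64, 64, 1) grid at 2 mm
isotropic spacing -- with the CTV complex placed centrally and the twelve
OARs arranged on a surrounding ring, disjoint from the targets.  The
layout is schematic, not anatomical: what matters downstream is that the
geometry produces the competing coverage/sparing trade-offs that priority
tuning has to negotiate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "CTV_ROLES",
    "OAR_NAMES",
    "PhantomConfigError",
    "AugmentationError",
    "StructureSpec",
    "PhantomConfig",
    "PhantomGeometry",
    "generate_phantom",
    "augment_anatomy",
    "replan_variant",
    "save_geometry",
    "load_geometry",
]

CTV_ROLES = ("CTV1", "CTV2", "CTV3")

#: Twelve typical head-and-neck organs at risk: brainstem, spinal cord,
#: mandible, larynx, pharynx, left/right parotid, left/right cochlea,
#: left/right submandibular gland, esophagus.
OAR_NAMES = (
    "BRS", "SC", "MAN", "LAR", "PHY",
    "PARL", "PARR", "COCHL", "COCHR",
    "SMGL", "SMGR", "ESO",
)


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration cannot produce a valid geometry."""


class AugmentationError(ValueError):
    """Raised when an anatomical augmentation destroys a structure."""


@dataclass(frozen=True)
class StructureSpec:
    """Placement recipe for one structure.

    Parameters
    ----------
    name, role
        Structure name and its role, one of ``CTV1``/``CTV2``/``CTV3``/``OAR``.
    center
        Fractional grid coordinates in [0, 1] per axis, or the string
        ``"random"`` for seeded random placement.
    radii_mm
        Ellipsoid semi-axes in millimetres (a scalar means a ball).
    prescription
        Prescribed dose in GyRBE; required for CTV roles, ignored for OARs.
    """

    name: str
    role: str
    center: tuple[float, ...] | str
    radii_mm: tuple[float, ...] | float
    prescription: float | None = None

    def radii(self, ndim: int) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.radii_mm, dtype=float))
        if r.size == 1:
            r = np.full(ndim, r[0])
        if r.size != ndim:
            raise PhantomConfigError(
                f"structure {self.name!r}: {r.size} radii for {ndim} axes"
            )
        return r


def _default_structures() -> tuple[StructureSpec, ...]:
    """Three disjoint targets with OARs packed around them.

    The CTVs are treated as independent target volumes (primary tumor and
    two nodal volumes) rather than nested contours, so each can carry its
    own uniform prescription without conflicting objectives on shared
    voxels.  Several OARs (parotids, submandibular glands, larynx,
    pharynx, spinal cord) sit directly adjacent to the targets or in the
    beam paths, so sparing them genuinely competes with coverage; the
    remaining OARs (cochleas, mandible, brainstem, esophagus) are
    peripheral and largely spared by geometry.
    """
    ctvs = [
        StructureSpec("CTV1", "CTV1", (0.42, 0.42, 0.5), 7.0, prescription=70.0),
        StructureSpec("CTV2", "CTV2", (0.58, 0.42, 0.5), 9.0, prescription=59.85),
        StructureSpec("CTV3", "CTV3", (0.50, 0.60, 0.5), 10.0, prescription=53.90),
    ]
    oars = [
        StructureSpec("PARL", "OAR", (0.30, 0.42, 0.5), 5.0),
        StructureSpec("PARR", "OAR", (0.70, 0.42, 0.5), 5.0),
        StructureSpec("SMGL", "OAR", (0.36, 0.58, 0.5), 5.0),
        StructureSpec("SMGR", "OAR", (0.64, 0.58, 0.5), 5.0),
        StructureSpec("LAR", "OAR", (0.50, 0.30, 0.5), 5.0),
        StructureSpec("PHY", "OAR", (0.50, 0.73, 0.5), 5.0),
        StructureSpec("SC", "OAR", (0.50, 0.82, 0.5), 4.0),
        StructureSpec("BRS", "OAR", (0.50, 0.90, 0.5), 4.0),
        StructureSpec("MAN", "OAR", (0.50, 0.14, 0.5), 6.0),
        StructureSpec("ESO", "OAR", (0.30, 0.74, 0.5), 5.0),
        StructureSpec("COCHL", "OAR", (0.18, 0.22, 0.5), 4.0),
        StructureSpec("COCHR", "OAR", (0.82, 0.22, 0.5), 4.0),
    ]
    return tuple(ctvs + oars)


@dataclass(frozen=True)
class PhantomConfig:
    """Grid geometry plus the roster of structures to synthesize."""

    grid_shape: tuple[int, ...] = (64, 64, 1)
    spacing: tuple[float, ...] = (2.0, 2.0, 2.0)
    structures: tuple[StructureSpec, ...] = field(default_factory=_default_structures)
    jitter_mm: float = 0.0  # seeded random jitter applied to every center

    @classmethod
    def default(cls) -> "PhantomConfig":
        """The standard desk-scale phantom: 3 CTVs + 12 OARs on a 64x64 slice."""
        return cls()

    @classmethod
    def small(cls) -> "PhantomConfig":
        """A 48x48 variant of the default layout for fast experiments.

        Structure radii scale with the grid so fractional placements keep
        the targets disjoint.
        """
        scale = 48 / 64
        structures = tuple(
            replace(
                s,
                radii_mm=(
                    tuple(scale * r for r in s.radii_mm)
                    if isinstance(s.radii_mm, tuple)
                    else scale * s.radii_mm
                ),
            )
            for s in _default_structures()
        )
        return cls(grid_shape=(48, 48, 1), structures=structures)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        structures = tuple(
            StructureSpec(
                name=s["name"],
                role=s["role"],
                center=tuple(s["center"]) if s["center"] != "random" else "random",
                radii_mm=(
                    tuple(s["radii_mm"])
                    if isinstance(s["radii_mm"], (list, tuple))
                    else float(s["radii_mm"])
                ),
                prescription=s.get("prescription"),
            )
            for s in d["structures"]
        )
        return cls(
            grid_shape=tuple(d.get("grid_shape", (64, 64, 1))),
            spacing=tuple(d.get("spacing", (2.0, 2.0, 2.0))),
            structures=structures,
            jitter_mm=float(d.get("jitter_mm", 0.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PhantomGeometry:
    """A voxelized anatomy: grid, spacing, and per-structure binary masks.

    ``structure_roles`` maps each structure name to one of
    ``CTV1``/``CTV2``/``CTV3``/``OAR``; ``prescriptions`` holds the
    prescribed dose in GyRBE for every CTV-role structure.
    """

    grid_shape: tuple[int, ...]
    spacing: tuple[float, ...]
    masks: dict[str, np.ndarray]
    structure_roles: dict[str, str]
    prescriptions: dict[str, float]

    def __post_init__(self):
        if len(self.spacing) != len(self.grid_shape):
            raise PhantomConfigError("spacing and grid_shape rank mismatch")
        if any(s <= 0 for s in self.spacing):
            raise PhantomConfigError("spacing must be strictly positive")
        for name, mask in self.masks.items():
            if mask.shape != tuple(self.grid_shape):
                raise PhantomConfigError(f"mask {name!r} shape != grid_shape")
        ctvs = self.ctv_names
        if not ctvs or not self.masks[ctvs[0]].any():
            raise PhantomConfigError("CTV1 mask must be non-empty")
        for name in ctvs:
            if name not in self.prescriptions:
                raise PhantomConfigError(f"missing prescription for {name!r}")
        rx = [self.prescriptions[n] for n in ctvs]
        if any(a < b for a, b in zip(rx, rx[1:])):
            raise PhantomConfigError(
                "prescriptions must be non-increasing CTV1 >= CTV2 >= CTV3"
            )

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in cc (product of spacings in mm^3, divided by 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def ctv_names(self) -> tuple[str, ...]:
        """CTV-role structures ordered CTV1, CTV2, CTV3."""
        present = {r: n for n, r in self.structure_roles.items() if r in CTV_ROLES}
        return tuple(present[r] for r in CTV_ROLES if r in present)

    @property
    def oar_names(self) -> tuple[str, ...]:
        return tuple(
            n for n in self.masks if self.structure_roles[n] == "OAR"
        )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def structure_indices(self, name: str) -> np.ndarray:
        """Flat voxel indices of a structure (row indices into D)."""
        return np.flatnonzero(self.masks[name].ravel())

    def voxel_centers_mm(self) -> np.ndarray:
        """(n_voxels, ndim) physical coordinates of voxel centers."""
        axes = [
            (np.arange(n) + 0.5) * s for n, s in zip(self.grid_shape, self.spacing)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)


def generate_phantom(config: PhantomConfig, seed: int = 0) -> PhantomGeometry:
    """Build a deterministic phantom from a configuration and a seed.

    The seed drives random placement (``center="random"``) and the optional
    center jitter; with fixed placements and zero jitter the result is
    independent of the seed.  Repeated calls with the same ``(config, seed)``
    are bitwise identical.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(config.grid_shape)
    spacing = np.asarray(config.spacing, dtype=float)
    extent = np.array(shape) * spacing
    ndim = len(shape)

    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(*axes, indexing="ij")

    masks: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    prescriptions: dict[str, float] = {}
    for spec in config.structures:
        radii = spec.radii(ndim)
        nondegenerate = np.array(shape) > 1
        if np.any((2 * radii > extent) & nondegenerate):
            raise PhantomConfigError(
                f"structure {spec.name!r}: radius exceeds grid extent"
            )
        if isinstance(spec.center, str):  # "random"
            frac = rng.uniform(0.25, 0.75, size=ndim)
        else:
            frac = np.asarray(spec.center, dtype=float)
        if config.jitter_mm > 0:
            frac = frac + rng.uniform(-config.jitter_mm, config.jitter_mm, ndim) / extent
        center = frac * extent
        # collapse degenerate axes (single-slice grids) onto the voxel center
        center = np.where(np.array(shape) == 1, extent / 2.0, center)
        q = np.zeros(shape)
        for ax in range(ndim):
            q = q + ((grids[ax] - center[ax]) / radii[ax]) ** 2
        mask = q <= 1.0
        if not mask.any():
            raise PhantomConfigError(
                f"structure {spec.name!r}: empty mask (grid too small?)"
            )
        masks[spec.name] = mask
        roles[spec.name] = spec.role
        if spec.role in CTV_ROLES:
            if spec.prescription is None:
                raise PhantomConfigError(
                    f"CTV structure {spec.name!r} has no prescription"
                )
            prescriptions[spec.name] = float(spec.prescription)

    return PhantomGeometry(
        grid_shape=shape,
        spacing=tuple(float(s) for s in spacing),
        masks=masks,
        structure_roles=roles,
        prescriptions=prescriptions,
    )


def _ball_element(radii_vox: np.ndarray) -> np.ndarray:
    """Discrete ellipsoid structuring element with per-axis voxel radii."""
    r = np.maximum(radii_vox.astype(int), 0)
    ranges = [np.arange(-k, k + 1) for k in r]
    grids = np.meshgrid(*ranges, indexing="ij")
    q = np.zeros(grids[0].shape)
    for g, k in zip(grids, r):
        q = q + (g / max(k, 1)) ** 2
    return q <= 1.0


def _margin_radii(geom: PhantomGeometry, margin_mm: np.ndarray) -> np.ndarray:
    radii = np.round(np.asarray(margin_mm, float) / np.asarray(geom.spacing))
    # axes of extent 1 (single-slice grids) cannot support morphology
    radii[np.array(geom.grid_shape) == 1] = 0
    return radii.astype(int)


def augment_anatomy(
    geom: PhantomGeometry, mode: str, margin: float | None = None
) -> PhantomGeometry:
    """Simulate tumor progression or regression on every CTV contour.

    ``progression`` dilates each CTV mask by the physical margin (default
    2 mm); ``regression`` erodes it (default 3 mm).  OAR masks are left
    untouched and the input geometry is never modified.  The structuring
    element is a discrete ball with per-axis radius ``round(margin/spacing)``.
    """
    defaults = {"progression": 2.0, "regression": 3.0}
    if mode not in defaults:
        raise ValueError(f"mode must be 'progression' or 'regression', got {mode!r}")
    margin = defaults[mode] if margin is None else float(margin)
    if margin <= 0:
        raise ValueError("margin must be > 0 mm")

    radii = _margin_radii(geom, np.full(len(geom.grid_shape), margin))
    selem = _ball_element(radii)
    op = ndimage.binary_dilation if mode == "progression" else ndimage.binary_erosion

    masks = {}
    for name, mask in geom.masks.items():
        if geom.structure_roles[name] in CTV_ROLES:
            new = op(mask, structure=selem)
            if mode == "regression" and not new.any():
                raise AugmentationError(
                    f"regression by {margin} mm erodes {name!r} to empty"
                )
            masks[name] = new
        else:
            masks[name] = mask.copy()
    return replace(geom, masks=masks)


def replan_variant(
    geom: PhantomGeometry,
    ctv_margins_mm: tuple[float, ...] = (3.0, 1.0, 0.0),
    oar_shift: tuple[str, tuple[int, ...]] = ("PARL", (0, 2, 0)),
) -> PhantomGeometry:
    """A held-out anatomy emulating a replanning CT.

    The change is deliberately distinct from the isotropic training
    augmentations: CTVs are dilated *anisotropically* (per-axis millimetre
    margins) and one OAR is rigidly shifted by whole voxels, mimicking an
    organ displaced by the deformation.
    """
    radii = _margin_radii(geom, np.asarray(ctv_margins_mm, float))
    selem = _ball_element(radii)
    masks = {}
    for name, mask in geom.masks.items():
        if geom.structure_roles[name] in CTV_ROLES:
            masks[name] = ndimage.binary_dilation(mask, structure=selem)
        else:
            masks[name] = mask.copy()
    oar_name, shift = oar_shift
    if oar_name in masks:
        shifted = ndimage.shift(
            masks[oar_name].astype(np.uint8), shift, order=0, cval=0
        ).astype(bool)
        if not shifted.any():
            warnings.warn(f"OAR shift pushed {oar_name!r} off the grid; kept original")
        else:
            masks[oar_name] = shifted
    return replace(geom, masks=masks)


# ---------------------------------------------------------------------------
# persistence: masks to HDF5 with a JSON manifest
# ---------------------------------------------------------------------------

def save_geometry(geom: PhantomGeometry, h5_path, manifest_path=None) -> None:
    with h5py.File(h5_path, "w") as fh:
        fh.attrs["grid_shape"] = geom.grid_shape
        fh.attrs["spacing"] = geom.spacing
        grp = fh.create_group("masks")
        for name, mask in geom.masks.items():
            grp.create_dataset(name, data=mask.astype(np.uint8), compression="gzip")
    manifest = {
        "grid_shape": list(geom.grid_shape),
        "spacing": list(geom.spacing),
        "structures": [
            {
                "name": n,
                "role": geom.structure_roles[n],
                "voxels": int(geom.masks[n].sum()),
                "prescription": geom.prescriptions.get(n),
            }
            for n in geom.masks
        ],
    }
    if manifest_path is None:
        manifest_path = str(h5_path) + ".json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_geometry(h5_path, manifest_path=None) -> PhantomGeometry:
    if manifest_path is None:
        manifest_path = str(h5_path) + ".json"
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    roles = {s["name"]: s["role"] for s in manifest["structures"]}
    prescriptions = {
        s["name"]: s["prescription"]
        for s in manifest["structures"]
        if s["prescription"] is not None
    }
    with h5py.File(h5_path, "r") as fh:
        masks = {n: fh["masks"][n][...].astype(bool) for n in fh["masks"]}
        grid_shape = tuple(int(v) for v in fh.attrs["grid_shape"])
        spacing = tuple(float(v) for v in fh.attrs["spacing"])
    return PhantomGeometry(
        grid_shape=grid_shape,
        spacing=spacing,
        masks=masks,
        structure_roles=roles,
        prescriptions=prescriptions,
    )
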