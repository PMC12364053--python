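"""Pencil-beam dose-influence matrices for synthetic phantoms.

In a treatment planning system the dose d_i in voxel i is linear in the
beamlet intensities x_j:  d_i = sum_j D_ij x_j, with the dose-influence
matrix D precalculated once per anatomy.  Here D is built from a
simplified proton pencil-beam model: each beamlet deposits a Bragg-like
depth-dose profile along its ray (low entrance plateau, peak at the
configured range, sharp distal falloff) modulated by a lateral Gaussian.
Any smooth nonnegative linear dose operator supports the priority-tuning
method downstream; the Bragg-shaped profile keeps the proton-therapy
motivation visible and gives the optimizer the characteristic
depth-selectivity of IMPT.

Beamlets are indexed beam-major: column ``b * beamlets_per_beam + k`` is
the k-th lateral spot of beam b.  Columns that miss the grid entirely are
kept as all-zero columns (with a warning) so beamlet indexing stays
stable across augmented anatomies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.io import mmread, mmwrite

from .phantom import PhantomGeometry

__all__ = [
    "BeamConfig",
    "DoseInfluence",
    "bragg_depth_dose",
    "compute_dose_influence",
    "save_dose_influence",
    "load_dose_influence",
]


@dataclass(frozen=True)
class BeamConfig:
    """Beam arrangement and pencil-beam model parameters.

    ``range_mm=None`` places each beam's Bragg peak at the isocenter depth
    along its central axis, which is the natural choice for a target-centred
    arrangement.  ``isocenter="ctv"`` aims at the centroid of all CTV
    voxels; ``"ctv1"`` at the CTV1 centroid alone.
    """

    gantry_angles: tuple[float, ...] = (0.0, 120.0, 240.0)
    beamlets_per_beam: int = 15
    beamlet_spacing_mm: float = 5.0
    lateral_sigma: float = 12.0
    depth_dose_profile: str = "bragg"
    range_mm: float | None = None
    entrance_fraction: float = 0.35
    proximal_width_mm: float = 14.0
    distal_width_mm: float = 3.0
    dose_cutoff: float = 1e-3
    isocenter: str | tuple[float, ...] = "ctv"

    def __post_init__(self):
        if len(self.gantry_angles) < 1:
            raise ValueError("need at least one gantry angle")
        if self.beamlets_per_beam < 1:
            raise ValueError("beamlets_per_beam must be >= 1")
        if self.lateral_sigma <= 0:
            raise ValueError("lateral_sigma must be > 0")
        if not 0 <= self.dose_cutoff < 1:
            raise ValueError("dose_cutoff must be in [0, 1)")
        if self.depth_dose_profile != "bragg":
            raise ValueError(f"unknown depth-dose profile {self.depth_dose_profile!r}")

    @classmethod
    def small(cls) -> "BeamConfig":
        return cls(beamlets_per_beam=11)

    @classmethod
    def from_dict(cls, d: dict) -> "BeamConfig":
        d = dict(d)
        if "gantry_angles" in d:
            d["gantry_angles"] = tuple(d["gantry_angles"])
        if isinstance(d.get("isocenter"), (list, tuple)):
            d["isocenter"] = tuple(d["isocenter"])
        return cls(**d)

    @property
    def n_beamlets(self) -> int:
        return len(self.gantry_angles) * self.beamlets_per_beam


def bragg_depth_dose(
    depth_mm: np.ndarray,
    range_mm: float,
    entrance_fraction: float = 0.35,
    proximal_width_mm: float = 14.0,
    distal_width_mm: float = 3.0,
) -> np.ndarray:
    """Parametric Bragg-like depth-dose curve, peak normalized to 1.

    Proximal of the range: an entrance plateau plus a broad Gaussian rising
    to the peak.  Distal: a narrow Gaussian drop, emulating the sharp
    falloff beyond the Bragg peak.  Negative depths (upstream of the grid
    entry) receive zero.
    """
    depth = np.asarray(depth_mm, dtype=float)
    prox = entrance_fraction + (1.0 - entrance_fraction) * np.exp(
        -0.5 * ((depth - range_mm) / proximal_width_mm) ** 2
    )
    dist = np.exp(-0.5 * ((depth - range_mm) / distal_width_mm) ** 2)
    out = np.where(depth <= range_mm, prox, dist)
    return np.where(depth < 0, 0.0, out)


@dataclass
class DoseInfluence:
    """Sparse nonnegative matrix mapping beamlet intensities to voxel doses.

    Rows are voxels of the flattened grid, columns are beamlets.
    ``structure_rows`` gives, per structure, the row indices belonging to
    that structure's mask; :meth:`view` returns the corresponding row
    submatrix (cached).
    """

    matrix: sparse.csr_matrix
    structure_rows: dict[str, np.ndarray]
    grid_shape: tuple[int, ...]
    _views: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("dose-influence entries must be nonnegative")

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    def view(self, name: str) -> sparse.csr_matrix:
        if name not in self._views:
            self._views[name] = self.matrix[self.structure_rows[name]].tocsr()
        return self._views[name]


def _entry_parameter(origin: np.ndarray, direction: np.ndarray, extent: np.ndarray):
    """Ray-box entry parameter (slab method); NaN if the ray misses the box."""
    t_lo, t_hi = -np.inf, np.inf
    for ax in range(len(extent)):
        o, u = origin[ax], direction[ax]
        if abs(u) < 1e-12:
            if not (0.0 <= o <= extent[ax]):
                return np.nan
            continue
        t1, t2 = (0.0 - o) / u, (extent[ax] - o) / u
        t_lo = max(t_lo, min(t1, t2))
        t_hi = min(t_hi, max(t1, t2))
    return t_lo if t_lo <= t_hi else np.nan


def compute_dose_influence(
    geom: PhantomGeometry, beams: BeamConfig | None = None
) -> DoseInfluence:
    """Build the sparse dose-influence matrix for a phantom.

    Deterministic in (geometry, beam config).  Per-beamlet columns are the
    depth-dose along the ray times a lateral Gaussian; entries below
    ``dose_cutoff`` x column-max are zeroed before sparse storage.
    """
    beams = beams or BeamConfig()
    coords = geom.voxel_centers_mm()
    extent = np.array(geom.grid_shape) * np.array(geom.spacing)
    ndim = len(geom.grid_shape)

    if beams.isocenter == "ctv":
        idx = np.concatenate([geom.structure_indices(n) for n in geom.ctv_names])
        iso = coords[idx].mean(axis=0)
    elif beams.isocenter == "ctv1":
        iso = coords[geom.structure_indices(geom.ctv_names[0])].mean(axis=0)
    else:
        iso = np.asarray(beams.isocenter, dtype=float) * extent

    offsets = (
        np.arange(beams.beamlets_per_beam) - (beams.beamlets_per_beam - 1) / 2.0
    ) * beams.beamlet_spacing_mm

    columns = []
    for angle in beams.gantry_angles:
        th = np.deg2rad(angle)
        u = np.zeros(ndim)
        v = np.zeros(ndim)
        u[0], u[1] = np.cos(th), np.sin(th)
        v[0], v[1] = -np.sin(th), np.cos(th)

        t0_central = _entry_parameter(iso, u, extent)
        if np.isnan(t0_central):
            beam_range = beams.range_mm if beams.range_mm is not None else 0.0
        else:
            beam_range = (
                beams.range_mm if beams.range_mm is not None else -t0_central
            )

        for off in offsets:
            c = iso + off * v
            t0 = _entry_parameter(c, u, extent)
            if np.isnan(t0):
                warnings.warn(
                    f"beamlet (angle={angle}, offset={off} mm) misses the grid; "
                    "keeping zero column"
                )
                columns.append(sparse.csr_matrix((coords.shape[0], 1)))
                continue
            rel = coords - c
            along = rel @ u
            depth = along - t0
            lat2 = np.einsum("ij,ij->i", rel, rel) - along**2
            col = bragg_depth_dose(
                depth,
                beam_range,
                beams.entrance_fraction,
                beams.proximal_width_mm,
                beams.distal_width_mm,
            ) * np.exp(-0.5 * np.maximum(lat2, 0.0) / beams.lateral_sigma**2)
            peak = col.max()
            if peak > 0:
                col[col < beams.dose_cutoff * peak] = 0.0
            columns.append(sparse.csr_matrix(col[:, None]))

    matrix = sparse.hstack(columns, format="csr")
    rows = {name: geom.structure_indices(name) for name in geom.masks}
    return DoseInfluence(matrix=matrix, structure_rows=rows, grid_shape=geom.grid_shape)


def save_dose_influence(dinf: DoseInfluence, mtx_path, sidecar_path=None) -> None:
    """Persist as Matrix Market plus a JSON sidecar with the row index map."""
    mmwrite(str(mtx_path), dinf.matrix)
    sidecar = {
        "grid_shape": list(dinf.grid_shape),
        "n_beamlets": int(dinf.n_beamlets),
        "structure_rows": {k: v.tolist() for k, v in dinf.structure_rows.items()},
    }
    if sidecar_path is None:
        sidecar_path = str(mtx_path) + ".json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh)


def load_dose_influence(mtx_path, sidecar_path=None) -> DoseInfluence:
    if sidecar_path is None:
        sidecar_path = str(mtx_path) + ".json"
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    matrix = sparse.csr_matrix(mmread(str(mtx_path)))
    return DoseInfluence(
        matrix=matrix,
        structure_rows={
            k: np.asarray(v, dtype=int) for k, v in sidecar["structure_rows"].items()
        },
        grid_shape=tuple(sidecar["grid_shape"]),
    )
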