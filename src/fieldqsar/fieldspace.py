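"""Molecular interaction fields, field points, and descriptor matrices.

Four field channels are evaluated around each aligned molecule:

* ``electro_pos`` / ``electro_neg`` — the positive and negative parts of the
  Coulomb electrostatic potential per unit probe charge,
  V(p) = sum_i k q_i / (eps(r_i) r_i) with k = 332.063 kcal*A/(mol*e^2) and a
  distance-dependent dielectric eps(r) = r by default (so each term decays
  as 1/r^2); a constant-dielectric mode is available.
* ``steric`` — a soft van der Waals shape overlap,
  S(p) = sum_i A exp(-r_i^2 / sigma_i^2), sigma_i the vdW radius, A = 10
  kcal/mol.
* ``hydrophobic`` — per-atom Crippen lipophilicity contributions weighted by
  exp(-r_i^2 / 4 A^2), a dimensionless local lipophilicity score.

Field *points* are strict local extrema of these channels on a 1 A grid
restricted to the 1.5-4.5 A shell around the molecule. The union of the
training molecules' field points, snapped to a 1 A lattice anchored at the
template-frame origin, forms the gauge-invariant sample-point set whose
(point x channel) pairs are the descriptor columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import json
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from scipy import ndimage

from .chemio import Molecule3D

__all__ = [
    "CHANNELS",
    "FieldConfig",
    "FieldPoint",
    "SamplePointSet",
    "DescriptorMatrix",
    "esp_at_point",
    "steric_at_point",
    "hydrophobic_at_point",
    "compute_field_points",
    "build_sample_points",
    "descriptor_matrix",
]

COULOMB_K = 332.063  # kcal*A/(mol*e^2)
ESP_CAP = 100.0      # kcal/mol clamp near nuclei
CHANNELS = ("electro_pos", "electro_neg", "steric", "hydrophobic")

_PT = Chem.GetPeriodicTable()


@dataclass(frozen=True)
class FieldConfig:
    """Field evaluation and field-point extraction parameters."""

    dielectric: str = "distance"        # "distance" (eps = r) or "constant"
    constant_eps: float = 1.0
    steric_amplitude: float = 10.0      # kcal/mol
    hydrophobic_sigma2: float = 4.0     # A^2
    shell_inner: float = 1.5            # A
    shell_outer: float = 4.5            # A
    grid_spacing: float = 1.0           # A
    threshold_electro: float = 1.0      # kcal/mol
    threshold_steric: float = 0.5       # kcal/mol
    threshold_hydrophobic: float = 0.1  # dimensionless

    def threshold(self, channel: str) -> float:
        if channel.startswith("electro"):
            return self.threshold_electro
        if channel == "steric":
            return self.threshold_steric
        return self.threshold_hydrophobic


@dataclass(frozen=True)
class FieldPoint:
    """A local field extremum: position (template frame, A), channel, value."""

    position: tuple[float, float, float]
    channel: str
    magnitude: float


def _atom_arrays(mol3d: Molecule3D) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords = mol3d.coords
    charges = mol3d.partial_charges
    radii = np.array(
        [_PT.GetRvdw(a.GetAtomicNum()) for a in mol3d.mol.GetAtoms()], dtype=float
    )
    return coords, charges, radii


def _crippen_contribs(mol: Chem.Mol) -> np.ndarray:
    return np.array([c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)],
                    dtype=float)


def _esp_values(points: np.ndarray, coords: np.ndarray, charges: np.ndarray,
                cfg: FieldConfig) -> np.ndarray:
    """Vectorized Coulomb sum at (m,3) points; clamped to +-ESP_CAP."""
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    d = np.maximum(d, 1e-6)
    if cfg.dielectric == "distance":
        denom = d * d
    else:
        denom = cfg.constant_eps * d
    v = (COULOMB_K * charges[None, :] / denom).sum(axis=1)
    return np.clip(v, -ESP_CAP, ESP_CAP)


def _steric_values(points: np.ndarray, coords: np.ndarray, radii: np.ndarray,
                   cfg: FieldConfig) -> np.ndarray:
    d2 = ((points[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return (cfg.steric_amplitude * np.exp(-d2 / (radii[None, :] ** 2))).sum(axis=1)


def _hydrophobic_values(points: np.ndarray, coords: np.ndarray,
                        logp: np.ndarray, cfg: FieldConfig) -> np.ndarray:
    d2 = ((points[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return (logp[None, :] * np.exp(-d2 / cfg.hydrophobic_sigma2)).sum(axis=1)


def esp_at_point(mol3d: Molecule3D, point: Sequence[float],
                 cfg: FieldConfig | None = None) -> float:
    """Electrostatic potential (kcal/mol per unit probe charge) at one point."""
    cfg = cfg or FieldConfig()
    coords, charges, _ = _atom_arrays(mol3d)
    return float(_esp_values(np.asarray([point], float), coords, charges, cfg)[0])


def steric_at_point(mol3d: Molecule3D, point: Sequence[float],
                    cfg: FieldConfig | None = None) -> float:
    """Soft vdW-overlap steric field (kcal/mol) at one point."""
    cfg = cfg or FieldConfig()
    coords, _, radii = _atom_arrays(mol3d)
    return float(_steric_values(np.asarray([point], float), coords, radii, cfg)[0])


def hydrophobic_at_point(mol3d: Molecule3D, point: Sequence[float],
                         cfg: FieldConfig | None = None) -> float:
    """Gaussian-weighted lipophilicity score at one point (dimensionless)."""
    cfg = cfg or FieldConfig()
    coords, _, _ = _atom_arrays(mol3d)
    logp = _crippen_contribs(mol3d.mol)
    return float(_hydrophobic_values(np.asarray([point], float), coords, logp, cfg)[0])


def field_values(mol3d: Molecule3D, points: np.ndarray,
                 cfg: FieldConfig | None = None) -> np.ndarray:
    """All four channels at (m,3) points -> (m, 4) array in CHANNELS order.

    The signed electrostatic potential is split into its positive part
    (electro_pos) and the magnitude of its negative part (electro_neg) so
    every channel is a non-negative intensity except hydrophobic, which
    keeps its sign.
    """
    cfg = cfg or FieldConfig()
    points = np.asarray(points, float)
    coords, charges, radii = _atom_arrays(mol3d)
    logp = _crippen_contribs(mol3d.mol)
    esp = _esp_values(points, coords, charges, cfg)
    out = np.empty((len(points), 4))
    out[:, 0] = np.maximum(esp, 0.0)
    out[:, 1] = np.maximum(-esp, 0.0)
    out[:, 2] = _steric_values(points, coords, radii, cfg)
    out[:, 3] = _hydrophobic_values(points, coords, logp, cfg)
    return out


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-covariant molecular frame: centroid origin, principal axes.

    Returns (E, c) with axes as columns of E (det +1) and centroid c, so
    local coordinates are (x - c) @ E. Axis signs are fixed by the third
    moment of the projections (falling back to the largest-|projection|
    sign when the distribution is symmetric), which makes the frame — and
    hence the field-point grid — follow the molecule under rigid motion.
    """
    coords = np.asarray(coords, float)
    c = coords.mean(axis=0)
    X = coords - c
    cov = X.T @ X / max(len(X), 1)
    _w, E = np.linalg.eigh(cov)
    E = E[:, ::-1]  # descending variance
    for k in range(3):
        proj = X @ E[:, k]
        s = (proj ** 3).sum()
        if abs(s) < 1e-9:
            s = proj[np.argmax(np.abs(proj))]
        if s < 0:
            E[:, k] = -E[:, k]
    if np.linalg.det(E) < 0:
        E[:, 2] = -E[:, 2]
    return E, c


def _shell_grid(coords: np.ndarray, cfg: FieldConfig
                ) -> tuple[np.ndarray, np.ndarray, tuple]:
    """1 A lattice covering the molecule plus the outer shell, with a mask of
    points whose nearest-atom distance lies in [shell_inner, shell_outer]."""
    pad = cfg.shell_outer + cfg.grid_spacing
    lo = np.floor((coords.min(axis=0) - pad) / cfg.grid_spacing)
    hi = np.ceil((coords.max(axis=0) + pad) / cfg.grid_spacing)
    axes = [np.arange(l, h + 1) * cfg.grid_spacing for l, h in zip(lo, hi)]
    shape = tuple(len(a) for a in axes)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.sqrt(((grid[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    mask = (d >= cfg.shell_inner) & (d <= cfg.shell_outer)
    return grid, mask, shape


def compute_field_points(mol3d: Molecule3D, cfg: FieldConfig | None = None
                         ) -> list[FieldPoint]:
    """Field points: strict local extrema of each channel on the shell grid.

    A grid point is an extremum when its channel value strictly exceeds all
    26-neighbour values *and* the per-channel threshold; points outside the
    1.5-4.5 A shell are excluded. The grid is built in the molecule's
    canonical (principal-axes) frame so field points follow the molecule
    under rigid motion; positions are returned in the input frame.
    Deterministic. May be empty for molecules with no significant field.
    """
    cfg = cfg or FieldConfig()
    coords = mol3d.coords
    E, center = canonical_frame(coords[[i for i in mol3d.heavy_atom_indices()]]
                                if mol3d.heavy_atom_indices() else coords)
    local = (coords - center) @ E
    grid, mask, shape = _shell_grid(local, cfg)
    # evaluate fields at the corresponding world positions
    world = grid @ E.T + center
    vals = field_values(mol3d, world, cfg)
    grid = world
    out: list[FieldPoint] = []
    for ci, channel in enumerate(CHANNELS):
        v = vals[:, ci].copy()
        if channel == "hydrophobic":
            v = np.abs(v)  # lipophilic magnitude; hydrophilic troughs ignored
        v[~mask] = -np.inf
        cube = v.reshape(shape)
        footprint = np.ones((3, 3, 3), bool)
        footprint[1, 1, 1] = False  # exclude the center: strict extrema only
        neigh_max = ndimage.maximum_filter(cube, footprint=footprint,
                                           mode="constant", cval=-np.inf)
        is_max = (cube > neigh_max) & np.isfinite(cube)
        idx = np.flatnonzero(is_max.reshape(-1) & (v > cfg.threshold(channel)))
        for i in idx:
            out.append(FieldPoint(tuple(grid[i]), channel,
                                  float(vals[i, ci])))
    return out


@dataclass(frozen=True)
class SamplePointSet:
    """Gauge-invariant descriptor anchor points on the shared 1 A lattice.

    ``positions`` are lattice coordinates in the template frame; descriptor
    columns are every (position, channel) pair. Identical for any ordering
    of the same training molecules.
    """

    positions: tuple[tuple[float, float, float], ...]
    channels: tuple[str, ...] = CHANNELS
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_columns(self) -> int:
        return len(self.positions) * len(self.channels)

    def column_metadata(self) -> list[dict]:
        return [
            {"point": list(p), "channel": ch}
            for p in self.positions
            for ch in self.channels
        ]

    def to_json(self) -> str:
        return json.dumps({
            "positions": [list(p) for p in self.positions],
            "channels": list(self.channels),
            "provenance": self.provenance,
        })

    @classmethod
    def from_json(cls, text: str) -> "SamplePointSet":
        d = json.loads(text)
        return cls(tuple(tuple(p) for p in d["positions"]),
                   tuple(d["channels"]), d.get("provenance", ""))


def snap_to_lattice(position: Sequence[float], spacing: float = 1.0
                    ) -> tuple[float, float, float]:
    """Snap a point to the lattice using round-half-to-even per coordinate."""
    p = np.asarray(position, float) / spacing
    return tuple((np.round(p) * spacing).tolist())


def build_sample_points(
    field_point_sets: Iterable[Sequence[FieldPoint]],
    spacing: float = 1.0,
    channels: tuple[str, ...] = CHANNELS,
) -> SamplePointSet:
    """Union of training field-point positions snapped to the shared lattice.

    Order-independent (positions sorted lexicographically) and idempotent
    under duplicated input; the lattice origin is the template-frame origin
    so the descriptor space is shared across models built in that frame.
    """
    sets = list(field_point_sets)
    if not sets:
        raise ValueError("empty training set: no field points to union")
    snapped = {
        snap_to_lattice(fp.position, spacing)
        for fps in sets
        for fp in fps
    }
    if not snapped:
        raise ValueError("no field points above threshold in the training set")
    positions = tuple(sorted(snapped))
    return SamplePointSet(positions, channels, provenance=f"n_sets={len(sets)}")


@dataclass
class DescriptorMatrix:
    """Molecules x (sample point x channel) real matrix with column metadata."""

    ids: list[str]
    values: np.ndarray
    sample_points: SamplePointSet

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.ids), self.sample_points.n_columns):
            raise ValueError(
                f"descriptor shape {self.values.shape} != "
                f"({len(self.ids)}, {self.sample_points.n_columns})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite descriptor values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, mol_id: str) -> np.ndarray:
        return self.values[self.ids.index(mol_id)]

    def write_tsv(self, path: str | Path) -> None:
        """Tabular serialization: JSON header line + TSV matrix."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("#" + self.sample_points.to_json() + "\n")
            cols = [f"p{i}_{ch}" for i in range(len(self.sample_points))
                    for ch in self.sample_points.channels]
            fh.write("id\t" + "\t".join(cols) + "\n")
            for rid, row in zip(self.ids, self.values):
                fh.write(rid + "\t"
                         + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DescriptorMatrix":
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing JSON header line")
            sps = SamplePointSet.from_json(header[1:])
            fh.readline()  # column names
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(ids, np.asarray(rows), sps)


def descriptor_matrix(
    molecules: Sequence[Molecule3D],
    sps: SamplePointSet,
    cfg: FieldConfig | None = None,
) -> DescriptorMatrix:
    """Evaluate every channel of every sample point for aligned molecules.

    Molecules must already be in the common template frame; rows follow the
    input order.
    """
    cfg = cfg or FieldConfig()
    pts = np.asarray(sps.positions, float)
    n_ch = len(sps.channels)
    ch_index = [CHANNELS.index(c) for c in sps.channels]
    rows = np.empty((len(molecules), len(pts) * n_ch))
    for r, m in enumerate(molecules):
        vals = field_values(m, pts, cfg)[:, ch_index]
        rows[r] = vals.reshape(-1)
    return DescriptorMatrix([m.id for m in molecules], rows, sps)


def export_field_points_pdb(points: Sequence[FieldPoint], path: str | Path) -> None:
    """Write field points as PDB HETATM pseudo-atoms for visualization."""
    names = {"electro_pos": "EP", "electro_neg": "EN",
             "steric": "ST", "hydrophobic": "HY"}
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, fp in enumerate(points, start=1):
            x, y, z = fp.position
            fh.write(
                f"HETATM{i:5d} {names[fp.channel]:<4s}FPT A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{fp.magnitude:6.2f}\n")
        fh.write("END\n")
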