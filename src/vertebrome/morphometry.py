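"""Per-vertebra morphometry: the 25 element/outcome measures.

For each skeletal element (neural arch, centrum, haemal arch/ribs) and for
the whole vertebra ("total", computed on the union mask) six quantities are
measured: tissue mineral density (TMD, mgHA/cm^3), mean local thickness
(Th, um), volume (Vol, um^3), surface area (SA, um^2), and the
intra-specimen variations TMD.sd and Th.sd (population SDs over the voxels
of one element). Centrum length (Cent.Le, um) is derived from the seed
boundary midpoints, giving 4 x 6 + 1 = 25 measures per vertebra.

Conventions: volume is exactly voxel-count based; surface area uses the
perimeter-voxel-count estimator (a foreground voxel counts if it has at
least one face-adjacent background neighbor, volume-boundary voxels
included), which is biased relative to meshed surfaces and should not be
compared across estimators; thickness is the model-independent local
thickness (largest-inscribed-sphere diameter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import ElementMasks, SeedLine, VertebraLabelMap
from .volume_io import CalibratedVolume

__all__ = [
    "MEASURES",
    "LONG_NAMES",
    "SHORT_NAMES",
    "ElementMeasures",
    "Phenome",
    "local_thickness",
    "measure_element",
    "centrum_length",
    "assemble_phenome",
    "write_phenome",
    "read_phenome",
]

_ELEMENTS = ("Cent", "Neur", "Haem", "Tot")
_OUTCOMES = ("TMD", "Th", "Vol", "SA", "TMD.sd", "Th.sd")

#: Canonical order of the 25 per-vertebra measures.
MEASURES: tuple[str, ...] = tuple(
    f"{e}.{o}" for e in _ELEMENTS for o in _OUTCOMES
) + ("Cent.Le",)

#: Short measure name -> long column name used in phenome text tables.
LONG_NAMES: dict[str, str] = {
    "Tot.Vol": "VertebralVolumes",
    "Cent.Vol": "CentrumVolumes",
    "Haem.Vol": "HaemalVolumes",
    "Neur.Vol": "NeuralVolumes",
    "Tot.SA": "VertebralSAs",
    "Cent.SA": "CentrumSAs",
    "Haem.SA": "HaemalSAs",
    "Neur.SA": "NeuralSAs",
    "Tot.TMD": "VertebralTMDs",
    "Cent.TMD": "CentrumTMDs",
    "Haem.TMD": "HaemalTMDs",
    "Neur.TMD": "NeuralTMDs",
    "Tot.TMD.sd": "VertebralISs",
    "Cent.TMD.sd": "CentrumISs",
    "Haem.TMD.sd": "HaemalISs",
    "Neur.TMD.sd": "NeuralISs",
    "Tot.Th": "VertebralMTs",
    "Cent.Th": "CentrumMTs",
    "Haem.Th": "HaemalMTs",
    "Neur.Th": "NeuralMTs",
    "Tot.Th.sd": "VertebralTSs",
    "Cent.Th.sd": "CentrumTSs",
    "Haem.Th.sd": "HaemalTSs",
    "Neur.Th.sd": "NeuralTSs",
    "Cent.Le": "CentrumLength",
}

SHORT_NAMES: dict[str, str] = {v: k for k, v in LONG_NAMES.items()}


@dataclass
class ElementMeasures:
    """The six measures of one skeletal element (NaN when unmeasurable)."""

    vol: float
    sa: float
    th: float
    th_sd: float
    tmd: float
    tmd_sd: float


@dataclass
class Phenome:
    """One fish: a vertebra x measure table plus body-size metadata.

    ``table`` is indexed by vertebra number (consecutive from 1) with the
    25 short measure names as columns; missing vertebrae are represented
    as NaN rows, never zero-filled. ``standard_length`` is in mm.
    """

    fish_id: str
    table: pd.DataFrame
    standard_length: float | None = None
    group: str | None = None

    def feature(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"unknown measure {name!r}")
        return self.table[name]


# ---------------------------------------------------------------------------
# Local thickness
# ---------------------------------------------------------------------------

def local_thickness(mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Model-independent local thickness map over a binary structure.

    The thickness of a voxel is the diameter of the largest sphere that is
    fully inscribed in the structure and contains the voxel. Computed by
    the distance-transform -> distance-ridge -> sphere-propagation scheme:
    the Euclidean distance transform gives the inscribed-sphere radius at
    every voxel, redundant centers (spheres contained in a face-neighbor's
    sphere) are discarded, and the surviving spheres are painted in order
    of decreasing radius. Distances are center-to-center, so one voxel
    (the two half-voxel borders) is subtracted from the diameter to place
    the structure boundary at voxel faces: an isolated voxel is 1 voxel
    thick and an n-voxel slab n voxels. Returns a map in physical units
    (``voxel_size`` in um) that is zero outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no thickness")

    edt = ndimage.distance_transform_edt(mask)

    # distance ridge: drop centers whose sphere lies inside a neighbor's
    keep = mask.copy()
    for axis in range(3):
        for shift in (1, -1):
            nb = np.roll(edt, shift, axis=axis)
            # rolled-in border values are invalid; they cannot dominate anyway
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            nb[tuple(sl)] = 0.0
            keep &= ~(nb >= edt + 1.0)

    thick = np.where(mask, 2.0 * edt, 0.0)
    centers = np.argwhere(keep)
    radii = edt[keep]
    order = np.argsort(radii)[::-1]
    shape = mask.shape
    for idx in order:
        c = centers[idx]
        r = radii[idx]
        d = 2.0 * r
        ri = int(np.ceil(r))
        lo = np.maximum(c - ri, 0)
        hi = np.minimum(c + ri + 1, shape)
        box = tuple(slice(lo[a], hi[a]) for a in range(3))
        if thick[box].min() >= d:
            continue
        grids = np.ogrid[box]
        dist2 = sum((g - c[a]) ** 2 for a, g in enumerate(grids))
        inside = dist2 <= r * r
        region = thick[box]
        region[inside & (region < d)] = d
    thick = np.where(mask, np.maximum(thick - 1.0, 1.0), 0.0)
    thick *= float(voxel_size)
    return thick


# ---------------------------------------------------------------------------
# Element measures
# ---------------------------------------------------------------------------

def _surface_voxel_count(mask: np.ndarray) -> int:
    """Count foreground voxels with >=1 face-adjacent background neighbor.

    Voxels on the volume boundary count as surface.
    """
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    interior = np.ones_like(padded)
    for axis in range(3):
        for shift in (1, -1):
            interior &= np.roll(padded, shift, axis=axis)
    surface = padded & ~interior
    return int(surface.sum())


def measure_element(mask: np.ndarray, vol: CalibratedVolume) -> ElementMeasures:
    """Measure one element mask against the calibrated volume."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume {vol.shape}")
    if not mask.any():
        warnings.warn("empty element mask: measures reported as missing", stacklevel=2)
        nan = float("nan")
        return ElementMeasures(nan, nan, nan, nan, nan, nan)

    vs = vol.voxel_size
    n = int(mask.sum())
    volume = n * vs**3
    sa = _surface_voxel_count(mask) * vs**2
    th_map = local_thickness(mask, voxel_size=vs)
    th_vals = th_map[mask]
    tmd_vals = vol.calibrated()[mask]
    return ElementMeasures(
        vol=float(volume),
        sa=float(sa),
        th=float(th_vals.mean()),
        th_sd=float(th_vals.std()),
        tmd=float(tmd_vals.mean()),
        tmd_sd=float(tmd_vals.std()),
    )


def centrum_length(anterior: SeedLine, posterior: SeedLine, voxel_size: float) -> float:
    """Anteroposterior distance between boundary-line midpoints, in um."""
    d = abs(posterior.ap_midpoint - anterior.ap_midpoint)
    if d == 0:
        warnings.warn("coincident vertebral boundaries: centrum length 0", stacklevel=2)
    return d * voxel_size


# ---------------------------------------------------------------------------
# Phenome assembly and I/O
# ---------------------------------------------------------------------------

def assemble_phenome(
    elements: dict[int, ElementMasks],
    vol: CalibratedVolume,
    boundaries: list[SeedLine],
    fish_id: str = "fish",
    standard_length: float | None = None,
    group: str | None = None,
) -> Phenome:
    """Compute all 25 measures for every vertebra.

    ``elements`` maps vertebra number (1..n) to its element masks;
    ``boundaries`` are the n+1 accepted boundary lines ordered
    anteroposteriorly. Total measures are computed on the union mask of
    the three elements, not averaged from them.
    """
    boundaries = sorted(boundaries, key=lambda s: s.ap_midpoint)
    rows = {}
    for v in sorted(elements):
        masks = elements[v]
        row: dict[str, float] = {}
        per_element = dict(masks.as_dict())
        per_element["Tot"] = masks.union
        for name, m in per_element.items():
            if m.any():
                em = measure_element(m, vol)
            else:
                warnings.warn(
                    f"vertebra {v}: element {name} missing", stacklevel=2
                )
                nan = float("nan")
                em = ElementMeasures(nan, nan, nan, nan, nan, nan)
            row[f"{name}.TMD"] = em.tmd
            row[f"{name}.Th"] = em.th
            row[f"{name}.Vol"] = em.vol
            row[f"{name}.SA"] = em.sa
            row[f"{name}.TMD.sd"] = em.tmd_sd
            row[f"{name}.Th.sd"] = em.th_sd
        if v < len(boundaries):
            row["Cent.Le"] = centrum_length(
                boundaries[v - 1], boundaries[v], vol.voxel_size
            )
        else:
            row["Cent.Le"] = float("nan")
        rows[v] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(MEASURES))
    table.index.name = "vertebra"
    return Phenome(
        fish_id=fish_id,
        table=table,
        standard_length=standard_length,
        group=group,
    )


def write_phenome(phenome: Phenome, path) -> None:
    """Write one fish's phenome as a tab-separated table.

    One row per vertebra, columns under their long names
    (VertebralVolumes, CentrumTMDs, ...) so that cohort tables in that
    dialect parse with :func:`read_phenome`.
    """
    out = phenome.table.rename(columns=LONG_NAMES)
    out.to_csv(path, sep="\t", index=False)


def read_phenome(
    path,
    fish_id: str | None = None,
    standard_length: float | None = None,
    group: str | None = None,
) -> Phenome:
    """Read a tab-separated phenome table (long or short column names)."""
    table = pd.read_csv(path, sep="\t")
    table = table.rename(columns=SHORT_NAMES)
    if "vertebra" in table.columns:
        table = table.set_index("vertebra")
        table.index = table.index.astype(int)
    else:
        table.index = pd.RangeIndex(1, len(table) + 1, name="vertebra")
    unknown = [c for c in table.columns if c not in MEASURES]
    if unknown:
        raise ValueError(f"unrecognized measure columns: {unknown}")
    return Phenome(
        fish_id=fish_id or str(path),
        table=table,
        standard_length=standard_length,
        group=group,
    )
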