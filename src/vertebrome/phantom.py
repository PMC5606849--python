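"""Synthetic spine phantoms with ground truth.

Generates microCT-like volumes of a vertebral column so that segmentation
and morphometry are testable without scan data. Each vertebra is built
from three analytic structures on the (dorsoventral, mediolateral,
anteroposterior) grid:

* centrum: a hollow hourglass cylinder along the anteroposterior axis
  (outer radius tapers to a waist at mid-length, constant wall thickness);
* neural arch: a dorsal half-annulus seated on top of the centrum;
* haemal arch/ribs: a ventral half-annulus, enlarged on anterior
  vertebrae to emulate the rib-bearing precaudal region's higher haemal
  volumes. The haemal arch is offset ventrally from the centrum wall by a
  small clearance emulating the soft-tissue separation at its base (and
  keeping the default centrum buffer from annexing the arch).

Intensities default to raw values whose calibrated densities fall in the
range of adult zebrafish bone (~390-490 mgHA/cm^3); Gaussian noise is
added over the whole grid. Ground truth (label map, element masks,
analytic measures, ideal seed lines) accompanies every volume; truth
measures are analytic except volume, where the voxel count is the
definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import LONG_NAMES
from .segmentation import ElementMasks, SeedLine, VertebraLabelMap, write_seed_lines
from .volume_io import (
    CalibratedVolume,
    CalibrationParams,
    calibrate_intensity,
    write_dicom_series,
)

__all__ = ["PhantomSpec", "PhantomTruth", "generate_spine_phantom",
           "generate_seed_lines", "write_dicom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of a spine phantom.

    Lengths and radii are in voxels; intensities are raw scanner values.
    """

    n_vertebrae: int = 5
    centrum_radius: float = 14.0
    centrum_wall: float = 4.0
    centrum_length: int = 30
    waist_factor: float = 0.8
    arch_radius: float = 12.0
    arch_wall: float = 3.0
    arch_extent: int = 12
    rib_extra_radius: float = 6.0
    arch_clearance: int = 6
    gap: int = 4
    centrum_intensity: float = 10000.0
    arch_intensity: float = 8500.0
    noise_sd: float = 150.0
    voxel_size: float = 21.0
    seed: int = 0
    margin: int = 4

    def __post_init__(self) -> None:
        if self.centrum_wall < 1 or self.arch_wall < 1:
            raise ValueError("wall thickness must be >= 1 voxel")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.n_vertebrae < 1:
            raise ValueError("need at least one vertebra")

    @property
    def pitch(self) -> int:
        """Anteroposterior period of the column (centrum + gap)."""
        return self.centrum_length + self.gap


@dataclass
class PhantomTruth:
    """Ground truth for one phantom volume."""

    label_map: VertebraLabelMap
    elements: dict[int, ElementMasks]
    table: pd.DataFrame
    seed_lines: list[SeedLine]
    spec: PhantomSpec
    suggested_threshold: float = 0.0


def _grid(shape):
    dv = np.arange(shape[0])[:, None, None]
    ml = np.arange(shape[1])[None, :, None]
    ap = np.arange(shape[2])[None, None, :]
    return dv, ml, ap


def generate_spine_phantom(
    spec: PhantomSpec = PhantomSpec(),
    calibration: CalibrationParams | None = None,
) -> tuple[CalibratedVolume, PhantomTruth]:
    """Build a phantom volume and its ground truth. Deterministic per seed."""
    cal = calibration or CalibrationParams()
    n = spec.n_vertebrae
    r_o, wall = spec.centrum_radius, spec.centrum_wall
    r_a, w_a = spec.arch_radius, spec.arch_wall
    r_rib = r_a + spec.rib_extra_radius
    clear = spec.arch_clearance
    L, gap, m = spec.centrum_length, spec.gap, spec.margin

    dv_size = int(m + r_a + w_a + 2 * r_o + clear + r_rib + w_a + m)
    ml_size = int(2 * (max(r_o, r_rib) + m))
    ap_size = int(2 * m + (n + 1) * gap + n * L)
    shape = (dv_size, ml_size, ap_size)
    c_dv = float(m + r_a + w_a + r_o)  # centrum axis, dorsoventral
    c_ml = ml_size / 2.0 - 0.5

    dv, ml, ap = _grid(shape)
    intensities = np.zeros(shape, dtype=float)
    elements: dict[int, ElementMasks] = {}
    labels = np.zeros(shape, dtype=np.int32)
    seed_lines: list[SeedLine] = []
    rows = {}

    dv_n = c_dv - r_o  # dorsal rim of the centrum
    dv_v = c_dv + r_o  # ventral rim

    for v in range(1, n + 1):
        z0 = m + gap * v + L * (v - 1)
        zc = z0 + L / 2.0

        # hollow hourglass centrum
        s = np.clip(2.0 * (ap - zc) / L, -1.0, 1.0)
        r_z = r_o * (spec.waist_factor + (1.0 - spec.waist_factor) * s**2)
        rad2 = (dv - c_dv) ** 2 + (ml - c_ml) ** 2
        in_span = (ap >= z0) & (ap < z0 + L)
        cent = in_span & (rad2 <= r_z**2) & (rad2 > (r_z - wall) ** 2)

        # arches: half annuli over the middle arch_extent slices
        a0 = int(round(zc - spec.arch_extent / 2))
        arch_span = (ap >= a0) & (ap < a0 + spec.arch_extent)
        rad2_n = (dv - dv_n) ** 2 + (ml - c_ml) ** 2
        neur = (
            arch_span
            & (dv < dv_n)
            & (rad2_n <= r_a**2)
            & (rad2_n > (r_a - w_a) ** 2)
        )
        anterior = v <= (n + 1) // 2
        r_h = r_rib if anterior else r_a
        dv_h = dv_v + clear
        rad2_h = (dv - dv_h) ** 2 + (ml - c_ml) ** 2
        haem = (
            arch_span
            & (dv > dv_h)
            & (rad2_h <= r_h**2)
            & (rad2_h > (r_h - w_a) ** 2)
        )

        cent &= ~(neur | haem)
        union = cent | neur | haem
        if (labels[union] != 0).any():
            raise ValueError(
                "phantom not separable: elements of adjacent vertebrae overlap"
            )
        labels[union] = v
        elements[v] = ElementMasks(neur=neur, cent=cent, haem=haem)
        intensities[cent] = spec.centrum_intensity
        intensities[neur | haem] = spec.arch_intensity

        rows[v] = {
            "Cent.Vol": cent.sum() * spec.voxel_size**3,
            "Neur.Vol": neur.sum() * spec.voxel_size**3,
            "Haem.Vol": haem.sum() * spec.voxel_size**3,
            "Tot.Vol": union.sum() * spec.voxel_size**3,
            "Cent.Th": wall * spec.voxel_size,
            "Neur.Th": w_a * spec.voxel_size,
            "Haem.Th": w_a * spec.voxel_size,
            "Cent.Le": spec.pitch * spec.voxel_size,
            "Cent.TMD": calibrate_intensity(spec.centrum_intensity, cal),
            "Neur.TMD": calibrate_intensity(spec.arch_intensity, cal),
            "Haem.TMD": calibrate_intensity(spec.arch_intensity, cal),
        }

    # ideal seed lines at the centers of the intervertebral gaps
    for b in range(n + 1):
        b_ap = m + gap * (b + 0.5) + L * b
        seed_lines.append(
            SeedLine(
                np.array([[dv_n, c_ml, b_ap], [dv_v, c_ml, b_ap]]),
                index=b,
            )
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensities = intensities + rng.normal(0.0, spec.noise_sd, shape)
    intensities = np.clip(np.round(intensities), 0, 65535).astype(np.uint16)

    vol = CalibratedVolume(intensities, spec.voxel_size, cal)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "vertebra"
    truth = PhantomTruth(
        label_map=VertebraLabelMap(labels, n, boundaries=seed_lines),
        elements=elements,
        table=table,
        seed_lines=seed_lines,
        spec=spec,
        suggested_threshold=0.5 * min(spec.centrum_intensity, spec.arch_intensity),
    )
    return vol, truth


def generate_seed_lines(
    truth: PhantomTruth,
    jitter: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[SeedLine]:
    """Simulated user seeds: ideal gap-center lines with uniform jitter.

    Endpoint coordinates are perturbed by uniform noise in [-jitter,
    jitter] (dorsoventral and anteroposterior); a line whose endpoints
    would leave its intervertebral gap is resampled up to 10 times before
    raising.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if jitter == 0:
        return [SeedLine(s.endpoints.copy(), s.index) for s in truth.seed_lines]
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    spec = truth.spec
    half_gap = spec.gap / 2.0
    out = []
    for s in truth.seed_lines:
        center_ap = s.ap_midpoint
        for attempt in range(10):
            pts = s.endpoints.copy()
            pts[:, 0] += gen.uniform(-jitter, jitter, 2)
            pts[:, 2] += gen.uniform(-jitter, jitter, 2)
            if np.all(np.abs(pts[:, 2] - center_ap) < half_gap):
                out.append(SeedLine(pts, s.index))
                break
        else:
            raise ValueError(
                f"seed {s.index}: jitter {jitter} exceeds the intervertebral gap"
            )
    return out


def write_dicom(vol: CalibratedVolume, truth: PhantomTruth, path) -> Path:
    """Write the phantom as a DICOM series with text truth sidecars.

    Sidecars: ``seeds.tsv`` (ideal boundary lines) and
    ``truth_measures.tsv`` (analytic per-vertebra measures, long column
    names where defined).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_dicom_series(vol, path)
    write_seed_lines(truth.seed_lines, path / "seeds.tsv")
    table = truth.table.rename(columns=LONG_NAMES)
    table.to_csv(path / "truth_measures.tsv", sep="\t")
    return path
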