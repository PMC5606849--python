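"""Seeded segmentation of the vertebral column.

The workflow mirrors supervised spine segmentation for whole-body microCT:

1. an automatic IsoData threshold (scaled by a conservative correction
   factor) binarizes mineralized tissue;
2. user seed lines drawn between adjacent centra are extruded into
   separation planes; each plane is grown (the seed segment is extended
   along its own direction) until the connected components on its two
   anteroposterior sides have distinct plurality components;
3. connected components between consecutive accepted boundaries receive
   consecutive vertebra labels;
4. each vertebra is split into neural arch, centrum and haemal-arch/rib
   masks from the seed-line endpoints.

Seed lines are drawn in the mid-sagittal (dorsoventral x anteroposterior)
plane and extruded across the full mediolateral extent, the only geometry
consistent with "the plane defined by the separation line".

Coordinates are voxel indices ordered (dorsoventral, mediolateral,
anteroposterior); dorsal is index 0 along axis 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw, measure

from .volume_io import CalibratedVolume

__all__ = [
    "SeedLine",
    "read_seed_lines",
    "write_seed_lines",
    "VertebraLabelMap",
    "ElementMasks",
    "isodata_threshold",
    "compute_threshold",
    "binarize",
    "separate_vertebrae",
    "apply_cut",
    "assign_components",
    "segment_elements",
    "dice_coefficient",
]

_DV, _ML, _AP = 0, 1, 2


@dataclass
class SeedLine:
    """A user-drawn boundary between two adjacent centra.

    ``endpoints`` are two (dv, ml, ap) voxel-coordinate points, one dorsal
    and one ventral; ``index`` is the ordinal position of the boundary along
    the column (0 = boundary anterior to vertebra 1). For ``n`` analyzed
    vertebrae there are ``n + 1`` boundaries.
    """

    endpoints: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=float).reshape(2, 3)
        if np.allclose(self.endpoints[0], self.endpoints[1]):
            raise ValueError("seed line endpoints must be distinct")

    @property
    def ap_midpoint(self) -> float:
        return float(self.endpoints[:, _AP].mean())

    @property
    def midpoint(self) -> np.ndarray:
        return self.endpoints.mean(axis=0)

    @property
    def dorsal(self) -> np.ndarray:
        """Endpoint with the smaller dorsoventral coordinate."""
        return self.endpoints[np.argmin(self.endpoints[:, _DV])]

    @property
    def ventral(self) -> np.ndarray:
        return self.endpoints[np.argmax(self.endpoints[:, _DV])]


@dataclass
class VertebraLabelMap:
    """Integer voxel map: 0 = background, v >= 1 = vertebra v."""

    labels: np.ndarray
    n_vertebrae: int
    boundaries: list[SeedLine] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")

    def vertebra_mask(self, v: int) -> np.ndarray:
        if not 1 <= v <= self.n_vertebrae:
            raise ValueError(f"vertebra {v} out of range 1..{self.n_vertebrae}")
        return self.labels == v

    def check_component_invariant(self) -> None:
        """Assert no 26-connected foreground component carries two labels."""
        comps = measure.label(self.labels > 0, connectivity=3)
        for c in range(1, comps.max() + 1):
            vals = np.unique(self.labels[comps == c])
            if len(vals) > 1:
                raise AssertionError(
                    f"connected component {c} carries labels {vals.tolist()}"
                )


@dataclass
class ElementMasks:
    """Neural-arch / centrum / haemal-arch binary masks of one vertebra.

    The three masks are pairwise disjoint and partition the vertebra.
    """

    neur: np.ndarray
    cent: np.ndarray
    haem: np.ndarray

    def __post_init__(self) -> None:
        for m in (self.neur, self.cent, self.haem):
            if m.shape != self.neur.shape:
                raise ValueError("element masks must share one shape")
        overlap = (
            (self.neur & self.cent) | (self.neur & self.haem) | (self.cent & self.haem)
        )
        if overlap.any():
            raise ValueError("element masks must be pairwise disjoint")

    @property
    def union(self) -> np.ndarray:
        return self.neur | self.cent | self.haem

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"Neur": self.neur, "Cent": self.cent, "Haem": self.haem}


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def isodata_threshold(values, nbins: int = 256) -> float:
    """Iterative intermeans (IsoData) threshold of an intensity sample.

    Finds the fixed point ``T = (mean(values < T) + mean(values >= T)) / 2``
    on an ``nbins``-bin histogram of the input and returns the value-scale
    threshold. Raises on a degenerate (constant) sample.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty intensity sample")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("degenerate histogram: all intensities equal")

    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    csum = np.cumsum(counts)
    cmass = np.cumsum(counts * centers)
    total_n, total_m = csum[-1], cmass[-1]

    t = 0.5 * (lo + hi)
    for _ in range(500):
        # mean below / at-or-above t, from the cumulative histogram
        i = int(np.searchsorted(centers, t, side="left"))
        n_lo = csum[i - 1] if i > 0 else 0
        if n_lo == 0 or n_lo == total_n:
            # walk inward from a one-sided split
            i = max(1, min(nbins - 1, i))
            n_lo = csum[i - 1]
        m_lo = cmass[i - 1] if i > 0 else 0.0
        mean_lo = m_lo / n_lo
        mean_hi = (total_m - m_lo) / (total_n - n_lo)
        t_new = 0.5 * (mean_lo + mean_hi)
        if abs(t_new - t) < 0.5 * (centers[1] - centers[0]):
            return float(t_new)
        t = t_new
    return float(t)


def compute_threshold(
    vol: CalibratedVolume,
    fish_outline: np.ndarray,
    correction: float = 0.73,
    projection_axis: int | None = None,
    nbins: int = 256,
) -> float:
    """Semi-automatic specimen threshold.

    ``fish_outline`` is a 2D boolean mask drawn on a maximum-intensity
    projection (by default along the mediolateral axis). The outline is
    extruded back along the projection axis, voxels outside it are zeroed,
    IsoData runs on the histogram of the remaining nonzero voxels, and the
    result is multiplied by ``correction`` (default 0.73; a correction
    below 1 gives more permissive thresholding of weakly mineralized fish).
    """
    if correction <= 0:
        raise ValueError("correction factor must be positive")
    fish_outline = np.asarray(fish_outline, dtype=bool)
    if not fish_outline.any():
        raise ValueError("empty fish outline")
    axis = (
        vol.axis_labels.index("mediolateral")
        if projection_axis is None
        else projection_axis
    )
    expected = tuple(s for i, s in enumerate(vol.shape) if i != axis)
    if fish_outline.shape != expected:
        raise ValueError(
            f"outline shape {fish_outline.shape} does not match projection {expected}"
        )
    inside = np.expand_dims(fish_outline, axis=axis)
    masked = np.where(inside, vol.intensities, 0)
    sample = masked[masked > 0]
    if sample.size == 0:
        raise ValueError("no nonzero voxels inside the outline")
    return isodata_threshold(sample, nbins=nbins) * correction


def binarize(vol, threshold: float) -> np.ndarray:
    """Foreground mask: intensity >= threshold (inclusive)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    data = vol.intensities if isinstance(vol, CalibratedVolume) else np.asarray(vol)
    return data >= threshold


# ---------------------------------------------------------------------------
# Separation-plane growing
# ---------------------------------------------------------------------------

def _plane_voxels(shape, p0, p1):
    """Rasterize the mid-sagittal segment p0-p1 and extrude across ml.

    Returns (dv_idx, ap_idx) index arrays of in-plane pixels, clipped to
    the volume bounds.
    """
    r0, c0 = int(round(p0[_DV])), int(round(p0[_AP]))
    r1, c1 = int(round(p1[_DV])), int(round(p1[_AP]))
    rr, cc = draw.line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < shape[_DV]) & (cc >= 0) & (cc < shape[_AP])
    return rr[keep], cc[keep]


def _side_of_line(p0, p1, dv, ap):
    """Signed side of (dv, ap) points relative to the directed line p0->p1.

    The sign is arranged so that negative is anterior when the line runs
    dorsal-to-ventral.
    """
    d_dv, d_ap = p1[_DV] - p0[_DV], p1[_AP] - p0[_AP]
    return d_dv * (ap - p0[_AP]) - d_ap * (dv - p0[_DV])


def _plurality(labels, counts):
    """Label with the plurality of voxel votes; None on a tie or no votes."""
    if len(labels) == 0:
        return None
    order = np.argsort(counts)[::-1]
    if len(counts) > 1 and counts[order[0]] == counts[order[1]]:
        return None
    return labels[order[0]]


def _grow_separation(mask, seed, step, window, max_extent=None):
    """Extend one seed line until its plane separates the two sides.

    Returns the accepted (p0, p1) endpoints and the in-plane pixel indices.
    Raises if the line leaves the volume without achieving separation.
    """
    shape = mask.shape
    p0 = seed.endpoints[0][[_DV, _AP]].astype(float)
    p1 = seed.endpoints[1][[_DV, _AP]].astype(float)
    u = p1 - p0
    norm = np.hypot(*u)
    if norm == 0:
        raise ValueError(f"seed {seed.index}: zero-length line")
    u /= norm
    pad = lambda q: np.array([q[0], 0, q[1]])  # (dv, ap) -> (dv, ml, ap)

    for it in range(max(shape) // max(1, step) + 2):
        q0 = p0 - u * step * it
        q1 = p1 + u * step * it
        rr, cc = _plane_voxels(shape, pad(q0), pad(q1))
        if rr.size == 0:
            break
        work = mask.copy()
        work[rr, :, cc] = False

        ap_lo = max(0, int(cc.min()) - window)
        ap_hi = min(shape[_AP], int(cc.max()) + window + 1)
        sub = work[:, :, ap_lo:ap_hi]
        comps = measure.label(sub, connectivity=3)
        fg = comps > 0
        if not fg.any():
            raise ValueError(f"seed {seed.index}: separation plane removed all foreground")
        dv_idx, _, ap_idx = np.nonzero(fg)
        side = _side_of_line(pad(q0), pad(q1), dv_idx, ap_idx + ap_lo)
        labels_fg = comps[fg]

        ant = side < 0
        post = side > 0
        la, ca = np.unique(labels_fg[ant], return_counts=True)
        lp, cp = np.unique(labels_fg[post], return_counts=True)
        # an empty side (e.g. the boundary anterior to vertebra 1) is
        # trivially separated; a plurality tie counts as not separated
        if len(la) == 0 or len(lp) == 0:
            return q0, q1, (rr, cc)
        win_a = _plurality(la, ca)
        win_p = _plurality(lp, cp)
        if win_a is not None and win_p is not None and win_a != win_p:
            return q0, q1, (rr, cc)

        extent = np.hypot(*(q1 - q0))
        if max_extent is not None and extent > max_extent:
            break
        # stop once both endpoints are outside the mid-sagittal bounds
        out0 = not (0 <= q0[0] < shape[_DV] and 0 <= q0[1] < shape[_AP])
        out1 = not (0 <= q1[0] < shape[_DV] and 0 <= q1[1] < shape[_AP])
        if out0 and out1:
            break
    raise ValueError(
        f"seed {seed.index}: line extension reached the volume boundary "
        "without separating the two sides"
    )


def separate_vertebrae(
    mask: np.ndarray,
    seeds: list[SeedLine],
    step: int = 2,
    window: int = 10,
) -> VertebraLabelMap:
    """Partition a foreground mask into vertebrae from seed boundary lines.

    Each seed line is extruded mediolaterally into a separation plane whose
    voxels are zeroed; the plurality connected component is tallied (by
    voxel count) on the two anteroposterior sides of the plane within a
    local window of ``window`` voxels, and the line is extended outward by
    ``step`` voxels per endpoint and iteration until the plurality
    components differ. Voxels between consecutive accepted boundaries
    receive consecutive labels 1..n.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(seeds) < 2:
        raise ValueError("need at least two seed lines (n+1 boundaries for n vertebrae)")
    seeds = sorted(seeds, key=lambda s: s.ap_midpoint)

    work = mask.copy()
    accepted: list[SeedLine] = []
    used_pixels: set[tuple[int, int]] = set()
    for i, seed in enumerate(seeds):
        q0, q1, (rr, cc) = _grow_separation(work, seed, step, window)
        pix = set(zip(rr.tolist(), cc.tolist()))
        if pix & used_pixels:
            raise ValueError(
                f"separation plane of seed {seed.index} overlaps a previous plane"
            )
        used_pixels |= pix
        work[rr, :, cc] = False
        accepted.append(
            SeedLine(
                np.array([[q0[0], 0.0, q0[1]], [q1[0], 0.0, q1[1]]]),
                index=i,
            )
        )

    bounds_ap = [s.ap_midpoint for s in accepted]
    comps = measure.label(work, connectivity=3)
    labels = np.zeros(mask.shape, dtype=np.int32)
    n_vert = len(accepted) - 1
    if comps.max() > 0:
        centroids_ap = np.array(
            [c.centroid[_AP] for c in measure.regionprops(comps)]
        )
        for cid, ap in enumerate(centroids_ap, start=1):
            slab = int(np.searchsorted(bounds_ap, ap))
            if 1 <= slab <= n_vert:
                labels[comps == cid] = slab
    return VertebraLabelMap(labels=labels, n_vertebrae=n_vert, boundaries=accepted)


def apply_cut(mask: np.ndarray, p0, p1) -> np.ndarray:
    """Manually sever connections: zero the extruded plane through p0-p1.

    Idempotent; points are (dv, ml, ap) voxel coordinates.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    p0, p1 = np.asarray(p0, dtype=float), np.asarray(p1, dtype=float)
    for p in (p0, p1):
        if not all(0 <= p[a] < mask.shape[a] for a in range(3)):
            raise ValueError(f"cut point {p.tolist()} outside volume {mask.shape}")
    rr, cc = _plane_voxels(mask.shape, p0, p1)
    mask[rr, :, cc] = False
    return mask


def assign_components(
    labelmap: VertebraLabelMap, reassignments: list[tuple[int, int]]
) -> VertebraLabelMap:
    """Reassign whole connected components to different vertebrae.

    ``reassignments`` pairs a connected-component id (of the foreground of
    the label map, 26-connectivity, ids as produced by
    ``skimage.measure.label``) with a target vertebra label.
    """
    labels = labelmap.labels.copy()
    comps = measure.label(labels > 0, connectivity=3)
    n_comp = comps.max()
    for cid, v in reassignments:
        if not 1 <= cid <= n_comp:
            raise ValueError(f"component {cid} does not exist (1..{n_comp})")
        if not 0 <= v <= labelmap.n_vertebrae:
            raise ValueError(f"vertebra label {v} out of range 0..{labelmap.n_vertebrae}")
        labels[comps == cid] = v
    out = VertebraLabelMap(labels, labelmap.n_vertebrae, labelmap.boundaries)
    out.check_component_invariant()
    return out


# ---------------------------------------------------------------------------
# Element segmentation
# ---------------------------------------------------------------------------

def _polygon_area(pts) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def segment_elements(
    vertebra_mask: np.ndarray,
    anterior: SeedLine,
    posterior: SeedLine,
    buffer: int = 5,
) -> ElementMasks:
    """Split one vertebra into neural arch, centrum and haemal arch/ribs.

    * neural arch: vertebra voxels dorsal to the line through the two
      dorsal seed endpoints (extruded mediolaterally);
    * centrum: vertebra voxels inside the quadrilateral prism spanned by
      all four endpoints, dilated by ``buffer`` voxels in the
      dorsoventral/anteroposterior plane, minus the neural arch;
    * haemal arch/ribs: the remaining vertebra voxels.
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    vertebra_mask = np.asarray(vertebra_mask, dtype=bool)
    shape = vertebra_mask.shape

    ad, av = anterior.dorsal, anterior.ventral
    pd_, pv = posterior.dorsal, posterior.ventral
    quad = np.array(
        [
            [ad[_DV], ad[_AP]],
            [pd_[_DV], pd_[_AP]],
            [pv[_DV], pv[_AP]],
            [av[_DV], av[_AP]],
        ]
    )
    if _polygon_area(quad) < 0.5:  # sub-voxel area: effectively collinear
        raise ValueError("degenerate centrum quadrilateral: endpoints are collinear")

    dv_grid = np.arange(shape[_DV], dtype=float)[:, None]
    ap_grid = np.arange(shape[_AP], dtype=float)[None, :]

    # dorsal line in the (dv, ap) plane; vertical lines cannot span a vertebra
    if abs(pd_[_AP] - ad[_AP]) < 0.5:
        raise ValueError("dorsal endpoints share one anteroposterior position")
    slope = (pd_[_DV] - ad[_DV]) / (pd_[_AP] - ad[_AP])
    dv_line = ad[_DV] + slope * (ap_grid - ad[_AP])
    neur2d = dv_grid < dv_line  # strictly dorsal of the line

    rr, cc = draw.polygon(quad[:, 0], quad[:, 1], shape=(shape[_DV], shape[_AP]))
    poly2d = np.zeros((shape[_DV], shape[_AP]), dtype=bool)
    poly2d[rr, cc] = True
    if buffer > 0:
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~poly2d)
        poly2d = dist <= buffer

    neur = vertebra_mask & neur2d[:, None, :]
    cent = vertebra_mask & poly2d[:, None, :] & ~neur
    haem = vertebra_mask & ~neur & ~cent
    return ElementMasks(neur=neur, cent=cent, haem=haem)


def write_seed_lines(seeds: list[SeedLine], path) -> None:
    """Write seed lines as tab-separated text (index, then both endpoints)."""
    with open(path, "w") as fh:
        fh.write("index\tdv1\tml1\tap1\tdv2\tml2\tap2\n")
        for s in sorted(seeds, key=lambda s: s.index):
            p, q = s.endpoints
            fh.write(
                f"{s.index}\t{p[0]:g}\t{p[1]:g}\t{p[2]:g}"
                f"\t{q[0]:g}\t{q[1]:g}\t{q[2]:g}\n"
            )


def read_seed_lines(path) -> list[SeedLine]:
    """Read seed lines written by :func:`write_seed_lines`."""
    seeds = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("index"):
            raise ValueError(f"{path}: not a seed-line table")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            idx, *coords = parts
            coords = [float(c) for c in coords]
            seeds.append(
                SeedLine(np.array([coords[:3], coords[3:]]), index=int(idx))
            )
    return sorted(seeds, key=lambda s: s.index)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A&B| / (|A|+|B|); 1.0 when both empty."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    a, b = int(mask_a.sum()), int(mask_b.sum())
    if a + b == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / (a + b)
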