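"""Synapse calling on expansion-microscopy volumes.

Implements the calibrated intensity-profile-overlap definition of a synapse:
presynaptic puncta are detected and paired with a dendrite centerline, a
two-channel relative-fluorescence line scan is taken across each apposition
in its best side-on (in-plane) or face-on (optical-axis) view, and the
apposition is called a synapse when the overlap of the two channels'
half-maximum supports exceeds a threshold calibrated as the minimum overlap
observed across marker-confirmed synapses.  Densities are then reported per
10 um of dendrite in the shape of a proximal/distal comparison table.

Overlap thresholds and bouton-diameter filters are expressed in
pre-expansion micrometres; measured lengths divide by the expansion factor E.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Punctum",
    "Apposition",
    "IntensityProfile",
    "OverlapResult",
    "CalibrationResult",
    "DensityReport",
    "detect_puncta",
    "find_appositions",
    "choose_orientation",
    "extract_profile",
    "compute_overlap",
    "calibrate_thresholds",
    "classify_apposition",
    "assign_segments",
    "compute_density",
    "convert_expansion",
    "quantify_volume",
]

# Side-on / face-on thresholds calibrated on VGAT/gephyrin-confirmed
# GABAergic synapses (um pre-expansion); used when no calibration set is
# supplied.
THETA_SIDE_UM = 0.23
THETA_FACE_UM = 0.42


def convert_expansion(length_um: float, expansion_factor: float,
                      direction: str) -> float:
    """Convert a length between pre- and post-expansion frames.

    ``direction`` is ``"pre_to_post"`` (multiply by E) or ``"post_to_pre"``
    (divide by E).  The round trip is exact.
    """
    if not expansion_factor > 1:
        raise ValueError("expansion_factor must exceed 1")
    if length_um < 0:
        raise ValueError("length must be non-negative")
    if direction == "pre_to_post":
        return length_um * expansion_factor
    if direction == "post_to_pre":
        return length_um / expansion_factor
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class Punctum:
    """A detected presynaptic bouton.

    ``centroid`` is (x, y, z) um post-expansion; ``diameter`` is the
    equivalent-sphere diameter in um pre-expansion (measured / E).
    """
    centroid: np.ndarray
    diameter: float
    peak_intensity: float
    voxel_count: int


@dataclass
class Apposition:
    """A candidate punctum-dendrite contact.

    ``dendrite_point`` is the nearest centerline arc-length in um
    pre-expansion; ``membrane_gap`` the punctum-surface to tube-surface
    distance in um post-expansion (clamped at 0 for overlapping bodies).
    """
    punctum: Punctum
    dendrite_point: float
    membrane_gap: float
    nearest_xyz: np.ndarray
    surface_xyz: np.ndarray
    radial_axis: np.ndarray
    orientation: str | None = None
    profile: "IntensityProfile | None" = None


@dataclass
class IntensityProfile:
    """A two-channel relative-fluorescence line scan.

    ``positions`` (um post-expansion) are uniform and increasing; each
    channel is normalised to its own maximum within the scan window.
    ``axis`` is ``"in_plane"`` or ``"z"``.
    """
    positions: np.ndarray
    cyto: np.ndarray
    presyn: np.ndarray
    axis: str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.cyto = np.asarray(self.cyto, dtype=float)
        self.presyn = np.asarray(self.presyn, dtype=float)
        if not (len(self.positions) == len(self.cyto) == len(self.presyn)):
            raise ValueError("profile arrays must have equal length")
        if len(self.positions) < 3:
            raise ValueError("profile needs at least 3 samples")
        steps = np.diff(self.positions)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("positions must be uniformly increasing")


@dataclass
class OverlapResult:
    """Outcome of classifying one apposition."""
    overlap_post: float
    overlap_pre: float
    is_synapse: bool
    threshold_used: float
    orientation: str


@dataclass
class CalibrationResult:
    """Classifier thresholds derived from marker-confirmed synapses.

    theta_* are the minimum half-max-support overlaps (um pre-expansion)
    observed across the side-on and face-on calibration profiles.
    """
    theta_side: float
    theta_face: float
    n_side: int
    n_face: int
    overlaps: dict = field(default_factory=dict)


@dataclass
class DensityReport:
    """Per-zone synapse counts and density per 10 um of dendrite."""
    zone: str
    segment_length: float
    n_segments: int
    n_contacted: int
    n_contacts_total: int
    denominator_mode: str = "contacted_only"
    expansion_factor: float | None = None

    def __post_init__(self) -> None:
        if self.n_segments <= 0:
            raise ValueError("need at least one segment")
        if self.n_contacted > self.n_segments:
            raise ValueError("n_contacted cannot exceed n_segments")
        if self.denominator_mode not in ("contacted_only", "all_segments"):
            raise ValueError("denominator_mode must be contacted_only or all_segments")

    @property
    def percent_contacted(self) -> float:
        return 100.0 * self.n_contacted / self.n_segments

    @property
    def density_per_10um(self) -> float:
        denom = (self.n_contacted if self.denominator_mode == "contacted_only"
                 else self.n_segments)
        if denom == 0:
            warnings.warn("no contacted segments; density reported as 0",
                          stacklevel=2)
            return 0.0
        return 10.0 * self.n_contacts_total / (denom * self.segment_length)

    @property
    def density_display(self) -> float:
        """Density rounded to 1 decimal, as reported in summary tables."""
        return round(self.density_per_10um, 1)

    def to_dict(self) -> dict:
        return {
            "zone": self.zone,
            "segment_length_um_pre": self.segment_length,
            "n_segments": self.n_segments,
            "n_contacted": self.n_contacted,
            "n_contacts_total": self.n_contacts_total,
            "percent_contacted": self.percent_contacted,
            "density_per_10um": self.density_per_10um,
            "density_display": self.density_display,
            "denominator_mode": self.denominator_mode,
            "expansion_factor": self.expansion_factor,
        }


# ---------------------------------------------------------------------------
# detection

def detect_puncta(volume, channel: int = 1, min_diameter: float = 0.4,
                  detect_frac: float = 0.25,
                  smooth_sigma_um: float = 0.05) -> list[Punctum]:
    """Detect presynaptic puncta and filter by pre-expansion diameter.

    The channel is lightly smoothed, thresholded at ``detect_frac`` of its
    maximum and labelled; each component is re-segmented at half its own
    peak so that the voxel count measures the half-maximum support, from
    which the equivalent-sphere diameter follows.  Only puncta strictly
    larger than ``min_diameter`` (um pre-expansion, default the 0.4 um
    bouton filter) are kept.  An empty channel yields an empty list.
    """
    img = np.asarray(volume.voxels[channel], dtype=float)
    if img.max() <= 0:
        return []
    if np.mean(img >= img.max() * (1 - 1e-6)) > 1e-3:
        warnings.warn("channel appears saturated; centroids and diameters "
                      "may be biased", stacklevel=2)
    sig = (smooth_sigma_um / volume.voxel_z,
           smooth_sigma_um / volume.voxel_xy,
           smooth_sigma_um / volume.voxel_xy)
    sm = ndimage.gaussian_filter(img, sig)

    labels, n = ndimage.label(sm > detect_frac * sm.max())
    if n == 0:
        return []
    voxel_vol = volume.voxel_xy ** 2 * volume.voxel_z
    E = volume.expansion_factor
    out: list[Punctum] = []
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        comp = labels[slc] == lab
        sub = sm[slc]
        # half-max refinement may split merged neighbours
        refined, m = ndimage.label(comp & (sub >= 0.5 * sub[comp].max()))
        for rlab in range(1, m + 1):
            mask = refined == rlab
            peak = float(sub[mask].max())
            mask = comp & (sub >= 0.5 * peak) & \
                ndimage.binary_dilation(mask, iterations=1)
            count = int(mask.sum())
            d_post = (6.0 * count * voxel_vol / math.pi) ** (1.0 / 3.0)
            d_pre = d_post / E
            if not d_pre > min_diameter:
                continue
            w = sub * mask
            zz, yy, xx = np.nonzero(mask)
            wts = w[zz, yy, xx]
            z0, y0, x0 = (s.start for s in slc)
            centroid = np.array([
                np.average((xx + x0), weights=wts) * volume.voxel_xy,
                np.average((yy + y0), weights=wts) * volume.voxel_xy,
                np.average((zz + z0), weights=wts) * volume.voxel_z,
            ])
            out.append(Punctum(centroid=centroid, diameter=float(d_pre),
                               peak_intensity=peak, voxel_count=count))
    return out


# ---------------------------------------------------------------------------
# apposition geometry

def _nearest_on_polyline(point: np.ndarray, centerline: np.ndarray
                         ) -> tuple[np.ndarray, float, float]:
    """Nearest point on a polyline: (xyz, arc-length, distance)."""
    a = centerline[:-1]
    b = centerline[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", point[None, :] - a, ab)
                / np.maximum(denom, 1e-12), 0, 1)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(point[None, :] - proj, axis=1)
    i = int(np.argmin(d))
    seg_len = np.linalg.norm(ab, axis=1)
    arcs = np.concatenate([[0.0], np.cumsum(seg_len)])
    return proj[i], float(arcs[i] + t[i] * seg_len[i]), float(d[i])


def find_appositions(puncta: list[Punctum], centerline: np.ndarray,
                     dendrite_radius: float, expansion_factor: float,
                     gap_tol: float = 0.2) -> list[Apposition]:
    """Pair puncta with the dendrite tube.

    Keeps puncta whose surface-to-surface distance to the tube (centerline
    distance minus tube radius minus punctum radius, both post-expansion)
    is at most ``gap_tol`` um; records the nearest arc-length position
    (um pre-expansion) and the clamped membrane gap.
    """
    centerline = np.asarray(centerline, dtype=float)
    if centerline.ndim != 2 or len(centerline) < 2:
        raise ValueError("centerline needs at least 2 nodes")
    E = expansion_factor
    r_post = dendrite_radius * E
    out: list[Apposition] = []
    for p in puncta:
        near, arc_post, dist = _nearest_on_polyline(np.asarray(p.centroid, float),
                                                    centerline)
        gap = max(0.0, dist - r_post - (p.diameter * E) / 2.0)
        if gap > gap_tol:
            continue
        radial = np.asarray(p.centroid, float) - near
        nrm = np.linalg.norm(radial)
        if nrm < 1e-9:
            warnings.warn("punctum centroid coincides with the centerline; "
                          "radial axis undefined, defaulting to in-plane",
                          stacklevel=2)
            radial = np.array([0.0, 1.0, 0.0])
        else:
            radial = radial / nrm
        surface = near + radial * min(r_post, dist)
        out.append(Apposition(punctum=p, dendrite_point=arc_post / E,
                              membrane_gap=gap, nearest_xyz=near,
                              surface_xyz=surface, radial_axis=radial))
    return out


def choose_orientation(apposition: Apposition, volume=None) -> Apposition:
    """Fix the scan geometry: face-on if the surface-to-centroid axis lies
    within 45 degrees of the optical (z) axis, else side-on.

    For a punctum whose centroid sits on the membrane the surface-to-centroid
    vector vanishes; the radial direction (centerline point to centroid),
    which is collinear with it whenever it is defined, is used throughout.
    """
    axis = apposition.radial_axis
    cos_z = abs(axis[2])
    apposition.orientation = "face_on" if cos_z >= math.cos(math.radians(45.0)) - 1e-12 \
        else "side_on"
    return apposition


def extract_profile(apposition: Apposition, volume,
                    half_window: float = 3.0) -> IntensityProfile:
    """Line-scan both channels across the apposition.

    Samples over +/- ``half_window`` um (post-expansion) around the
    midpoint of the membrane contact, stepping by the xy voxel size for
    side-on scans and by the z step for face-on scans, with linear
    interpolation between voxels.  Each channel is normalised to its own
    window maximum.  A window that exits the volume is truncated with a
    warning; an all-zero channel in the window is an error.
    """
    if apposition.orientation is None:
        raise ValueError("orientation must be set before profile extraction")
    mid = (apposition.surface_xyz
           + np.asarray(apposition.punctum.centroid, float)) / 2.0

    if apposition.orientation == "face_on":
        axis = np.array([0.0, 0.0, 1.0])
        step = volume.voxel_z
        label = "z"
    else:
        axis = np.array([apposition.radial_axis[0], apposition.radial_axis[1], 0.0])
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 1e-9 else np.array([0.0, 1.0, 0.0])
        step = volume.voxel_xy
        label = "in_plane"

    n_half = int(math.floor(half_window / step))
    offsets = np.arange(-n_half, n_half + 1) * step
    pts = mid[None, :] + offsets[:, None] * axis[None, :]
    nz, ny, nx = volume.shape
    coords = np.stack([pts[:, 2] / volume.voxel_z,
                       pts[:, 1] / volume.voxel_xy,
                       pts[:, 0] / volume.voxel_xy])
    inside = ((coords[0] >= 0) & (coords[0] <= nz - 1)
              & (coords[1] >= 0) & (coords[1] <= ny - 1)
              & (coords[2] >= 0) & (coords[2] <= nx - 1))
    if not inside.all():
        warnings.warn("scan window truncated at the volume boundary",
                      stacklevel=2)
        # keep the contiguous valid run containing the centre sample
        centre = n_half
        if not inside[centre]:
            raise ValueError("apposition midpoint outside the volume")
        lo = centre
        while lo > 0 and inside[lo - 1]:
            lo -= 1
        hi = centre
        while hi < len(offsets) - 1 and inside[hi + 1]:
            hi += 1
        offsets = offsets[lo:hi + 1]
        coords = coords[:, lo:hi + 1]

    prof = []
    for ch in range(2):
        vals = ndimage.map_coordinates(volume.voxels[ch], coords, order=1,
                                       mode="nearest")
        m = vals.max()
        if m <= 0:
            raise ValueError("no signal in scan window")
        prof.append(vals / m)
    return IntensityProfile(positions=offsets, cyto=prof[0], presyn=prof[1],
                            axis=label)


# ---------------------------------------------------------------------------
# overlap and classification

def _half_max_support(positions: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Contiguous interval around the global peak where y >= half max,
    with linearly interpolated boundaries."""
    y = np.asarray(y, dtype=float)
    half = 0.5 * y.max()
    peak = int(np.argmax(y))
    lo = peak
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < len(y) - 1 and y[hi + 1] >= half:
        hi += 1
    if np.any(y[:lo] >= half) or np.any(y[hi + 1:] >= half):
        warnings.warn("multimodal profile; using the interval around the "
                      "global peak only", stacklevel=2)
    if lo == 0:
        left = positions[0]
    else:
        f = (y[lo] - half) / (y[lo] - y[lo - 1])
        left = positions[lo] - f * (positions[lo] - positions[lo - 1])
    if hi == len(y) - 1:
        right = positions[-1]
    else:
        f = (y[hi] - half) / (y[hi] - y[hi + 1])
        right = positions[hi] + f * (positions[hi + 1] - positions[hi])
    return float(left), float(right)


def compute_overlap(profile: IntensityProfile,
                    expansion_factor: float) -> tuple[float, float]:
    """Overlap of the two channels' half-maximum supports.

    Returns ``(overlap_pre, overlap_post)`` in um; 0 when the supports are
    disjoint.  ``overlap_pre`` is exactly ``overlap_post / E``.
    """
    l1, r1 = _half_max_support(profile.positions, profile.cyto)
    l2, r2 = _half_max_support(profile.positions, profile.presyn)
    post = max(0.0, min(r1, r2) - max(l1, l2))
    return post / expansion_factor, post


def calibrate_thresholds(side_profiles: list[IntensityProfile],
                         face_profiles: list[IntensityProfile],
                         expansion_factor: float) -> CalibrationResult:
    """Derive classifier thresholds from marker-confirmed synapse profiles.

    The threshold for each orientation is the minimum overlap across its
    calibration set — the floor of overlaps seen at real synapses.  A
    confirmed synapse with zero overlap invalidates the premise and raises.
    """
    if not side_profiles or not face_profiles:
        raise ValueError("need at least one profile per orientation")
    side = [compute_overlap(p, expansion_factor)[0] for p in side_profiles]
    face = [compute_overlap(p, expansion_factor)[0] for p in face_profiles]
    if min(side) <= 0 or min(face) <= 0:
        raise ValueError("a confirmed synapse shows zero overlap; "
                         "calibration set is inconsistent with the method")
    return CalibrationResult(theta_side=min(side), theta_face=min(face),
                             n_side=len(side), n_face=len(face),
                             overlaps={"side": side, "face": face})


def classify_apposition(apposition: Apposition,
                        calibration: CalibrationResult,
                        expansion_factor: float) -> OverlapResult:
    """Call an apposition a synapse iff its overlap strictly exceeds the
    calibrated threshold for its orientation."""
    if apposition.profile is None:
        raise ValueError("profile must be extracted first")
    pre, post = compute_overlap(apposition.profile, expansion_factor)
    theta = (calibration.theta_side if apposition.orientation == "side_on"
             else calibration.theta_face)
    return OverlapResult(overlap_post=post, overlap_pre=pre,
                         is_synapse=pre > theta, threshold_used=theta,
                         orientation=apposition.orientation)


# ---------------------------------------------------------------------------
# density

def assign_segments(arc_positions_pre, segment_length: float) -> np.ndarray:
    """Map arc-length positions (um pre-expansion) to segment indices.

    Positions exactly on a boundary are assigned to the lower segment.
    """
    arc = np.asarray(arc_positions_pre, dtype=float)
    idx = np.floor(arc / segment_length).astype(int)
    on_boundary = (np.mod(arc, segment_length) == 0) & (arc > 0)
    idx[on_boundary] -= 1
    return idx


def compute_density(synapse_counts_per_segment=None, *, zone: str,
                    segment_length: float | None = None,
                    n_segments: int | None = None,
                    n_contacted: int | None = None,
                    n_contacts_total: int | None = None,
                    denominator_mode: str = "contacted_only",
                    expansion_factor: float | None = None) -> DensityReport:
    """Build a density report either from per-segment synapse counts or
    directly from printed totals.

    ``segment_length`` defaults to 60 um for the proximal zone and 15 um
    for the distal dendron.
    """
    if segment_length is None:
        segment_length = {"proximal": 60.0, "distal": 15.0}[zone]
    if synapse_counts_per_segment is not None:
        counts = np.asarray(synapse_counts_per_segment, dtype=int)
        if counts.size == 0:
            raise ValueError("need at least one segment")
        n_segments = int(counts.size)
        n_contacted = int((counts > 0).sum())
        n_contacts_total = int(counts.sum())
    if n_segments is None or n_contacted is None or n_contacts_total is None:
        raise ValueError("provide per-segment counts or all three totals")
    return DensityReport(zone=zone, segment_length=segment_length,
                         n_segments=n_segments, n_contacted=n_contacted,
                         n_contacts_total=n_contacts_total,
                         denominator_mode=denominator_mode,
                         expansion_factor=expansion_factor)


# ---------------------------------------------------------------------------
# pipeline

def quantify_volume(volume, centerline, calibration: CalibrationResult,
                    zone: str = "distal", dendrite_radius: float = 0.4,
                    min_diameter: float = 0.4, gap_tol: float = 0.2,
                    segment_length: float | None = None,
                    denominator_mode: str = "contacted_only",
                    half_window: float = 3.0
                    ) -> tuple[DensityReport, list[dict]]:
    """Full pipeline: detect, appose, orient, scan, classify, densify.

    Returns the density report and one record per retained apposition
    (segment, arc position, orientation, overlap, call).
    """
    E = volume.expansion_factor
    if segment_length is None:
        segment_length = {"proximal": 60.0, "distal": 15.0}[zone]
    puncta = detect_puncta(volume, min_diameter=min_diameter)
    apps = find_appositions(puncta, centerline, dendrite_radius, E,
                            gap_tol=gap_tol)
    rows: list[dict] = []
    arc_total = float(np.sum(np.linalg.norm(np.diff(centerline, axis=0),
                                            axis=1))) / E
    n_segments = max(1, int(round(arc_total / segment_length)))
    counts = np.zeros(n_segments, dtype=int)
    for app in apps:
        choose_orientation(app, volume)
        app.profile = extract_profile(app, volume, half_window=half_window)
        res = classify_apposition(app, calibration, E)
        seg = int(assign_segments([app.dendrite_point], segment_length)[0])
        seg = min(seg, n_segments - 1)
        if res.is_synapse:
            counts[seg] += 1
        rows.append({
            "segment_id": seg,
            "arc_length_um": app.dendrite_point,
            "orientation": app.orientation,
            "membrane_gap_um": app.membrane_gap,
            "overlap_pre_um": res.overlap_pre,
            "overlap_post_um": res.overlap_post,
            "is_synapse": bool(res.is_synapse),
            "centroid_um_post": [float(v) for v in app.punctum.centroid],
            "diameter_um_pre": app.punctum.diameter,
        })
    report = compute_density(counts, zone=zone, segment_length=segment_length,
                             denominator_mode=denominator_mode,
                             expansion_factor=E)
    return report, rows
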