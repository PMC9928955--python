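"""3D synaptic puncta detection, juxtaposition pairing and density statistics.

The quantification mirrors a standard confocal colocalization workflow:
nuclei/vasculature are segmented from an occluder channel and excluded from
the analyzed ("neuropil") volume; pre- and postsynaptic puncta are detected
as scale-matched Laplacian-of-Gaussian blobs at the expected marker diameter
(0.5 µm presynaptic, 0.3 µm postsynaptic); a presynaptic punctum within
0.5 µm of a postsynaptic punctum counts as an anatomical synapse; density is
synapses per µm³ of neuropil. All distances are computed in physical µm so
anisotropic voxels (e.g. 0.1 µm xy, 0.2 µm z) are handled transparently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import ball

#: Expected puncta diameters in µm (presynaptic marker, postsynaptic marker).
PRE_DIAMETER_UM = 0.5
POST_DIAMETER_UM = 0.3

#: Physiological sanity band for punctum diameters, µm.
DIAMETER_BAND_UM = (0.25, 0.8)

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class DegenerateInputError(ValueError):
    pass


@dataclass
class ImageStack:
    """Two-channel (plus optional occluder) 3D stack with voxel size in µm."""

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]  # (z, y, x) µm
    animal_id: str = ""
    layer: str = ""
    marker_pair: str = ""
    group: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class PunctaSet:
    """Detected puncta: centroids in physical µm plus peak intensities."""

    centroids: np.ndarray  # (n, 3) in µm, (z, y, x)
    diameter: float  # expected diameter, µm
    intensities: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, float).reshape(-1, 3)
        lo, hi = DIAMETER_BAND_UM
        if not lo <= self.diameter <= hi:
            raise ValueError(
                f"diameter {self.diameter} µm outside sanity band [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class SynapseDensityRecord:
    """Per-image synapse counts, neuropil volume and density."""

    n_pre: int
    n_post: int
    n_synapses: int
    neuropil_volume: float  # µm³
    density: float  # synapses / µm³
    animal_id: str = ""
    layer: str = ""
    marker_pair: str = ""
    group: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        if self.n_synapses > min(self.n_pre, self.n_post):
            raise ValueError("n_synapses cannot exceed min(n_pre, n_post)")


def _sigma_voxels(sigma_um: float, voxel_size) -> np.ndarray:
    return sigma_um / np.asarray(voxel_size, float)


def estimate_neuropil(
    stack: ImageStack,
    method: str = "field",
    smooth_um: float = 0.2,
    occluder_threshold: float | None = None,
    closing_radius_um: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exclusion mask, neuropil mask and neuropil volume (µm³).

    The occluder channel (nuclei + vasculature) is Gaussian-smoothed,
    thresholded (Otsu when no threshold given) and morphologically closed to
    form the exclusion mask. The neuropil is the imaged field minus the
    exclusion mask ("field" method, the default, appropriate when the
    postsynaptic stain tiles the field); the "surface" method instead builds
    the neuropil from the smoothed, thresholded post-masked postsynaptic
    channel.
    """
    post = stack.channels.get("post")
    if post is None or not np.any(post):
        raise DegenerateInputError("postsynaptic channel missing or all-zero")
    shape = stack.shape
    occ = stack.channels.get("occluder")
    if occ is None or not np.any(occ):
        exclusion = np.zeros(shape, dtype=bool)
    else:
        sig = _sigma_voxels(smooth_um, stack.voxel_size)
        sm = ndimage.gaussian_filter(occ.astype(float), sigma=sig)
        thr = occluder_threshold if occluder_threshold is not None else threshold_otsu(sm)
        exclusion = sm > thr
        r_vox = max(1, int(round(closing_radius_um / min(stack.voxel_size))))
        # pad so closing does not erode objects touching the stack border
        padded = np.pad(exclusion, r_vox, mode="edge")
        closed = ndimage.binary_closing(padded, structure=ball(r_vox))
        exclusion = closed[(slice(r_vox, -r_vox),) * 3]
        exclusion = ndimage.binary_fill_holes(exclusion)
    if method == "field":
        neuropil = ~exclusion
    elif method == "surface":
        sig = _sigma_voxels(max(smooth_um, 0.3), stack.voxel_size)
        masked = np.where(exclusion, 0.0, post.astype(float))
        sm = ndimage.gaussian_filter(masked, sigma=sig)
        thr = threshold_otsu(sm) if sm.max() > 0 else 0.0
        neuropil = ndimage.binary_fill_holes(sm > thr) & ~exclusion
    else:
        raise ValueError(f"unknown neuropil method {method!r}")
    volume = float(neuropil.sum()) * stack.voxel_volume
    return exclusion, neuropil, volume


def _refine_subvoxel(response: np.ndarray, peak: np.ndarray) -> np.ndarray:
    """Quadratic (parabolic) sub-voxel refinement of a local maximum per axis."""
    offset = np.zeros(3)
    for ax in range(3):
        i = peak[ax]
        if i == 0 or i == response.shape[ax] - 1:
            continue
        idx = list(peak)
        idx[ax] = i - 1
        f_m = response[tuple(idx)]
        idx[ax] = i + 1
        f_p = response[tuple(idx)]
        f_0 = response[tuple(peak)]
        denom = f_m - 2 * f_0 + f_p
        if denom < 0:
            offset[ax] = 0.5 * (f_m - f_p) / denom
    return peak + np.clip(offset, -0.5, 0.5)


def detect_spots(
    channel: np.ndarray,
    expected_diameter: float,
    voxel_size: tuple[float, float, float],
    threshold: float | None = None,
    neuropil_mask: np.ndarray | None = None,
) -> PunctaSet:
    """Scale-matched 3D LoG blob detection at the expected punctum diameter.

    The channel is filtered with a negated Laplacian-of-Gaussian at
    sigma = diameter / (2 sqrt(2 ln 2)) per axis (in voxels); local maxima of
    the response above ``threshold`` (Otsu of the response when None, the
    automatic surrogate for a per-animal manual threshold) become puncta.
    Centroids are refined to sub-voxel precision by a parabolic fit and
    returned in physical µm; spots outside ``neuropil_mask`` are discarded.
    """
    if expected_diameter <= 0:
        raise ValueError("expected_diameter must be positive")
    channel = np.asarray(channel, float)
    if not np.any(channel):
        return PunctaSet(centroids=np.empty((0, 3)), diameter=float(expected_diameter))
    sigma_um = expected_diameter / FWHM_FACTOR
    sig_vox = _sigma_voxels(sigma_um, voxel_size)
    # scale-normalized response: sigma^2 * (-LoG)
    response = -ndimage.gaussian_laplace(channel, sigma=sig_vox) * float(np.mean(sig_vox) ** 2)
    if threshold is None:
        # Otsu separates blob responses from background; the MAD-based floor
        # guards the blob-free case where Otsu would bisect pure noise. MAD is
        # used (not SD) so sparse bright blobs cannot inflate the noise scale,
        # and the multiplier is generous because LoG-filtered Poisson noise is
        # heavy-tailed.
        med = float(np.median(response))
        sigma_mad = 1.4826 * float(np.median(np.abs(response - med)))
        threshold = float(max(threshold_otsu(response), med + 10.0 * sigma_mad))
    # non-maximum suppression within roughly one punctum radius
    size = np.maximum(3, (2 * np.ceil(sig_vox) + 1).astype(int))
    local_max = ndimage.maximum_filter(response, size=tuple(size)) == response
    peaks = np.argwhere(local_max & (response > threshold))
    centroids, intensities = [], []
    for peak in peaks:
        if neuropil_mask is not None and not neuropil_mask[tuple(peak)]:
            continue
        refined = _refine_subvoxel(response, peak)
        centroids.append(refined * np.asarray(voxel_size))
        intensities.append(channel[tuple(peak)])
    return PunctaSet(
        centroids=np.asarray(centroids).reshape(-1, 3),
        diameter=float(expected_diameter),
        intensities=np.asarray(intensities),
    )


def pair_synapses(
    pre: PunctaSet,
    post: PunctaSet,
    max_dist: float = 0.5,
    neuropil_volume: float | None = None,
    one_to_one: bool = True,
    **meta,
) -> tuple[list[tuple[int, int, float]], SynapseDensityRecord]:
    """Juxtaposition pairing: pre/post centroid pairs within ``max_dist`` µm.

    Candidate pairs are accepted greedily in ascending distance order with
    each punctum used at most once (one-to-one), preventing double counting;
    ``one_to_one=False`` instead counts every presynaptic punctum with at
    least one postsynaptic punctum in range. Returns the accepted
    (pre_index, post_index, distance) list and a
    :class:`SynapseDensityRecord`; density needs a positive
    ``neuropil_volume``.
    """
    pairs: list[tuple[int, int, float]] = []
    if len(pre) and len(post):
        tree = cKDTree(post.centroids)
        if one_to_one:
            cand: list[tuple[float, int, int]] = []
            for i, c in enumerate(pre.centroids):
                for j in tree.query_ball_point(c, r=max_dist):
                    cand.append((float(np.linalg.norm(c - post.centroids[j])), i, j))
            cand.sort()
            used_pre: set[int] = set()
            used_post: set[int] = set()
            for d, i, j in cand:
                if i in used_pre or j in used_post:
                    continue
                used_pre.add(i)
                used_post.add(j)
                pairs.append((i, j, d))
        else:
            for i, c in enumerate(pre.centroids):
                hits = tree.query_ball_point(c, r=max_dist)
                if hits:
                    j = min(hits, key=lambda j: np.linalg.norm(c - post.centroids[j]))
                    pairs.append((i, j, float(np.linalg.norm(c - post.centroids[j]))))
    n_syn = len(pairs)
    if neuropil_volume is not None:
        if neuropil_volume <= 0:
            raise ZeroDivisionError("neuropil volume must be positive for density")
        density = n_syn / neuropil_volume
        volume = neuropil_volume
    else:
        density, volume = 0.0, 0.0
    record = SynapseDensityRecord(
        n_pre=len(pre), n_post=len(post), n_synapses=n_syn,
        neuropil_volume=volume, density=density, **meta)
    return pairs, record


@dataclass
class GroupComparison:
    """Two-sided two-sample t-test result with descriptives."""

    t: float
    df: float
    p_value: float
    welch: bool
    descriptives: pd.DataFrame


def compare_groups(
    records,
    metric: str = "density",
    welch: str = "auto",
    outlier_rule: str = "iqr",
) -> GroupComparison:
    """Compare PME vs PSE on a density metric with a two-sample t-test.

    Welch's correction is applied when Levene's test rejects variance
    equality at 0.05 (``welch="auto"``), or always/never with
    ``"always"``/``"never"``. Descriptives include per-observation outlier
    flags: by default any point beyond the interquartile range [Q1, Q3] is
    flagged (the box-plot annotation convention); ``outlier_rule="tukey"``
    uses the 1.5×IQR fences instead.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([{
            "group": r.group, "value": getattr(r, metric), "animal_id": r.animal_id,
        } for r in records])
        metric = "value"
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    # PME first so positive t means PME > PSE
    if "PME" in groups:
        groups = ["PME", [g for g in groups if g != "PME"][0]]
    a = df.loc[df["group"] == groups[0], metric].to_numpy(float)
    b = df.loc[df["group"] == groups[1], metric].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 records")
    if welch == "auto":
        use_welch = stats.levene(a, b).pvalue < 0.05
    elif welch in ("always", "never"):
        use_welch = welch == "always"
    else:
        raise ValueError(f"welch must be auto/always/never, got {welch!r}")
    res = stats.ttest_ind(a, b, equal_var=not use_welch)
    rows = []
    for g, vals in ((groups[0], a), (groups[1], b)):
        q1, q3 = np.percentile(vals, [25, 75])
        if outlier_rule == "iqr":
            lo, hi = q1, q3
        elif outlier_rule == "tukey":
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        else:
            raise ValueError(f"unknown outlier rule {outlier_rule!r}")
        for v in vals:
            rows.append({"group": g, "value": float(v), "q1": q1, "q3": q3,
                         "outlier": bool(v < lo or v > hi)})
    return GroupComparison(t=float(res.statistic), df=float(res.df),
                           p_value=float(res.pvalue), welch=use_welch,
                           descriptives=pd.DataFrame(rows))
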