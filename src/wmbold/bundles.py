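"""GM-WM-GM fiber-bundle units.

A bundle unit is a structural triplet: two gray-matter parcels plus the
white-matter streamline bundle connecting them.  Streamlines are grouped
by their connected parcel pair, bundles below a minimum voxel count are
excluded, and each retained bundle is classified as *association*
(cortex-to-cortex) or *projection* (one endpoint in a pseudo-GM parcel:
cerebellar cortex or cervical spinal cord).  The module also measures
bundle morphology (volume, mean streamline length, deviation from the
superior-inferior axis), voxel-mask overlap (Dice), and bundle-wise means
of voxel-wise scalar maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Parcellation",
    "Bundle",
    "BundleSet",
    "assign_streamline",
    "build_bundle_set",
    "morphology",
    "dice",
    "sample_map",
    "load_streamlines",
    "save_streamlines",
]

#: default nearest-label search radius (mm) for endpoints that fall on
#: background or WM voxels
DEFAULT_SEARCH_RADIUS_MM = 2.0
#: default bundle retention threshold: 500 voxels = 4000 mm^3 at 2 mm
DEFAULT_MIN_VOXELS = 500


@dataclass
class Parcellation:
    """Integer label volume with a voxel-to-world affine.

    Label 0 is background.  ``pseudo_gm_labels`` mark parcels standing in
    for cerebellar cortex / cervical spinal cord; a bundle touching
    exactly one of them is a projection bundle.  ``wm_label``, when set,
    marks an interior white-matter region that is *not* a parcel.
    """

    labels: np.ndarray
    affine: np.ndarray
    pseudo_gm_labels: frozenset[int] = frozenset()
    wm_label: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        self.pseudo_gm_labels = frozenset(int(v) for v in self.pseudo_gm_labels)
        present = set(np.unique(self.labels).tolist())
        if not self.pseudo_gm_labels <= present:
            raise ValueError("pseudo_gm_labels not all present in the volume")

    @property
    def parcel_labels(self) -> frozenset[int]:
        """All parcel labels (background and WM excluded)."""
        vals = set(int(v) for v in np.unique(self.labels)) - {0}
        if self.wm_label is not None:
            vals -= {int(self.wm_label)}
        return frozenset(vals)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index of world coordinates (may be out of bounds)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
        return np.rint(ijk).astype(int)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), str(path))

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        pseudo_gm_labels: Iterable[int] = (),
        wm_label: int | None = None,
    ) -> "Parcellation":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(
            np.asarray(img.dataobj).astype(int),
            img.affine,
            frozenset(pseudo_gm_labels),
            wm_label,
        )


@dataclass
class Bundle:
    """One GM-WM-GM unit."""

    bundle_id: int
    parcel_pair: frozenset[int]
    streamline_ids: tuple[int, ...]
    voxel_mask: np.ndarray  # (n, 3) int voxel indices, unique rows
    kind: str  # "association" or "projection"
    volume_mm3: float = 0.0
    mean_length_mm: float = 0.0
    si_angle_deg: float = 0.0

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_mask.shape[0])

    def mask_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        vol = np.zeros(shape, dtype=bool)
        if self.n_voxels:
            i, j, k = self.voxel_mask.T
            vol[i, j, k] = True
        return vol


@dataclass
class BundleSet:
    bundles: list[Bundle]
    voxel_size_mm: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bundles)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for b in self.bundles:
            pa, pb = sorted(b.parcel_pair)
            rows.append(
                dict(
                    bundle_id=b.bundle_id,
                    parcel_a=pa,
                    parcel_b=pb,
                    kind=b.kind,
                    n_voxels=b.n_voxels,
                    volume_mm3=b.volume_mm3,
                    mean_length_mm=b.mean_length_mm,
                    si_angle_deg=b.si_angle_deg,
                )
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _classify(pair: frozenset[int], pseudo: frozenset[int]) -> str:
    """Association iff neither parcel is pseudo-GM, projection otherwise."""
    return "projection" if pair & pseudo else "association"


def _nearest_parcel(
    point_mm: np.ndarray,
    parc: Parcellation,
    radius_mm: float,
) -> int | None:
    """Closest parcel label within ``radius_mm`` of a world point.

    Ties on distance are broken by the lowest label id.
    """
    vs = parc.voxel_size_mm
    center = parc.world_to_voxel(point_mm)[0]
    reach = np.maximum(np.ceil(radius_mm / vs).astype(int) + 1, 1)
    shape = parc.labels.shape
    lo = np.maximum(center - reach, 0)
    hi = np.minimum(center + reach + 1, shape)
    if np.any(lo >= hi):
        return None
    parcels = parc.parcel_labels
    best: tuple[float, int] | None = None
    sub = parc.labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    idx = np.argwhere(sub != 0)
    for off in idx:
        ijk = lo + off
        lab = int(parc.labels[tuple(ijk)])
        if lab not in parcels:
            continue
        d = float(np.linalg.norm(parc.voxel_to_world(ijk)[0] - point_mm))
        if d <= radius_mm and (best is None or (d, lab) < best):
            best = (d, lab)
    return None if best is None else best[1]


def assign_streamline(
    streamline: np.ndarray,
    parc: Parcellation,
    search_radius_mm: float = DEFAULT_SEARCH_RADIUS_MM,
) -> frozenset[int] | None:
    """Unordered GM parcel pair connected by a streamline, or None.

    Each endpoint is mapped to the parcel label at its voxel; endpoints
    on background/WM are reassigned to the nearest parcel voxel within
    ``search_radius_mm`` (ties broken by lowest label).  Returns None if
    either endpoint stays unassigned or both endpoints hit the same
    parcel (self-loops are excluded).
    """
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("streamline must be an (n>=2, 3) point sequence")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    parcels = parc.parcel_labels
    labels = []
    shape = parc.labels.shape
    for endpoint in (pts[0], pts[-1]):
        ijk = parc.world_to_voxel(endpoint)[0]
        lab: int | None = None
        if np.all(ijk >= 0) and np.all(ijk < shape):
            v = int(parc.labels[tuple(ijk)])
            if v in parcels:
                lab = v
        if lab is None:
            lab = _nearest_parcel(endpoint, parc, search_radius_mm)
        if lab is None:
            return None
        labels.append(lab)
    if labels[0] == labels[1]:
        return None
    return frozenset(labels)


def _rasterize(
    streamline: np.ndarray, parc: Parcellation, step_frac: float = 0.25
) -> np.ndarray:
    """Voxels traversed by a polyline, by dense sampling of each segment.

    Sampling step is ``step_frac`` of the smallest voxel dimension, small
    enough that no traversed voxel of practical size is skipped.
    """
    pts = np.asarray(streamline, dtype=float)
    step = float(parc.voxel_size_mm.min()) * step_frac
    samples = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        samples.append(a + t[:, None] * (b - a))
    all_pts = np.vstack([np.atleast_2d(s) for s in samples])
    ijk = parc.world_to_voxel(all_pts)
    shape = np.asarray(parc.labels.shape)
    keep = np.all((ijk >= 0) & (ijk < shape), axis=1)
    return np.unique(ijk[keep], axis=0)


def build_bundle_set(
    streamlines: Sequence[np.ndarray],
    parc: Parcellation,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    search_radius_mm: float = DEFAULT_SEARCH_RADIUS_MM,
) -> BundleSet:
    """Group streamlines into GM-WM-GM bundles and filter small ones.

    The voxel mask of a bundle is the union of voxels traversed by any
    member streamline (segment rasterization, not just vertices).
    Bundles with fewer than ``min_voxels`` voxels are dropped — the
    default reproduces the 500-voxel (4000 mm^3 at 2 mm) exclusion rule.
    """
    if len(streamlines) == 0:
        raise ValueError("need at least one streamline")
    groups: dict[frozenset[int], list[int]] = {}
    for sid, sl in enumerate(streamlines):
        pair = assign_streamline(sl, parc, search_radius_mm)
        if pair is not None:
            groups.setdefault(pair, []).append(sid)
    voxel_vol = float(np.prod(parc.voxel_size_mm))
    bundles: list[Bundle] = []
    for pair in sorted(groups, key=lambda p: tuple(sorted(p))):
        sids = groups[pair]
        masks = [_rasterize(streamlines[s], parc) for s in sids]
        mask = np.unique(np.vstack(masks), axis=0)
        if mask.shape[0] < min_voxels:
            continue
        b = Bundle(
            bundle_id=len(bundles),
            parcel_pair=pair,
            streamline_ids=tuple(sids),
            voxel_mask=mask,
            kind=_classify(pair, parc.pseudo_gm_labels),
            volume_mm3=mask.shape[0] * voxel_vol,
        )
        b.volume_mm3, b.mean_length_mm, b.si_angle_deg = morphology(
            b, [streamlines[s] for s in sids], voxel_vol
        )
        bundles.append(b)
    if not bundles:
        logger.warning("no bundles retained after the %d-voxel filter", min_voxels)
    return BundleSet(
        bundles,
        voxel_size_mm=float(parc.voxel_size_mm[0]),
        provenance=dict(min_voxels=min_voxels, search_radius_mm=search_radius_mm),
    )


def morphology(
    bundle: Bundle,
    streamlines: Sequence[np.ndarray],
    voxel_vol_mm3: float = 8.0,
) -> tuple[float, float, float]:
    """Volume (mm^3), mean streamline arc length (mm) and S-I angle (deg).

    The orientation is the angle between the first principal axis of all
    pooled streamline points and the superior-inferior unit vector (third
    world axis), folded into [0, 90].
    """
    if bundle.n_voxels == 0 or len(streamlines) == 0:
        raise ValueError("bundle is empty")
    lengths = []
    pooled = []
    for sl in streamlines:
        pts = np.asarray(sl, dtype=float)
        if pts.shape[0] < 2:
            logger.warning("single-point streamline excluded from length")
            continue
        lengths.append(float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()))
        pooled.append(pts)
    volume = bundle.n_voxels * voxel_vol_mm3
    if not pooled:
        return volume, 0.0, 0.0
    pts = np.vstack(pooled)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    cos = abs(axis[2]) / np.linalg.norm(axis)
    angle = float(np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))
    return volume, float(np.mean(lengths)), angle


def dice(bundle_a: Bundle, bundle_b: Bundle) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two bundle voxel masks."""
    na, nb = bundle_a.n_voxels, bundle_b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    sa = {tuple(v) for v in bundle_a.voxel_mask}
    sb = {tuple(v) for v in bundle_b.voxel_mask}
    return 2.0 * len(sa & sb) / (na + nb)


def sample_map(bundle: Bundle, scalar_map: np.ndarray) -> float:
    """Bundle-wise mean of a voxel-wise scalar map.

    Non-finite voxels are ignored (their count is logged); an error is
    raised when every voxel in the mask is non-finite.
    """
    scalar_map = np.asarray(scalar_map, dtype=float)
    i, j, k = bundle.voxel_mask.T
    vals = scalar_map[i, j, k]
    finite = np.isfinite(vals)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.info(
            "bundle %d: ignoring %d non-finite voxels of %d",
            bundle.bundle_id, n_bad, vals.size,
        )
    if not finite.any():
        raise ValueError("all voxels in the bundle mask are non-finite")
    return float(vals[finite].mean())


def save_streamlines(
    streamlines: Sequence[np.ndarray], path: str | Path
) -> None:
    """Write streamlines (world/mm coordinates) to a TCK or TRK file."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram

    tg = Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tg, str(path))


def load_streamlines(path: str | Path) -> list[np.ndarray]:
    """Read streamlines from TCK/TRK into world/mm point arrays."""
    import nibabel as nib

    tf = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
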