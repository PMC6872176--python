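"""Digital head phantoms with tissue structure and reference ROIs.

The phantom stands in for a segmented, template-normalized anatomy: an
ellipsoidal brain with a white-matter core, ventricle-like CSF pockets,
and a grey-matter shell whose partial-volume probability tapers from the
mid-shell outwards.  One compact reference ROI per contrast is placed
inside the grey-matter band; these play the role of the ground-truth
activation regions that detection performance is scored against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Phantom", "PlacementError", "generate_phantom"]


class PlacementError(ValueError):
    """The grid is too small to place all requested ROIs disjointly."""


@dataclass
class Phantom:
    """Tissue probability maps, baseline intensity and reference ROIs.

    Tissue probabilities are per-voxel in [0, 1] and sum to at most 1
    (the remainder is unmodelled tissue).  Each ROI mask lies inside the
    grey-matter band (GM probability >= 0.05) and ROIs are pairwise
    disjoint.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    baseline: np.ndarray
    rois: dict[str, np.ndarray]
    voxel_size_mm: float

    def __post_init__(self) -> None:
        total = self.gm + self.wm + self.csf
        if total.max() > 1.0 + 1e-9:
            raise ValueError("tissue probabilities exceed 1 somewhere")
        for name, roi in self.rois.items():
            if not roi.any():
                raise ValueError(f"ROI {name!r} is empty")
            if (self.gm[roi] < 0.05).any():
                raise ValueError(f"ROI {name!r} leaves the grey-matter band")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gm.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.baseline > 0

    def tissue_mask(self, tissue: str, threshold: float = 1.0) -> np.ndarray:
        """Binary mask of voxels whose *tissue* probability >= threshold.

        With the default threshold of 1 this selects pure-tissue voxels,
        the way noise-ROI masks for component-based nuisance extraction
        are usually defined.
        """
        maps = {"gm": self.gm, "wm": self.wm, "csf": self.csf}
        return maps[tissue] >= threshold


def _radius_grid(shape: tuple[int, int, int]) -> np.ndarray:
    """Normalized ellipsoidal radius: 0 at centre, 1 at the brain edge."""
    axes = [np.arange(n) - (n - 1) / 2.0 for n in shape]
    semi = [0.46 * n for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(
        (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2
    )


def generate_phantom(
    grid: tuple[int, int, int],
    voxel_size_mm: float,
    contrast_names: list[str],
    seed: int = 0,
    *,
    roi_radius_vox: float | None = None,
    baseline_value: float = 100.0,
) -> Phantom:
    """Build a deterministic phantom with one ROI per contrast.

    The white-matter core (r < 0.5) has probability exactly 1 outside two
    CSF pockets (probability 1) so that pure-tissue noise masks exist.
    The grey-matter shell spans 0.55 <= r <= 0.95 with probability peaking
    at 1 mid-shell and tapering to ~0.3 at its edges, giving the partial
    volume gradient that modulates activation amplitude in simulation.
    ROIs are balls centred mid-shell along well-separated directions,
    jittered by the seed.
    """
    grid = tuple(int(g) for g in grid)
    if min(grid) < 8:
        raise ValueError("grid must be at least 8 voxels per axis")
    if len(contrast_names) == 0:
        raise ValueError("at least one contrast name required")
    if len(set(contrast_names)) != len(contrast_names):
        raise ValueError("duplicate contrast names")

    rng = np.random.default_rng(seed)
    r = _radius_grid(grid)
    brain = r <= 1.0

    wm = np.zeros(grid)
    gm = np.zeros(grid)
    csf = np.zeros(grid)

    core = r < 0.5
    trans = (r >= 0.5) & (r < 0.55)
    shell = (r >= 0.55) & (r <= 0.95)
    rim = (r > 0.95) & brain

    wm[core] = 1.0
    wm[trans] = (0.55 - r[trans]) / 0.05
    gm[trans] = 1.0 - wm[trans]
    # mid-shell peak at r = 0.75, tapering to 0.3 at the shell edges
    gm[shell] = 0.3 + 0.7 * (1.0 - np.abs(r[shell] - 0.75) / 0.20)
    gm[rim] = 0.3 * (1.0 - r[rim]) / 0.05

    # two ventricle-like CSF pockets, mirrored about the mid-sagittal plane
    centre = np.array([(n - 1) / 2.0 for n in grid])
    pocket_r = max(1.5, 0.08 * min(grid))
    offsets = np.array([[0.12, 0.0, 0.0], [-0.12, 0.0, 0.0]]) * min(grid)
    idx = np.indices(grid).reshape(3, -1).T
    for off in offsets:
        d = np.linalg.norm(idx - (centre + off), axis=1).reshape(grid)
        pocket = d <= pocket_r
        csf[pocket] = 1.0
        wm[pocket] = 0.0
        gm[pocket] = 0.0

    baseline = np.where(brain, float(baseline_value), 0.0)

    if roi_radius_vox is None:
        roi_radius_vox = max(2.0, 0.11 * min(grid))

    # place ROI centres mid-shell along evenly spread directions + jitter
    n_roi = len(contrast_names)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    rois: dict[str, np.ndarray] = {}
    semi = np.array([0.46 * n for n in grid])
    claimed = np.zeros(grid, dtype=bool)
    for i, name in enumerate(contrast_names):
        z = 1.0 - 2.0 * (i + 0.5) / n_roi
        theta = golden * i + rng.uniform(-0.1, 0.1)
        rho = np.sqrt(max(0.0, 1.0 - z * z))
        direction = np.array([rho * np.cos(theta), rho * np.sin(theta), z])
        centre_i = centre + 0.75 * semi * direction
        d = np.linalg.norm(idx - centre_i, axis=1).reshape(grid)
        roi = (d <= roi_radius_vox) & (gm >= 0.05)
        if not roi.any():
            raise PlacementError(
                f"grid {grid} too small to place ROI for {name!r}"
            )
        if (roi & claimed).any():
            raise PlacementError(
                f"ROI for {name!r} overlaps a previous ROI; enlarge the grid"
            )
        claimed |= roi
        rois[name] = roi

    return Phantom(
        gm=gm, wm=wm, csf=csf, baseline=baseline, rois=rois,
        voxel_size_mm=float(voxel_size_mm),
    )
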