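"""Ellipsoidal left-ventricle phantoms for testing the voxel-wise ECV pipeline.

Real volume pairs come from registered baseline and late-enhancement cardiac
CT scans with externally segmented myocardium and blood-pool masks.  This
module builds a simple stand-in: two concentric ellipsoids on an isotropic
grid.  The inner ellipsoid is the blood pool, the shell between the two is
the LV myocardium.  Given a target per-voxel ECV field, the late-enhancement
volume is constructed by *inverting* the ECV relation

    ECV = (1 - Hct) * dHU_myo / dHU_blood
    =>  dHU_myo(v) = ECV(v) * dHU_blood / (1 - Hct)

so that, with zero added noise, the forward ECV pipeline recovers the field
(up to floating-point rounding).  Measurement noise is emulated as i.i.d.
Gaussian HU noise added independently to the baseline and late volumes.

No CT physics (beam hardening, kV dependence, contrast kinetics) and no
registration error are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import DomainError, ValidationError

__all__ = ["VolumePair", "ellipsoid_masks", "generate_volume_pair"]

#: default HU of the background / myocardium / blood on the baseline scan
_BG_HU, _MYO_HU, _BLOOD_HU = 0.0, 40.0, 50.0


@dataclass
class VolumePair:
    """Registered baseline / late-enhancement HU volumes with binary masks.

    All four arrays share one grid; ``lv_mask`` (myocardial shell) and
    ``bp_mask`` (blood pool) are disjoint; the blood pool is non-empty.
    """

    baseline_hu: np.ndarray
    lie_hu: np.ndarray
    lv_mask: np.ndarray
    bp_mask: np.ndarray
    voxel_spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.baseline_hu, self.lie_hu, self.lv_mask, self.bp_mask)}
        if len(shapes) != 1:
            raise ValidationError(f"volumes and masks must share one grid shape, got {shapes}")
        self.lv_mask = self.lv_mask.astype(bool)
        self.bp_mask = self.bp_mask.astype(bool)
        if np.any(self.lv_mask & self.bp_mask):
            raise ValidationError("lv_mask and bp_mask must be disjoint")
        if not self.bp_mask.any():
            raise ValidationError("bp_mask is empty")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError(f"voxel_spacing must be three positive floats, got {self.voxel_spacing}")

    @property
    def delta_hu(self) -> np.ndarray:
        """Late minus baseline attenuation, voxel-wise."""
        return self.lie_hu - self.baseline_hu


def ellipsoid_masks(shape=(64, 64, 64)):
    """Concentric-ellipsoid LV phantom masks.

    Outer semi-axes are 0.40/0.34/0.30 of the grid dimensions; the blood pool
    is the inner ellipsoid at 0.55 of the outer axes and the myocardial shell
    is the region between the two.  Returns ``(lv_mask, bp_mask)``.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 8 for s in shape):
        raise ValidationError(f"phantom grid too small: {shape}")
    centre = [(s - 1) / 2.0 for s in shape]
    semi_outer = (0.40 * shape[0], 0.34 * shape[1], 0.30 * shape[2])
    semi_inner = tuple(0.55 * a for a in semi_outer)
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    r_out = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi_outer))
    r_in = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi_inner))
    bp_mask = r_in <= 1.0
    lv_mask = (r_out <= 1.0) & ~bp_mask
    return lv_mask, bp_mask


def generate_volume_pair(
    ecv_field: np.ndarray,
    hct: float,
    dhu_blood: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    masks: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    voxel_spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> VolumePair:
    """Build a baseline/late-enhancement pair whose true ECV field is known.

    Parameters
    ----------
    ecv_field : ndarray
        3-D fractional ECV values; only the values on myocardial voxels are
        used, and those must lie in (0, 1).
    hct : float
        Serum haematocrit fraction in (0, 1) used for the inversion.
    dhu_blood : float
        True blood-pool attenuation change in HU (> 0), applied uniformly to
        the blood pool.
    noise_sd : float
        SD of i.i.d. Gaussian HU noise added independently to both volumes
        (0 gives an exactly invertible phantom).
    masks : (lv_mask, bp_mask), optional
        Override the default :func:`ellipsoid_masks` geometry.
    """
    ecv_field = np.asarray(ecv_field, dtype=float)
    if ecv_field.ndim != 3:
        raise ValidationError(f"ecv_field must be 3-D, got {ecv_field.ndim} dims")
    if not 0.0 < hct < 1.0:
        raise DomainError(f"hct must lie in (0, 1), got {hct}")
    if not dhu_blood > 0:
        raise DomainError(f"dhu_blood must be positive, got {dhu_blood}")
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd}")

    lv_mask, bp_mask = ellipsoid_masks(ecv_field.shape) if masks is None else masks
    lv_mask = np.asarray(lv_mask, dtype=bool)
    bp_mask = np.asarray(bp_mask, dtype=bool)
    myo_vals = ecv_field[lv_mask]
    if myo_vals.size and not ((myo_vals > 0) & (myo_vals < 1)).all():
        raise DomainError("ecv_field values on the myocardial shell must lie in (0, 1)")

    baseline = np.full(ecv_field.shape, _BG_HU, dtype=float)
    baseline[lv_mask] = _MYO_HU
    baseline[bp_mask] = _BLOOD_HU
    delta = np.zeros_like(baseline)
    delta[bp_mask] = dhu_blood
    delta[lv_mask] = ecv_field[lv_mask] * dhu_blood / (1.0 - hct)
    lie = baseline + delta
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        baseline = baseline + rng.normal(0.0, noise_sd, baseline.shape)
        lie = lie + rng.normal(0.0, noise_sd, lie.shape)
    return VolumePair(
        baseline_hu=baseline,
        lie_hu=lie,
        lv_mask=lv_mask,
        bp_mask=bp_mask,
        voxel_spacing=voxel_spacing,
    )
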