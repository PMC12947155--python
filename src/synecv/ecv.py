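"""Extracellular-volume computation: scalars, voxel-wise maps, NIfTI I/O.

The extracellular volume fraction of myocardium is computed from the
attenuation change between a pre-contrast baseline scan and a late
iodine-enhanced scan:

    ECV = (1 - Hct) * dHU_myo / dHU_blood

where ``dHU_myo`` is the per-voxel myocardial attenuation change and
``dHU_blood`` the mean change over an eroded sample at the centre of the
blood pool (erosion keeps the sample clear of trabeculations and residual
registration error).  Using the measured serum haematocrit gives the
conventional ECV (conECV); substituting a model-predicted synthetic
haematocrit gives synECV.  For any voxel the two are related exactly by

    synECV / conECV = (1 - synHct) / (1 - Hct).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DomainError, EmptyMaskError, ValidationError
from .models import LinearHctModel, StratifiedHctModel
from .phantom import VolumePair

__all__ = [
    "ECVMap",
    "compute_ecv",
    "erode_mask",
    "compute_ecv_map",
    "compute_synecv",
    "compute_synecv_map",
    "save_ecv_map",
    "save_volume_pair",
    "load_volume_pair",
]


def compute_ecv(hct: float, dhu_myo, dhu_blood: float):
    """Scalar (or voxel-wise) ECV from haematocrit and attenuation changes.

    ``hct`` is a fraction in [0, 1]; ``dhu_blood`` must be nonzero.  Values
    outside [0, 1] are *returned*, not clipped — callers flag them.
    """
    if not 0.0 <= hct <= 1.0:
        raise DomainError(f"hct must lie in [0, 1], got {hct}")
    if dhu_blood == 0:
        raise DomainError("dhu_blood must be nonzero")
    out = (1.0 - hct) * np.asarray(dhu_myo, dtype=float) / dhu_blood
    return float(out) if out.ndim == 0 else out


def erode_mask(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Morphological erosion with a 6-connected (face-adjacent) element.

    ``iterations = 0`` is the identity.  Eroding to an empty mask raises
    :class:`EmptyMaskError` — reduce ``iterations`` rather than silently
    sampling nothing.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValidationError(f"mask must be 3-D, got {mask.ndim} dims")
    if iterations < 0:
        raise DomainError(f"iterations must be >= 0, got {iterations}")
    if iterations == 0:
        return mask.copy()
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, iterations=iterations)
    if not eroded.any():
        raise EmptyMaskError(
            f"erosion with {iterations} iteration(s) emptied the mask "
            f"({int(mask.sum())} voxels before)"
        )
    return eroded


@dataclass
class ECVMap:
    """Voxel-wise ECV field on the myocardial mask.

    ``ecv`` is NaN outside ``lv_mask``; ``mean_lv_ecv`` is the mean over the
    mask (all mask voxels, including flagged ones, unless the map was built
    with ``exclude_flagged``); ``n_flagged_voxels`` counts voxels whose ECV
    fell outside [0, 1].
    """

    ecv: np.ndarray
    lv_mask: np.ndarray
    mean_lv_ecv: float
    dhu_blood: float
    hct_used: float
    source: str = "conventional"  # "conventional" | "synthetic"
    erosion_iterations: int = 2
    n_flagged_voxels: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("conventional", "synthetic"):
            raise ValidationError(f"source must be 'conventional' or 'synthetic', got {self.source!r}")
        if self.dhu_blood == 0:
            raise ValidationError("dhu_blood must be nonzero")


def compute_ecv_map(
    pair: VolumePair,
    hct: float,
    erosion_iterations: int = 2,
    source: str = "conventional",
    exclude_flagged: bool = False,
) -> ECVMap:
    """Run the image pipeline: erode the blood pool, subtract the scans,
    and evaluate the ECV relation per myocardial voxel.

    ``dhu_blood`` is the mean attenuation change over the *eroded* blood
    pool; each LV voxel then gets ``(1 - hct) * dHU(v) / dhu_blood``.
    ``exclude_flagged`` drops out-of-[0, 1] voxels from the mean (they remain
    in the map either way).
    """
    if not 0.0 <= hct <= 1.0:
        raise DomainError(f"hct must lie in [0, 1], got {hct}")
    bp_core = erode_mask(pair.bp_mask, erosion_iterations)
    delta = pair.delta_hu
    dhu_blood = float(delta[bp_core].mean())
    if dhu_blood == 0:
        raise DomainError("mean blood-pool attenuation change is zero")
    ecv = np.full(delta.shape, np.nan)
    lv = pair.lv_mask
    ecv[lv] = (1.0 - hct) * delta[lv] / dhu_blood
    vals = ecv[lv]
    flagged = (vals < 0) | (vals > 1)
    mean_vals = vals[~flagged] if exclude_flagged else vals
    if mean_vals.size == 0:
        raise EmptyMaskError("no myocardial voxels available for the mean")
    return ECVMap(
        ecv=ecv,
        lv_mask=lv,
        mean_lv_ecv=float(mean_vals.mean()),
        dhu_blood=dhu_blood,
        hct_used=float(hct),
        source=source,
        erosion_iterations=int(erosion_iterations),
        n_flagged_voxels=int(flagged.sum()),
    )


def compute_synecv(
    record,
    model: Union[LinearHctModel, StratifiedHctModel],
    dhu_myo,
    dhu_blood: float,
) -> Optional[float]:
    """Synthetic ECV for one patient: predict synHct, substitute into the
    ECV relation.

    The model prediction (Hct-percent) is converted to a fraction before the
    substitution.  Under a stratified model an unroutable record (the
    combined model makes no prediction for females with BMI < 22.4) yields
    ``None``.
    """
    if isinstance(model, StratifiedHctModel):
        line = model.route(record)
        if line is None:
            return None
    else:
        line = model
    hu = record.hu_blood if hasattr(record, "hu_blood") else record["hu_blood"]
    synhct = line.predict(hu) / 100.0
    if not 0.0 <= synhct <= 1.0:
        raise DomainError(
            f"predicted synHct {synhct:.3f} outside [0, 1]; model {line.label!r} "
            f"is being applied far outside its calibration range"
        )
    return compute_ecv(synhct, dhu_myo, dhu_blood)


def compute_synecv_map(
    pair: VolumePair,
    record,
    model: Union[LinearHctModel, StratifiedHctModel],
    erosion_iterations: int = 2,
    exclude_flagged: bool = False,
) -> Optional[ECVMap]:
    """Voxel-wise synECV map; ``None`` when the record is unroutable."""
    if isinstance(model, StratifiedHctModel):
        line = model.route(record)
        if line is None:
            return None
    else:
        line = model
    hu = record.hu_blood if hasattr(record, "hu_blood") else record["hu_blood"]
    synhct = line.predict(hu) / 100.0
    return compute_ecv_map(
        pair, synhct, erosion_iterations, source="synthetic", exclude_flagged=exclude_flagged
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(voxel_spacing) -> np.ndarray:
    return np.diag([*voxel_spacing, 1.0])


def save_ecv_map(ecv_map: ECVMap, path, voxel_spacing=(2.0, 2.0, 2.0)) -> None:
    """Write the map as float32 NIfTI (NaN outside the mask) + JSON sidecar."""
    img = nib.Nifti1Image(ecv_map.ecv.astype(np.float32), _affine(voxel_spacing))
    nib.save(img, str(path))
    sidecar = {
        "hct_used": ecv_map.hct_used,
        "dhu_blood": ecv_map.dhu_blood,
        "erosion_iterations": ecv_map.erosion_iterations,
        "mean_lv_ecv": ecv_map.mean_lv_ecv,
        "n_flagged_voxels": ecv_map.n_flagged_voxels,
        "source": ecv_map.source,
    }
    with open(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def save_volume_pair(pair: VolumePair, directory) -> None:
    """Write baseline/late volumes (float32) and masks (uint8) as NIfTI-1."""
    import os

    os.makedirs(directory, exist_ok=True)
    aff = _affine(pair.voxel_spacing)
    for name, arr, dtype in (
        ("baseline", pair.baseline_hu, np.float32),
        ("lie", pair.lie_hu, np.float32),
        ("lv_mask", pair.lv_mask, np.uint8),
        ("bp_mask", pair.bp_mask, np.uint8),
    ):
        nib.save(nib.Nifti1Image(arr.astype(dtype), aff), f"{directory}/{name}.nii.gz")


def load_volume_pair(baseline_path, lie_path, lv_path, bp_path) -> VolumePair:
    imgs = [nib.load(str(p)) for p in (baseline_path, lie_path, lv_path, bp_path)]
    spacing = tuple(float(z) for z in imgs[0].header.get_zooms()[:3])
    arrays = [np.asarray(img.dataobj, dtype=float) for img in imgs]
    return VolumePair(
        baseline_hu=arrays[0],
        lie_hu=arrays[1],
        lv_mask=arrays[2] > 0.5,
        bp_mask=arrays[3] > 0.5,
        voxel_spacing=spacing,
    )
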