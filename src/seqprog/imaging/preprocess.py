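"""Volume preprocessing and training-time augmentation.

The pipeline mirrors a standard PET/CT prognosis workflow: resample
the CT to an isotropic grid, align PET and mask onto it, crop a cube
centred on the mask centroid, convert PET activity to standardized
uptake values (SUV), clip CT to [-200, 250] HU and PET to [0, 25] SUV,
and min-max map both to [0, 1].  When PET acquisition attributes are
missing, conservative imputation defaults are used: 75 kg body weight,
105 min injection delay, 420 MBq injected dose (F-18 half-life
109.77 min).

Augmentation applies, each independently with probability 1/2:
Gaussian noise (followed by a clip back to [0, 1]), an axial flip, and
a small in-plane rotation; the geometric transforms are applied
identically to CT, PET and mask and the mask stays binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["SUVParams", "preprocess", "augment", "save_nifti", "load_nifti"]

F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class SUVParams:
    """PET acquisition attributes for body-weight SUV conversion."""

    body_weight_kg: float = 75.0
    injected_dose_mbq: float = 420.0
    injection_delay_min: float = 105.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self):
        for f in (self.body_weight_kg, self.injected_dose_mbq,
                  self.injection_delay_min, self.half_life_min):
            if f <= 0:
                raise ValueError("SUV parameters must be positive")

    def factor(self) -> float:
        """Multiplier taking activity concentration (Bq/ml) to SUV.

        SUV = C * body_weight[g] / (dose[Bq] * 2^(-delay / half_life)).
        """
        dose_bq = self.injected_dose_mbq * 1e6
        decayed = dose_bq * 2.0 ** (-self.injection_delay_min / self.half_life_min)
        return self.body_weight_kg * 1e3 / decayed


def _resample(vol, spacing, target, order):
    factors = np.asarray(spacing, float) / float(target)
    if np.allclose(factors, 1.0):
        return np.asarray(vol, float).copy()
    return ndimage.zoom(np.asarray(vol, float), factors, order=order)


def _crop_cube(vol, center_vox, half):
    pads, slices = [], []
    for c, n in zip(center_vox, vol.shape):
        lo, hi = int(round(c - half)), int(round(c - half)) + 2 * half
        pads.append((max(0, -lo), max(0, hi - n)))
        slices.append(slice(max(0, lo), min(n, hi)))
    out = vol[tuple(slices)]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads)
    return out


def preprocess(ct, pet, mask, *, spacing=(1.0, 1.0, 1.0),
               target_spacing: float = 1.0, crop_size_mm: float = 128.0,
               suv: SUVParams | None = SUVParams(),
               ct_clip=(-200.0, 250.0), pet_clip=(0.0, 25.0)):
    """Resample, crop, SUV-convert, clip and normalize a CT/PET/mask triple.

    Returns ``(ct01, pet01, mask)`` — intensities in [0, 1], mask uint8
    — on an isotropic grid of `target_spacing` mm cropped to a
    `crop_size_mm` cube centred on the mask centroid.  Pass
    ``suv=None`` for data already on the SUV scale (and clips matching
    the data's range for already-normalized volumes).
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("empty mask: no centroid to crop around")
    ct_r = _resample(ct, spacing, target_spacing, order=1)
    pet_r = _resample(pet, spacing, target_spacing, order=1)
    mask_r = (_resample(mask.astype(float), spacing, target_spacing, order=0) > 0.5)

    centroid = np.array(ndimage.center_of_mass(mask_r))
    half = int(round(crop_size_mm / (2.0 * target_spacing)))
    ct_c = _crop_cube(ct_r, centroid, half)
    pet_c = _crop_cube(pet_r, centroid, half)
    mask_c = _crop_cube(mask_r.astype(float), centroid, half) > 0.5

    if suv is not None:
        pet_c = pet_c * suv.factor()
    lo, hi = ct_clip
    ct01 = (np.clip(ct_c, lo, hi) - lo) / (hi - lo)
    lo, hi = pet_clip
    pet01 = (np.clip(pet_c, lo, hi) - lo) / (hi - lo)
    return ct01, pet01, mask_c.astype(np.uint8)


def augment(ct, pet, mask, seed: int = 0, *, p: float = 0.5,
            noise_sd: float = 0.02, max_rotation_deg: float = 15.0):
    """Randomly noise / flip / rotate a preprocessed triple.

    Returns ``(ct, pet, mask, applied)`` where `applied` records which
    transforms fired.  Noise is clipped back to [0, 1]; the flip and
    the in-plane rotation (axes 0-1) act identically on all three
    volumes, with nearest-neighbour interpolation for the mask.
    """
    rng = np.random.default_rng(seed)
    do_noise, do_flip, do_rot = rng.uniform(size=3) < p
    ct = np.asarray(ct, float).copy()
    pet = np.asarray(pet, float).copy()
    mask = np.asarray(mask).copy()
    if do_noise:
        ct = np.clip(ct + rng.normal(0.0, noise_sd, ct.shape), 0.0, 1.0)
        pet = np.clip(pet + rng.normal(0.0, noise_sd, pet.shape), 0.0, 1.0)
    if do_flip:
        ct, pet, mask = np.flip(ct, 0), np.flip(pet, 0), np.flip(mask, 0)
    if do_rot:
        angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
        rot = lambda v, order: ndimage.rotate(v, angle, axes=(0, 1),
                                              reshape=False, order=order)
        ct = np.clip(rot(ct, 1), 0.0, 1.0)
        pet = np.clip(rot(pet, 1), 0.0, 1.0)
        mask = rot(mask.astype(float), 0) > 0.5
    return (np.ascontiguousarray(ct), np.ascontiguousarray(pet),
            np.ascontiguousarray(mask.astype(np.uint8)),
            {"noise": bool(do_noise), "flip": bool(do_flip), "rotation": bool(do_rot)})


def save_nifti(path, volume, voxel_size_mm: float = 1.0):
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    data = (volume.astype(np.uint8) if volume.dtype == np.uint8
            else volume.astype(np.float32))
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])
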