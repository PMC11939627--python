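"""Epicardial adipose tissue segmentation by HU thresholding.

EAT is the fat enclosed by the pericardial sac; on CT it is identified as
contiguous voxels inside the pericardial region whose attenuation falls in
the adipose window (default -190 to -30 HU, both ends inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig
from .errors import GridIncompatibilityError
from .io import BinaryMask, CTVolume

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class EATSegmentation:
    """EAT mask plus its connected components at one phase."""

    mask: BinaryMask
    component_sizes: list[int]
    phase_percent: int

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels


def segment_eat(
    volume: CTVolume,
    peri_mask: BinaryMask,
    config: AnalysisConfig | None = None,
) -> EATSegmentation:
    """Segment EAT inside the pericardial region of ``volume``.

    A voxel is adipose when it lies in ``peri_mask`` and its HU is within
    ``[config.hu_low, config.hu_high]`` inclusive. Contiguity is evaluated
    with ``config.connectivity`` (default 26); components smaller than
    ``config.min_component_voxels`` are dropped (default keeps all).
    """
    config = config or AnalysisConfig()
    if volume.voxels.shape != peri_mask.voxels.shape:
        raise GridIncompatibilityError(
            f"volume grid {volume.voxels.shape} != mask grid {peri_mask.voxels.shape}"
        )
    candidate = (
        peri_mask.voxels
        & (volume.voxels >= config.hu_low)
        & (volume.voxels <= config.hu_high)
    )
    labels, n_comp = ndimage.label(candidate, structure=_STRUCTURES[config.connectivity])
    sizes = ndimage.sum_labels(candidate, labels, index=np.arange(1, n_comp + 1)).astype(int)
    keep = sizes >= config.min_component_voxels
    if config.min_component_voxels > 0 and not np.all(keep):
        keep_ids = np.flatnonzero(keep) + 1
        candidate = np.isin(labels, keep_ids)
        sizes = sizes[keep]
    if not candidate.any():
        warnings.warn(
            "empty EAT segmentation (low EAT volume limits the assessable area)",
            stacklevel=2,
        )
    mask = BinaryMask(voxels=candidate, affine=volume.affine, label="EAT")
    return EATSegmentation(
        mask=mask,
        component_sizes=sorted(sizes.tolist(), reverse=True),
        phase_percent=volume.phase_percent,
    )
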