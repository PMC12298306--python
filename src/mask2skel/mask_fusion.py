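"""Fuse a high-resolution foreground mask with a language-grounded object mask.

Segmentation foundation models produce two complementary silhouettes per view:
a spatially accurate foreground mask that may include background clutter, and
a semantically targeted but coarse object mask. The fused tree mask is

    M_final = LargestCC( M_fg AND Close(M_lang, s) )

with a square s x s structuring element (default s = 7) and 8-connected
components.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io_formats import BinaryMask

__all__ = ["morphological_close", "largest_connected_component", "fuse_masks"]

_STRUCT_8 = np.ones((3, 3), dtype=bool)


def _square(kernel: int) -> np.ndarray:
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    return np.ones((kernel, kernel), dtype=bool)


def morphological_close(mask: BinaryMask, kernel: int = 7) -> BinaryMask:
    """Binary closing: dilation then erosion with a square element.

    Dilation treats pixels outside the image as background while erosion
    treats them as foreground, so closing is extensive (output ⊇ input) and
    leaves an all-foreground mask unchanged.
    """
    st = _square(kernel)
    dilated = ndimage.binary_dilation(mask.grid, structure=st, border_value=0)
    closed = ndimage.binary_erosion(dilated, structure=st, border_value=1)
    return BinaryMask(grid=closed, view_id=mask.view_id)


def largest_connected_component(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Keep only the largest foreground component.

    Ties are broken by the component containing the first foreground pixel in
    row-major order. An all-background mask is returned unchanged with a
    ``warning`` set (upstream segmentation failure).
    """
    if connectivity == 8:
        structure = _STRUCT_8
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask.grid, structure=structure)
    if n == 0:
        return BinaryMask(grid=np.zeros_like(mask.grid), view_id=mask.view_id,
                          warning="empty mask: no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    # scipy labels components in row-major seed order, so among ties the
    # smallest label is the one seeded at the lowest (row, col)
    best_label = int(np.flatnonzero(sizes == best_size)[0]) + 1
    return BinaryMask(grid=labels == best_label, view_id=mask.view_id)


def fuse_masks(m_fg: BinaryMask, m_lang: BinaryMask, kernel: int = 7,
               connectivity: int = 8) -> BinaryMask:
    """Intersect the foreground mask with the closed language mask and keep
    the largest connected component."""
    if m_fg.shape != m_lang.shape:
        raise ValueError(f"mask shapes differ: {m_fg.shape} vs {m_lang.shape}")
    closed = morphological_close(m_lang, kernel)
    both = BinaryMask(grid=m_fg.grid & closed.grid, view_id=m_fg.view_id)
    return largest_connected_component(both, connectivity=connectivity)
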