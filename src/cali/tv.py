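"""Total-variation primitives: per-view smoothing and masked inpainting.

Smoothing uses the Rudin-Osher-Fatemi model solved by Chambolle's projection
algorithm (scikit-image's ``denoise_tv_chambolle``).  Inpainting solves the
masked TV minimisation by an iterated denoise-and-reinsert projection: each
sweep denoises the current estimate and resets the known pixels, so the
masked region relaxes toward the TV extension of its boundary while known
pixels remain bit-exact in the output.
"""
from __future__ import annotations

import numpy as np
from skimage.restoration import denoise_tv_chambolle

__all__ = ["tv_smooth_views", "tv_inpaint"]


def tv_smooth_views(stack: np.ndarray, weight: float,
                    max_num_iter: int = 100) -> np.ndarray:
    """ROF-smooth each 2-D view of an (n_views, rows, cols) stack.

    ``weight`` is the Chambolle denoising weight in data units: variations
    comparable to or smaller than it are flattened, larger edges survive.
    """
    out = np.empty_like(stack, dtype=float)
    for i in range(stack.shape[0]):
        view = stack[i]
        rng = np.ptp(view)
        if rng < 1e-12:  # constant view: denoiser is the identity
            out[i] = view
            continue
        out[i] = denoise_tv_chambolle(view, weight=weight,
                                      max_num_iter=max_num_iter)
    return out


def tv_inpaint(values: np.ndarray, mask: np.ndarray, weight: float | None = None,
               n_sweeps: int = 40, max_num_iter: int = 30) -> np.ndarray:
    """Replace ``mask`` pixels/voxels by TV-inpainted values.

    Works for 2-D and 3-D arrays.  Unmasked entries of the result are
    bit-exact copies of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape must match values")
    if mask.all():
        raise ValueError("cannot inpaint a fully masked array")
    out = np.array(values, dtype=float, copy=True)
    if not mask.any():
        return out
    known = ~mask
    # initialise the hole: 1-D linear interpolation along the last axis
    # (rows of a detector view), falling back to the known mean
    fill = out[known].mean()
    if out.ndim == 2:
        x = np.arange(out.shape[-1])
        for r in range(out.shape[0]):
            mrow = mask[r]
            if not mrow.any():
                continue
            if mrow.all():
                out[r] = fill
            else:
                out[r, mrow] = np.interp(x[mrow], x[~mrow], out[r, ~mrow])
    else:
        out[mask] = fill
    rng = np.ptp(out[known])
    if rng < 1e-12:
        out[mask] = fill
        return out
    if weight is None:
        weight = 0.25 * rng
    for _ in range(n_sweeps):
        sm = denoise_tv_chambolle(out, weight=weight, max_num_iter=max_num_iter)
        out[mask] = sm[mask]
        out[known] = values[known]
    out[known] = values[known]
    return out
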