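"""Literal, unoptimized re-implementation of the wavelet-product mask.

Used as an independent oracle: explicit 1-D Gaussian kernels applied with
Python loops over rows/columns, explicit per-pixel wavelet products, an
explicit threshold comparison, and an explicit neighborhood dilation. No
scipy.ndimage calls anywhere.
"""

import numpy as np

from transloquant.masking import MaskProfile, Optics, airy_radius_px


def _gauss_kernel(sigma: float) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _blur_axis0(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    r = (kernel.size - 1) // 2
    padded = np.pad(img, ((r, r), (0, 0)), mode="symmetric")
    out = np.empty_like(img, dtype=np.float64)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            acc = padded[i + r, j] * kernel[r]
            for t in range(1, r + 1):
                acc += kernel[r - t] * (padded[i + r - t, j] + padded[i + r + t, j])
            out[i, j] = acc
    return out


def brute_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur, axis 0 then axis 1, symmetric padding."""
    k = _gauss_kernel(sigma)
    out = _blur_axis0(np.asarray(img, dtype=np.float64), k)
    return _blur_axis0(out.T, k).T


def brute_mask(frame: np.ndarray, optics: Optics, profile: MaskProfile) -> np.ndarray:
    """Full pipeline: ladder, wavelets, product, threshold, dilation."""
    frame = np.asarray(frame, dtype=np.float64)
    base = airy_radius_px(optics)
    sigmas = [
        (m * base) / 2.355 if profile.sigma_convention == "fwhm" else m * base
        for m in profile.scale_multipliers
    ]
    ladder = [brute_blur(frame, s) for s in sigmas]

    wavelets = []
    for a, b in zip(ladder, ladder[1:]):
        w = a - b
        if profile.clamp_negative_wavelets:
            w = np.where(w < 0.0, 0.0, w)
        wavelets.append(w)

    ny, nx = frame.shape
    # per-pixel product, accumulated left to right over wavelet planes
    product = wavelets[0].copy()
    for w in wavelets[1:]:
        nxt = np.empty_like(product)
        for i in range(ny):
            for j in range(nx):
                nxt[i, j] = product[i, j] * w[i, j]
        product = nxt

    if profile.threshold_base == "product_mean_sd":
        thr = product.mean() + profile.threshold_factor * product.std()
    else:
        thr = profile.threshold_factor * frame.std()
    mask = product > thr

    for _ in range(profile.dilation_cycles):
        dil = np.zeros_like(mask)
        for i in range(ny):
            for j in range(nx):
                if mask[i, j]:
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ii, jj = i + di, j + dj
                            if 0 <= ii < ny and 0 <= jj < nx:
                                dil[ii, jj] = True
        mask = dil
    return mask
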