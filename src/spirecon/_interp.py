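"""Validity-aware trilinear / bilinear interpolation on regular grids."""

from __future__ import annotations

import numpy as np

#: minimum fraction of trilinear corner weight that must be valid for a sample
MIN_VALID_WEIGHT = 0.25


def trilinear(
    values: np.ndarray,
    valid: np.ndarray | None,
    coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of ``values`` at fractional voxel ``coords``.

    ``coords`` has shape ``(..., 3)``.  Corners flagged invalid are dropped
    and the remaining weights renormalized; a sample is invalid when it falls
    outside the grid or when less than ``MIN_VALID_WEIGHT`` of its corner
    weight is valid.  Returns ``(interpolated, valid_mask)``.
    """
    m0, m1, m2 = values.shape
    c = np.asarray(coords, dtype=float)
    out_shape = c.shape[:-1]
    c = c.reshape(-1, 3)
    i0 = np.floor(c).astype(np.int64)
    inside = (
        (i0[:, 0] >= 0) & (i0[:, 0] <= m0 - 2)
        & (i0[:, 1] >= 0) & (i0[:, 1] <= m1 - 2)
        & (i0[:, 2] >= 0) & (i0[:, 2] <= m2 - 2)
    )
    np.clip(i0[:, 0], 0, m0 - 2, out=i0[:, 0])
    np.clip(i0[:, 1], 0, m1 - 2, out=i0[:, 1])
    np.clip(i0[:, 2], 0, m2 - 2, out=i0[:, 2])
    f = c - i0
    g = 1.0 - f
    base = (i0[:, 0] * m1 + i0[:, 1]) * m2 + i0[:, 2]
    flat_v = values.reshape(-1)
    flat_ok = None if valid is None else valid.reshape(-1)
    acc = np.zeros(len(c), dtype=values.dtype)
    wacc = None
    for di in (0, 1):
        wi = f[:, 0] if di else g[:, 0]
        for dj in (0, 1):
            wij = wi * (f[:, 1] if dj else g[:, 1])
            for dk in (0, 1):
                w = wij * (f[:, 2] if dk else g[:, 2])
                idx = base + ((di * m1 + dj) * m2 + dk)
                if flat_ok is not None:
                    w = w * flat_ok[idx]
                acc += w * flat_v[idx]
                wacc = w if wacc is None else wacc + w
    if flat_ok is None:
        ok_out = inside
        out = acc
    else:
        ok_out = inside & (wacc >= MIN_VALID_WEIGHT)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = acc / np.where(wacc > 0, wacc, 1.0)
    out = out.copy()
    out[~ok_out] = 0.0
    return out.reshape(out_shape), ok_out.reshape(out_shape)


def bilinear(
    values: np.ndarray,
    valid: np.ndarray | None,
    rows: np.ndarray,
    cols: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """2D analogue of :func:`trilinear`; ``values`` may carry leading stack axes.

    ``rows``/``cols`` are fractional pixel coordinates of identical shape;
    interpolation acts on the two trailing axes of ``values``; ``valid``
    spans only those two axes (shared across any leading stack axes).
    Returns ``(interpolated, valid_mask)`` with the stack axes leading on
    the values and the mask covering the sample shape.
    """
    m0, m1 = values.shape[-2:]
    r = np.asarray(rows, dtype=float).ravel()
    ccol = np.asarray(cols, dtype=float).ravel()
    i0 = np.floor(r).astype(np.int64)
    j0 = np.floor(ccol).astype(np.int64)
    inside = (i0 >= 0) & (i0 <= m0 - 2) & (j0 >= 0) & (j0 <= m1 - 2)
    np.clip(i0, 0, m0 - 2, out=i0)
    np.clip(j0, 0, m1 - 2, out=j0)
    fr, fc = r - i0, ccol - j0
    lead = values.shape[:-2]
    acc = np.zeros(lead + r.shape, dtype=values.dtype)
    wacc = np.zeros(r.shape)
    for di in (0, 1):
        wi = fr if di else 1.0 - fr
        for dj in (0, 1):
            w = wi * (fc if dj else 1.0 - fc)
            v = values[..., i0 + di, j0 + dj]
            if valid is not None:
                w = w * valid[..., i0 + di, j0 + dj]
            acc += w * v
            wacc += w
    ok_out = inside & (wacc >= MIN_VALID_WEIGHT)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = acc / np.where(wacc > 0, wacc, 1.0)
    out[..., ~ok_out] = 0.0 if np.isrealobj(out) else 0
    shape = np.asarray(rows).shape
    return out.reshape(lead + shape), ok_out.reshape(shape)
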