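"""Peak-position initialisation shared by both quantifiers.

The initialiser multiplies all traces of a peptide pointwise and takes the
argmax of the product: only a peak present in every trace (both channels)
survives the product, which makes the starting retention time robust to
interfering signals in single transitions.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["trace_product_argmax"]


def trace_product_argmax(
    grid: np.ndarray,
    traces: list[np.ndarray],
    bounds: tuple[float, float] | None = None,
) -> tuple[float, bool]:
    """Argmax of the pointwise product of traces, clamped into ``bounds``.

    Negative intensities are clipped at zero before multiplying.  Returns
    ``(position, flagged)``; ``flagged`` is True when the product is
    identically zero, in which case the window midpoint is returned and a
    warning is emitted.  Ties break towards the earliest time.
    """
    grid = np.asarray(grid, dtype=float)
    if not traces:
        raise ValueError("need at least one trace")
    prod = np.ones_like(grid)
    for tr in traces:
        tr = np.asarray(tr, dtype=float)
        if tr.shape != grid.shape:
            raise ValueError("trace length does not match the grid")
        prod = prod * np.clip(tr, 0.0, None)
    if not np.any(prod > 0):
        lo, hi = (grid[0], grid[-1]) if bounds is None else bounds
        warnings.warn(
            "all-zero trace product; falling back to the window midpoint",
            stacklevel=2,
        )
        return 0.5 * (lo + hi), True
    pos = float(grid[int(np.argmax(prod))])  # argmax returns first max: earliest tie
    if bounds is not None:
        pos = float(min(max(pos, bounds[0]), bounds[1]))
    return pos, False
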