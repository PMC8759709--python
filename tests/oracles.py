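"""Brute-force reference implementations, independent of the package.

Each oracle is a naive breadth-first/loop formulation of an operation the
package implements with scipy.ndimage or vectorized numpy; tests check the
two routes agree on random small instances.
"""

from collections import deque

import numpy as np

_NEIGHBORS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _bfs(passable: np.ndarray, seeds) -> np.ndarray:
    """Pixels reachable from ``seeds`` through 4-connected passable pixels."""
    h, w = passable.shape
    reached = np.zeros((h, w), dtype=bool)
    queue = deque((y, x) for y, x in seeds if passable[y, x])
    for y, x in queue:
        reached[y, x] = True
    while queue:
        y, x = queue.popleft()
        for dy, dx in _NEIGHBORS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and passable[ny, nx] \
                    and not reached[ny, nx]:
                reached[ny, nx] = True
                queue.append((ny, nx))
    return reached


def _border_seeds(h: int, w: int):
    for x in range(w):
        yield 0, x
        yield h - 1, x
    for y in range(h):
        yield y, 0
        yield y, w - 1


def body_mask_bruteforce(pixels: np.ndarray, gray_tolerance: int = 10):
    """Body = complement of near-white pixels flood-filled from the border."""
    near_white = (pixels >= 255 - gray_tolerance).all(axis=2)
    h, w = near_white.shape
    background = _bfs(near_white, _border_seeds(h, w))
    return ~background


def fill_holes_bruteforce(painted: np.ndarray) -> np.ndarray:
    """Add every unpainted 4-connected region not reachable from the border."""
    h, w = painted.shape
    outside = _bfs(~painted, _border_seeds(h, w))
    return painted | ~outside


def accumulate_bruteforce(masks) -> np.ndarray:
    """Per-pixel overlap count by an explicit triple loop."""
    h, w = masks[0].shape
    counts = np.zeros((h, w), dtype=int)
    for y in range(h):
        for x in range(w):
            for m in masks:
                if m[y, x]:
                    counts[y, x] += 1
    return counts
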