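"""Bundled manual count sheets from two aerial-survey worked examples.

Both tables are quadrat counts read off uniformly-random tilted quadrat
grids; they exercise the manual-counting workflow end to end without any
external data.

* ``crowd_table`` — football-stadium crowd still (1796 x 1200 px picture),
  grid t = 50, T = 250 px: 6 stripes, 7 quadrat positions each, 50 heads
  counted in 17 nonempty quadrats.
* ``penguin_table`` — emperor-penguin colony photograph (2359 x 826 px
  region), grid t = 30, T = 200 px tilted 45 deg: 12 stripes of varying
  depth, 76 quadrats, 123 penguins counted.
"""

from __future__ import annotations

__all__ = [
    "crowd_table",
    "penguin_table",
    "CROWD_GRID",
    "PENGUIN_GRID",
]

CROWD_GRID = {"t": 50.0, "T": 250.0}
PENGUIN_GRID = {"t": 30.0, "T": 200.0}

# One inner list per stripe; position 1 (bottom-most quadrat) first.
_CROWD_STRIPES = [
    [0, 5, 4, 0, 0, 0, 0],
    [0, 3, 3, 2, 0, 0, 0],
    [1, 0, 3, 0, 2, 3, 0],
    [0, 0, 0, 4, 4, 3, 2],
    [0, 0, 0, 0, 4, 3, 2],
    [0, 0, 0, 0, 0, 0, 2],
]

_PENGUIN_STRIPES = [
    [0, 1],
    [0, 1, 3, 0],
    [0, 1, 5, 3, 1, 0],
    [0, 5, 9, 5, 0, 2, 0, 0],
    [0, 0, 6, 5, 0, 4, 0, 0, 0],
    [0, 0, 8, 7, 4, 0, 0, 0, 0],
    [0, 2, 2, 6, 4, 1, 0, 0, 0],
    [0, 0, 5, 9, 1, 0, 1, 0, 0],
    [0, 5, 5, 1, 1, 0, 0, 0],
    [0, 3, 0, 2, 0, 0],
    [2, 2, 0, 0],
    [1, 0],
]


def crowd_table() -> list[list[int]]:
    """Stadium-crowd count sheet (Q = 50 over 6 stripes)."""
    return [list(s) for s in _CROWD_STRIPES]


def penguin_table() -> list[list[int]]:
    """Penguin-colony count sheet (Q = 123 over 12 stripes)."""
    return [list(s) for s in _PENGUIN_STRIPES]
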