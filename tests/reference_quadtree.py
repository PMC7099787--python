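"""Independent brute-force quadtree reference used as a test oracle.

Plain top-down recursion over explicit array slices, written without any
code shared with the package implementation, following the same
conventions: root window of side s_max * 2**m when the area cap can bind
below the grid size, otherwise the smallest power of two covering the
grid; floor splits; NW, NE, SW, SE depth-first emission; windows without
valid cells dropped; population summed over valid cells only.
"""

import numpy as np


def reference_partition(values, mask, cell_size, pop_max, side_max_m, min_side_cells=1):
    """Return leaves as (row0, col0, n_rows, n_cols, population, n_valid)."""
    values = np.where(mask, np.asarray(values, dtype=float), 0.0)
    mask = np.asarray(mask, dtype=bool)
    nr_grid, nc_grid = values.shape
    s_max = int(side_max_m // cell_size)
    maxdim = max(nr_grid, nc_grid)

    if s_max >= maxdim:
        root = 1
        while root < maxdim:
            root *= 2
    else:
        root = s_max
        while root < maxdim:
            root *= 2

    leaves = []

    def visit(r0, c0, nr, nc):
        rr0, cc0 = min(r0, nr_grid), min(c0, nc_grid)
        rr1, cc1 = min(r0 + nr, nr_grid), min(c0 + nc, nc_grid)
        if rr0 >= rr1 or cc0 >= cc1:
            return
        sub_mask = mask[rr0:rr1, cc0:cc1]
        n_valid = int(sub_mask.sum())
        if n_valid == 0:
            return
        pop = float(values[rr0:rr1, cc0:cc1].sum())
        side = max(nr, nc)
        ok = pop < pop_max and side <= s_max
        if ok or side <= min_side_cells:
            leaves.append((r0, c0, nr, nc, pop, n_valid))
            return
        hr, hc = nr // 2, nc // 2
        visit(r0, c0, hr, hc)
        visit(r0, c0 + hc, hr, nc - hc)
        visit(r0 + hr, c0, nr - hr, hc)
        visit(r0 + hr, c0 + hc, nr - hr, nc - hc)

    if mask.any():
        visit(0, 0, root, root)
    return leaves
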