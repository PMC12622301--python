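"""Classical Saitou–Nei neighbor joining from a distance matrix.

This is the distance-based baseline that the learned join-scoring model is
measured against.  At each step the pair (i, j) minimizing

    Q(i, j) = (k - 2) d(i, j) - sum_m d(i, m) - sum_m d(j, m)

is joined (k = number of active clusters); ties are broken by the smallest
(i, j) index pair so that the construction is fully deterministic.  Estimated
branch lengths that come out negative are clamped to zero, which never
changes the topology.
"""

from __future__ import annotations

import numpy as np

from .trees import DistanceMatrix, PhyloTree

__all__ = ["neighbor_joining"]


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Build an unrooted binary tree from a distance matrix by neighbor joining.

    Requires at least 3 taxa.  The result is written with a trifurcating root
    (the standard unrooted representation).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    d = dm.values.astype(float).copy()
    # each active cluster is a newick fragment (without trailing length)
    frags = list(dm.labels)

    while len(frags) > 3:
        k = len(frags)
        row_sums = d.sum(axis=1)
        q = (k - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j), i < j, among the minima
        iu = np.triu_indices(k, 1)
        qvals = q[iu]
        best = np.argmin(qvals)  # argmin scans row-major upper triangle: lexicographic
        i, j = int(iu[0][best]), int(iu[1][best])

        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (k - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_frag = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"

        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [m for m in range(k) if m not in (i, j)]
        d_next = np.empty((k - 1, k - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d_next[-1, -1] = 0.0
        d = d_next
        frags = [frags[m] for m in keep] + [new_frag]

    # final trifurcation: three-point formulas
    l0 = max(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]), 0.0)
    l1 = max(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]), 0.0)
    l2 = max(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]), 0.0)
    newick = (f"({frags[0]}:{l0:.10g},{frags[1]}:{l1:.10g},"
              f"{frags[2]}:{l2:.10g});")
    return PhyloTree.from_newick(newick)
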