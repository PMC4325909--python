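"""Direct tree/ladder solver for the implicit cable update.

The discretised system couples, per compartment, an intracellular potential
and (for double-cable compartments) a periaxonal potential.  Ordering the
two unknowns of a compartment as a 2x2 block makes the whole matrix
block-tridiagonal along every branch of the tree: the off-diagonal block
between a compartment and its parent is diagonal (intracellular axial
conductance, periaxonal axial conductance).  A two-pass block elimination --
children before parents, then back-substitution from the root -- is an exact
direct solve with zero fill-in outside the blocks.

Single-cable compartments use a dummy periaxonal row (diagonal 1, rhs 0) so
one kernel covers both cases.  Compartments must be ordered so that every
parent index is smaller than its child's index; the root is compartment 0.
"""

import numpy as np
from numba import njit

__all__ = ["block_hines_solve"]


@njit(cache=True)
def block_hines_solve(parent, d11, d12, d22, oa, op, rhs1, rhs2, x1, x2):
    """Solve the block-tridiagonal tree system in place.

    ``d11, d12, d22`` are the symmetric 2x2 diagonal blocks, ``oa, op`` the
    (diagonal) coupling block entries between compartment i and parent[i].
    All arrays are modified; the solution lands in ``x1`` (intracellular)
    and ``x2`` (periaxonal).
    """
    n = parent.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        det = d11[i] * d22[i] - d12[i] * d12[i]
        bi11 = d22[i] / det
        bi12 = -d12[i] / det
        bi22 = d11[i] / det
        d11[p] -= oa[i] * oa[i] * bi11
        d12[p] -= oa[i] * op[i] * bi12
        d22[p] -= op[i] * op[i] * bi22
        r1 = bi11 * rhs1[i] + bi12 * rhs2[i]
        r2 = bi12 * rhs1[i] + bi22 * rhs2[i]
        rhs1[p] -= oa[i] * r1
        rhs2[p] -= op[i] * r2
    det = d11[0] * d22[0] - d12[0] * d12[0]
    x1[0] = (d22[0] * rhs1[0] - d12[0] * rhs2[0]) / det
    x2[0] = (d11[0] * rhs2[0] - d12[0] * rhs1[0]) / det
    for i in range(1, n):
        p = parent[i]
        r1 = rhs1[i] - oa[i] * x1[p]
        r2 = rhs2[i] - op[i] * x2[p]
        det = d11[i] * d22[i] - d12[i] * d12[i]
        x1[i] = (d22[i] * r1 - d12[i] * r2) / det
        x2[i] = (d11[i] * r2 - d12[i] * r1) / det
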