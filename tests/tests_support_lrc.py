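"""Brute-force periodic-image oracle for the LJ long-range correction.

Independent of the package's quadrature route: the neglected energy is
summed pair-by-pair over explicit periodic images out to a large spherical
radius, with the (tiny, closed-form) remainder beyond that radius added
analytically so the comparison is limited only by configurational
statistics.
"""

import itertools
import math

import numpy as np

from saisolv import lj_energy


def brute_force_neglected_energy(pos, r_min, epsilon, box, settings,
                                 n_images=4):
    """Sum of [U - U_switched] over all pairs and periodic images.

    ``pos`` is (N, 3); one LJ type per particle via ``r_min``/``epsilon``
    arrays.  Includes self-image interactions (i with its own periodic
    copies).  Images are counted inside a sphere of radius
    (n_images + 0.5) * box; the analytic r^-6/r^-12 remainder beyond that
    radius is added per pair so the truncation bias is negligible.
    """
    n = pos.shape[0]
    radius = (n_images + 0.5) * box
    shifts = np.array([s for s in itertools.product(
        range(-n_images, n_images + 1), repeat=3)], dtype=float) * box

    total = 0.0
    v = box**3
    remainder = 0.0
    for i in range(n):
        others = np.ones(n, dtype=bool)
        others[i] = False  # distinct pairs only (matches analytic_tail)
        disp = (pos[i][None, None, :] - pos[None, others, :]
                + shifts[:, None, :])
        r = np.sqrt((disp**2).sum(axis=2))  # (n_shifts, N-1)
        rm = 0.5 * (r_min[i] + r_min[others])
        ep = np.sqrt(epsilon[i] * epsilon[others])
        mask = r <= radius
        r_safe = np.where(mask, r, 1.0)
        u_full = np.where(mask, _lj_base(r_safe, rm[None, :], ep[None, :]),
                          0.0)
        u_sw = np.where(mask, lj_energy(r_safe, rm[None, :], ep[None, :],
                                        settings), 0.0)
        total += float(np.sum(u_full - u_sw))
        # continuum remainder beyond the image sphere:
        # (2 pi / V) * integral_R^inf U_ij(r) r^2 dr per ordered pair
        integ = (-2.0 * ep * rm**6 / (3.0 * radius**3)
                 + ep * rm**12 / (9.0 * radius**9))
        remainder += 2.0 * math.pi / v * float(np.sum(integ))
    # total counted each unordered pair twice; the remainder is already the
    # (2 pi / V) ordered-pair sum, which is the per-unordered-pair 4 pi / V
    return 0.5 * total + remainder


def _lj_base(r, rm, ep):
    t6 = (rm / r) ** 6
    return ep * (t6 * t6 - 2.0 * t6)
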