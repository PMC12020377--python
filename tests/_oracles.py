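"""Independent oracles used by the test suite.

These are deliberately written in a different style from the package code
(plain transcription of the published decision table, brute-force norms,
nested grid searches) so that they constitute an independent check rather
than a second call into the code under test.
"""

import math

import numpy as np


def norm_distance(p, q):
    """Brute-force Euclidean norm."""
    return math.sqrt(sum((float(a) - float(b)) ** 2 for a, b in zip(p, q)))


def in_syn(chi):
    chi = ((chi + 180.0) % 360.0) - 180.0
    if chi == -180.0:
        chi = 180.0
    return -25.0 <= chi <= 115.0


def in_anti(chi):
    chi = ((chi + 180.0) % 360.0) - 180.0
    if chi == -180.0:
        chi = 180.0
    return (-180.0 <= chi <= -25.0) or (115.0 <= chi <= 180.0)


def decision_table(d_n1, d_n2, d_o6, d_n7, d_rp, chi, r_loop, r_all):
    """Literal transcription of the published clustering criteria.

    Precedence: the stem+loop override first, then least- to most-disrupted,
    with the U6+U7+C8-bulge carve-out ahead of loop-disrupted.
    """
    if r_all > 4.6:
        return "stem_loop_disrupted"
    either = (d_n1 < 3.5) or (d_n2 < 3.5)
    if d_n1 < 3.5 and d_o6 < 3.5 and d_n7 < 3.5 and d_rp < 3.7 and in_syn(chi):
        return "native"
    if either and d_o6 < 3.5 and d_n7 > 3.5 and d_rp < 3.7 and in_syn(chi):
        return "sugar_base_N7_lost"
    if either and d_o6 < 3.5 and d_n7 < 4.0 and d_rp > 3.7 and in_syn(chi):
        return "bph7_lost"
    if either and d_o6 > 3.5 and d_n7 > 3.5 and d_rp < 3.7 and in_syn(chi):
        return "both_sugar_base_lost"
    if either and (d_o6 > 3.5 or d_n7 > 3.5) and d_rp > 5.0 and in_syn(chi):
        return "C8_bulge_one_sugar_base_lost"
    if d_n1 > 5.0 and d_o6 > 5.0 and in_syn(chi) and r_loop < 3.0:
        return "G9_bulge_syn"
    if d_n1 > 5.0 and d_o6 > 5.0 and in_anti(chi) and r_loop < 3.0:
        return "G9_bulge_anti"
    if d_n1 < 5.2 and (d_o6 < 3.7 or d_rp < 4.2) and in_anti(chi) and r_loop < 3.0:
        return "G9_back_in_pocket_anti"
    if d_n1 > 5.0 and (d_o6 < 4.0 or d_n7 < 4.0) and d_rp > 5.0 and in_syn(chi):
        return "U6U7C8_bulge"
    if r_loop > 3.0:
        return "loop_disrupted"
    return "unclassified"


def grid_search_superposition_rmsd(x, y, levels=4, span=math.pi, steps=9):
    """Minimum RMSD over rotations by nested grid search on Euler angles.

    Centres both point sets, then zooms a 3-D grid of z-y-z Euler angles.
    Accurate to well below 1e-3 Å for small systems.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)

    def rmsd_for(a, b, c):
        ca, sa = math.cos(a), math.sin(a)
        cb, sb = math.cos(b), math.sin(b)
        cc, sc = math.cos(c), math.sin(c)
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        r = rz1 @ ry @ rz2
        d = xc @ r.T - yc
        return math.sqrt(float(np.mean(np.sum(d * d, axis=1))))

    centre = np.zeros(3)
    width = span
    best = (math.inf, centre)
    for _ in range(levels):
        axes = [np.linspace(centre[k] - width, centre[k] + width, steps) for k in range(3)]
        for a in axes[0]:
            for b in axes[1]:
                for c in axes[2]:
                    v = rmsd_for(a, b, c)
                    if v < best[0]:
                        best = (v, np.array([a, b, c]))
        centre = best[1]
        width = width * 2.0 / (steps - 1)
    return best[0]


def gvector_by_hand(r_local, a=5.0, b=3.0, cutoff=2.4):
    """Scalar-arithmetic G vector of one inter-base separation."""
    x, y, z = (float(v) for v in r_local)
    xs, ys, zs = x / a, y / a, z / b
    rho = math.sqrt(xs * xs + ys * ys + zs * zs)
    if rho >= cutoff:
        return [0.0, 0.0, 0.0, 0.0]
    gamma = math.pi / cutoff
    s = math.sin(gamma * rho) / rho
    return [s * xs, s * ys, s * zs, 1.0 + math.cos(gamma * rho)]
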