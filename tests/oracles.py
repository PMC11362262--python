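"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from first principles or published
formulas, deliberately avoiding the code paths (and libraries) the
package itself uses for the same quantity.
"""

from math import comb

import numpy as np


def srgb_to_lab_oracle(rgb):
    """Reference sRGB -> XYZ(D65) -> CIELAB conversion from the published
    equations."""
    rgb = np.asarray(rgb, float) / 255.0
    lin = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [[0.4124564, 0.3575761, 0.1804375],
         [0.2126729, 0.7151522, 0.0721750],
         [0.0193339, 0.1191920, 0.9503041]]
    )
    xyz = M @ lin
    white = np.array([0.95047, 1.0, 1.08883])  # D65, 2 degree observer
    t = xyz / white
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    return np.array([116 * f[1] - 16, 500 * (f[0] - f[1]), 200 * (f[1] - f[2])])


def ciede2000_oracle(lab1, lab2):
    """CIEDE2000 transcribed step by step from the published formulation
    (worked-implementation notes), kL = kC = kH = 1."""
    L1, a1, b1 = lab1
    L2, a2, b2 = lab2
    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = (C1 + C2) / 2
    G = 0.5 * (1 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p, a2p = (1 + G) * a1, (1 + G) * a2
    C1p, C2p = np.hypot(a1p, b1), np.hypot(a2p, b2)
    h1p = np.degrees(np.arctan2(b1, a1p)) % 360 if (b1 != 0 or a1p != 0) else 0.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360 if (b2 != 0 or a2p != 0) else 0.0
    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0:
        dhp = 0.0
    elif abs(h2p - h1p) <= 180:
        dhp = h2p - h1p
    elif h2p - h1p > 180:
        dhp = h2p - h1p - 360
    else:
        dhp = h2p - h1p + 360
    dHp = 2 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp) / 2)
    Lbp = (L1 + L2) / 2
    Cbp = (C1p + C2p) / 2
    if C1p * C2p == 0:
        hbp = h1p + h2p
    elif abs(h1p - h2p) <= 180:
        hbp = (h1p + h2p) / 2
    elif h1p + h2p < 360:
        hbp = (h1p + h2p + 360) / 2
    else:
        hbp = (h1p + h2p - 360) / 2
    T = (1 - 0.17 * np.cos(np.radians(hbp - 30)) + 0.24 * np.cos(np.radians(2 * hbp))
         + 0.32 * np.cos(np.radians(3 * hbp + 6)) - 0.20 * np.cos(np.radians(4 * hbp - 63)))
    dtheta = 30 * np.exp(-(((hbp - 275) / 25) ** 2))
    RC = 2 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1 + 0.015 * (Lbp - 50) ** 2 / np.sqrt(20 + (Lbp - 50) ** 2)
    SC = 1 + 0.045 * Cbp
    SH = 1 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2 * dtheta)) * RC
    return np.sqrt(
        (dLp / SL) ** 2 + (dCp / SC) ** 2 + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )


def ari_oracle(l1, l2):
    """Adjusted Rand Index from the contingency-table formula."""
    l1, l2 = np.asarray(l1), np.asarray(l2)
    cats1, cats2 = np.unique(l1), np.unique(l2)
    table = np.array(
        [[np.sum((l1 == a) & (l2 == b)) for b in cats2] for a in cats1]
    )
    index = sum(comb(int(n), 2) for n in table.ravel())
    sum_a = sum(comb(int(n), 2) for n in table.sum(axis=1))
    sum_b = sum(comb(int(n), 2) for n in table.sum(axis=0))
    total = comb(len(l1), 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


def ward_oracle_from_points(points):
    """Brute-force Ward clustering evaluated on raw coordinates.

    At each step, merges the pair of clusters whose union minimizes the
    increase in total within-cluster sum of squares; heights follow
    scipy's convention (sqrt of twice the ESS increase).
    """
    clusters = {i: [i] for i in range(len(points))}
    heights = []
    merge_members = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                pa, pb = points[clusters[a]], points[clusters[b]]
                na, nb = len(pa), len(pb)
                delta = (
                    na * nb / (na + nb)
                    * np.sum((pa.mean(axis=0) - pb.mean(axis=0)) ** 2)
                )
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        delta, a, b = best
        heights.append(np.sqrt(2 * delta))
        merge_members.append(sorted(clusters[a] + clusters[b]))
        clusters[a] = clusters[a] + clusters.pop(b)
    return heights, merge_members


def members_of_linkage(Z, n):
    """Member sets produced by each merge of a scipy linkage matrix."""
    sets = {i: [i] for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = sorted(sets[int(a)] + sets[int(b)])
        sets[n + step] = merged
        out.append(merged)
    return out


def average_ranks(v):
    """Average ranks with explicit tie handling (1-based)."""
    v = np.asarray(v)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2
        i = j
    return ranks
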