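"""Independent brute-force reference implementations.

Every function here recomputes a network quantity with plain Python loops
over elements, directly from its defining rule, without reusing any array
machinery from the package.  They exist solely as oracles for equivalence
tests.
"""

from __future__ import annotations

import math

import numpy as np


def pair_difference(a, b):
    h, w = a.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            out[r, c] = abs(a[r, c] - b[r, c])
    return out


def cluster_filter(e, radius=3.0, min_count=10):
    h, w = e.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if e[r, c] <= 0:
                continue
            count = 0
            for rr in range(h):
                for cc in range(w):
                    if e[rr, cc] > 0 and math.hypot(rr - r, cc - c) <= radius:
                        count += 1
            if count > min_count:
                out[r, c] = e[r, c]
    return out


def zone_membership(shape, center, radius, top=0.25, bottom=0.25):
    h, w = shape
    cx, cy = center
    members = []
    for r in range(h):
        for c in range(w):
            d = math.hypot(c - cx, r - cy)
            if d <= radius and r >= top * h and r <= (1 - bottom) * h:
                members.append((c, r))
    return members


def r_coll(e, members, s):
    total = 0.0
    w_count = 0
    for c, r in members:
        if e[r, c] > 0:
            total += e[r, c]
            w_count += 1
    return (w_count / s) * total, w_count


def r_dist(e, members, center, radius, gain=10.0, level=0.5):
    cx, cy = center
    total = 0.0
    n = 0
    for c, r in members:
        d = math.hypot(c - cx, r - cy)
        if e[r, c] > level and 0 < d < radius / 2.0:
            total += 1.0 / d
            n += 1
    return gain * total, n


def i_dist(e_prev, offsets, weight=0.35):
    h, w = e_prev.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dx, dy in offsets:
                rr, cc = r + dy, c + dx
                if 0 <= rr < h and 0 <= cc < w:
                    acc += e_prev[rr, cc] / math.hypot(dx, dy)
            out[r, c] = weight * acc
    return out


def i_potential(e_now, stored, counter, decay_step=2.0):
    h, w = e_now.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            decay = max(stored[r, c] - decay_step * counter[r, c], 0.0)
            out[r, c] = max(e_now[r, c] - decay, 0.0)
    return out


def layer_excitation(i_pot, members, s, active=0.1, strong=1.0):
    total = 0.0
    m = 0
    for c, r in members:
        v = i_pot[r, c]
        if v > active:
            total += v
        if v > strong:
            m += 1
    return (m / s) * total
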