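"""Independent scalar-loop oracles for the level-set losses.

Deliberately written pixel-by-pixel in plain Python so they share no code
path with the vectorized implementations they check.
"""

import math


def step(x: float, eps: float) -> float:
    return 0.5 * (1.0 + (2.0 / math.pi) * math.atan(eps * x))


def _region_means(ref, phi, eps):
    h, w = len(ref), len(ref[0])
    num1 = num2 = den1 = den2 = 0.0
    for i in range(h):
        for j in range(w):
            H = step(phi[i][j] - 0.5, eps)
            num1 += ref[i][j] * H
            den1 += H
            num2 += ref[i][j] * (1.0 - H)
            den2 += 1.0 - H
    return num1 / den1, num2 / den2


def curve_length_oracle(phi, eps: float) -> float:
    h, w = len(phi), len(phi[0])
    H = [[step(phi[i][j] - 0.5, eps) for j in range(w)] for i in range(h)]
    total = 0.0
    for i in range(h):
        for j in range(w):
            if i + 1 < h:
                total += abs(H[i + 1][j] - H[i][j])
            if j + 1 < w:
                total += abs(H[i][j + 1] - H[i][j])
    return total


def ls_loss_oracle(image, phi, mu, chi, d1, d2, eps) -> float:
    h, w = len(image), len(image[0])
    c1, c2 = _region_means(image, phi, eps)
    area = fid1 = fid2 = 0.0
    for i in range(h):
        for j in range(w):
            H = step(phi[i][j] - 0.5, eps)
            area += H
            fid1 += (image[i][j] - c1) ** 2 * H
            fid2 += (image[i][j] - c2) ** 2 * (1.0 - H)
    return mu * curve_length_oracle(phi, eps) + chi * area + d1 * fid1 + d2 * fid2


def lsr_loss_oracle(G, phi, d1, d2, d3, eps) -> float:
    h, w = len(G), len(G[0])
    c1, c2 = _region_means(G, phi, eps)
    f1 = f2 = f3 = 0.0
    for i in range(h):
        for j in range(w):
            H = step(phi[i][j] - 0.5, eps)
            f1 += (G[i][j] - c1) ** 2 * H
            f2 += (G[i][j] - c2) ** 2 * (1.0 - H)
            f3 += (G[i][j] - phi[i][j]) ** 2
    return f1 / d1 + f2 / d2 + f3 / d3
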