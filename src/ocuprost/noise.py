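"""Seeded 3D gradient (Perlin) noise, vectorized.

Classic lattice gradient noise with a permutation-table hash and quintic
fade, plus a small fractional-Brownian-motion helper.  Values are roughly in
[-1, 1]; the generator is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

_GRADS = np.array([
    [1, 1, 0], [-1, 1, 0], [1, -1, 0], [-1, -1, 0],
    [1, 0, 1], [-1, 0, 1], [1, 0, -1], [-1, 0, -1],
    [0, 1, 1], [0, -1, 1], [0, 1, -1], [0, -1, -1],
    [1, 1, 0], [0, -1, 1], [-1, 1, 0], [0, -1, -1],
], dtype=float)


def _fade(t: np.ndarray) -> np.ndarray:
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


class PerlinNoise3D:
    def __init__(self, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        p = rng.permutation(256)
        self._perm = np.concatenate([p, p]).astype(np.int64)

    def _grad_dot(self, hsh: np.ndarray, x: np.ndarray, y: np.ndarray,
                  z: np.ndarray) -> np.ndarray:
        g = _GRADS[hsh & 15]
        return g[..., 0] * x + g[..., 1] * y + g[..., 2] * z

    def noise(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        z = np.asarray(z, dtype=np.float32)
        xi = np.floor(x).astype(np.int64) & 255
        yi = np.floor(y).astype(np.int64) & 255
        zi = np.floor(z).astype(np.int64) & 255
        xf = x - np.floor(x)
        yf = y - np.floor(y)
        zf = z - np.floor(z)
        u, v, w = _fade(xf), _fade(yf), _fade(zf)
        P = self._perm
        res = np.zeros_like(xf)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    h = P[P[P[xi + dx] + yi + dy] + zi + dz]
                    d = self._grad_dot(h, xf - dx, yf - dy, zf - dz)
                    wx = u if dx else (1.0 - u)
                    wy = v if dy else (1.0 - v)
                    wz = w if dz else (1.0 - w)
                    res += d * wx * wy * wz
        return res

    def fbm(self, x: np.ndarray, y: np.ndarray, z: np.ndarray,
            octaves: int = 2, lacunarity: float = 2.0, gain: float = 0.5) -> np.ndarray:
        total = np.zeros(np.broadcast(x, y, z).shape, dtype=np.float32)
        amp = 1.0
        freq = 1.0
        for _ in range(octaves):
            total += amp * self.noise(x * freq, y * freq, z * freq)
            amp *= gain
            freq *= lacunarity
        return total
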