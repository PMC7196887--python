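"""Ground-truth-known synthetic spot tables.

Generators emulate the statistical structure of two- and three-color
kinetochore localization experiments: a fixed true separation between
markers, an isotropically random 3D orientation per kinetochore,
anisotropic Gaussian localization noise applied to each spot
independently (so the displacement noise SD is the per-spot SD times √2),
per-cell chromatic offsets, and optional subpopulation mixtures. Every
generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .spot_io import SpotTable

__all__ = [
    "SyntheticSpec",
    "generate_pairs",
    "generate_triples",
    "generate_mixture",
]

_CHANNELS = ("488", "568", "647")


@dataclass
class SyntheticSpec:
    """Conditions for a synthetic experiment.

    mu may be a scalar (single population) or a sequence (mixture, with
    ``weights``). sigma_* are per-spot localization SDs; the implied
    displacement noise is tau = sigma * sqrt(2). chromatic_shift maps a
    channel label to a 3-vector offset applied to every cell;
    chromatic_shift_sd adds an independent per-cell, per-channel random
    offset on top (set 0 for none). ``triangle`` holds either three 3D
    vertex positions (3x3) or three side lengths (AB, BC, AC) for
    3-fluorophore experiments; ``triangle_vertex_sd`` optionally blurs
    each vertex within the rigid frame to emulate per-marker ensemble
    spread.
    """

    n_cells: int = 20
    kts_per_cell: int = 50
    mu: float | tuple = 50.0
    weights: tuple | None = None
    sigma_xy: float = 21.0
    sigma_z: float = 42.0
    chromatic_shift: dict | None = None
    chromatic_shift_sd: float = 0.0
    triangle: tuple | None = None
    triangle_vertex_sd: tuple = (0.0, 0.0, 0.0)
    seed: int = 0
    cell_spacing: float = 10_000.0  # grid pitch for cell centers, nm
    intensity_scale: float = 1000.0
    background_level: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("per-spot localization SDs must be positive")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("mixture weights must sum to 1")


def _cell_centers(n_cells: int, spacing: float) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_cells)))
    grid = [(i * spacing, j * spacing, 0.0) for j in range(side) for i in range(side)]
    return np.asarray(grid[:n_cells])


def _noise(rng, n: int, sxy: float, sz: float) -> np.ndarray:
    eps = rng.standard_normal((n, 3))
    eps[:, :2] *= sxy
    eps[:, 2] *= sz
    return eps


def _uniform_sphere(rng, n: int) -> np.ndarray:
    u = rng.standard_normal((n, 3))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def _rows(
    spec: SyntheticSpec, rng, cell: int, kt0: int, channel: str, pos: np.ndarray
) -> pd.DataFrame:
    n = len(pos)
    return pd.DataFrame(
        {
            "cell_id": f"cell{cell:04d}",
            "sister_pair_id": [f"c{cell:04d}_sp{k // 2:04d}" for k in range(n)],
            "kinetochore_id": [f"c{cell:04d}_kt{kt0 + k:04d}" for k in range(n)],
            "channel": channel,
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "z_nm": pos[:, 2],
            "intensity": spec.background_level
            + spec.intensity_scale * rng.lognormal(0.0, 0.25, size=n),
            "background": spec.background_level * np.ones(n),
        }
    )


def _channel_shift(spec: SyntheticSpec, rng, channel: str) -> np.ndarray:
    base = np.zeros(3)
    if spec.chromatic_shift and channel in spec.chromatic_shift:
        base = np.asarray(spec.chromatic_shift[channel], dtype=float)
    jitter = (
        rng.standard_normal(3) * spec.chromatic_shift_sd
        if spec.chromatic_shift_sd > 0
        else 0.0
    )
    return base + jitter


def generate_pairs(spec: SyntheticSpec, _mu: float | None = None) -> SpotTable:
    """Two-channel table: channel 568 at p, channel 488 at p + mu·u + noise.

    u is uniform on the sphere per kinetochore; both spots get independent
    anisotropic localization noise; channel 488 additionally carries the
    per-cell chromatic offset.
    """
    mu = float(spec.mu if _mu is None else _mu)
    rng = np.random.default_rng(spec.seed)
    centers = _cell_centers(spec.n_cells, spec.cell_spacing)
    frames = []
    for c, center in enumerate(centers):
        nk = spec.kts_per_cell
        base = center + rng.normal(0.0, 500.0, size=(nk, 3))
        u = _uniform_sphere(rng, nk)
        pos_ref = base + _noise(rng, nk, spec.sigma_xy, spec.sigma_z)
        shift = _channel_shift(spec, rng, "488")
        pos_query = (
            base + mu * u + _noise(rng, nk, spec.sigma_xy, spec.sigma_z) + shift
        )
        frames.append(_rows(spec, rng, c, 0, "568", pos_ref))
        frames.append(_rows(spec, rng, c, 0, "488", pos_query))
    df = pd.concat(frames, ignore_index=True)
    meta = {"generator": "generate_pairs", "mu_true": mu, "seed": spec.seed}
    return SpotTable(data=df, metadata=meta)


def _triangle_vertices(triangle) -> np.ndarray:
    tri = np.asarray(triangle, dtype=float)
    if tri.shape == (3, 3):
        return tri
    if tri.shape == (3,):
        ab, bc, ac = tri
        # degenerate (collinear) triangles are allowed; impossible ones not
        if ab + bc < ac or ab + ac < bc or bc + ac < ab:
            raise ValueError(f"side lengths {tuple(tri)} violate the triangle inequality")
        x = (ab**2 + ac**2 - bc**2) / (2.0 * ab)
        y2 = ac**2 - x**2
        return np.array([[0.0, 0.0, 0.0], [ab, 0.0, 0.0], [x, np.sqrt(max(y2, 0.0)), 0.0]])
    raise ValueError("triangle must be three 3D vertices or three side lengths")


def generate_triples(spec: SyntheticSpec) -> SpotTable:
    """Three-channel table from a rigid marker triangle at random orientation.

    Vertices A, B, C map to channels 488, 568, 647. Each kinetochore gets
    an independent uniform 3D rotation of the (optionally vertex-blurred)
    triangle, plus per-spot localization noise and chromatic offsets.
    """
    if spec.triangle is None:
        raise ValueError("spec.triangle is required for generate_triples")
    verts = _triangle_vertices(spec.triangle)
    vertex_sd = np.asarray(spec.triangle_vertex_sd, dtype=float)
    rng = np.random.default_rng(spec.seed)
    centers = _cell_centers(spec.n_cells, spec.cell_spacing)
    frames = []
    for c, center in enumerate(centers):
        nk = spec.kts_per_cell
        base = center + rng.normal(0.0, 500.0, size=(nk, 3))
        rots = Rotation.random(nk, random_state=rng)
        for ch, vertex, sd in zip(_CHANNELS, verts, vertex_sd):
            local = vertex + sd * rng.standard_normal((nk, 3))
            pos = base + rots.apply(local)
            pos = pos + _noise(rng, nk, spec.sigma_xy, spec.sigma_z)
            pos = pos + _channel_shift(spec, rng, ch)
            frames.append(_rows(spec, rng, c, 0, ch, pos))
    df = pd.concat(frames, ignore_index=True)
    meta = {"generator": "generate_triples", "seed": spec.seed}
    return SpotTable(data=df, metadata=meta)


def generate_mixture(spec: SyntheticSpec) -> tuple[SpotTable, pd.DataFrame]:
    """Two-component mixture of true separations, with per-kinetochore labels.

    Emulates coexisting kinetochore subpopulations (e.g. checkpoint-active
    vs silenced) whose true separations differ. Returns the pooled table
    and a (kinetochore_id, component, mu_true) label table.
    """
    mus = np.atleast_1d(np.asarray(spec.mu, dtype=float))
    if mus.size != 2:
        raise ValueError("generate_mixture expects exactly two mu values")
    weights = np.asarray(
        spec.weights if spec.weights is not None else (0.5, 0.5), dtype=float
    )
    rng = np.random.default_rng(spec.seed)
    centers = _cell_centers(spec.n_cells, spec.cell_spacing)
    frames, labels = [], []
    for c, center in enumerate(centers):
        nk = spec.kts_per_cell
        comp = rng.choice(2, size=nk, p=weights)
        base = center + rng.normal(0.0, 500.0, size=(nk, 3))
        u = _uniform_sphere(rng, nk)
        pos_ref = base + _noise(rng, nk, spec.sigma_xy, spec.sigma_z)
        shift = _channel_shift(spec, rng, "488")
        pos_query = (
            base
            + mus[comp][:, None] * u
            + _noise(rng, nk, spec.sigma_xy, spec.sigma_z)
            + shift
        )
        ref_rows = _rows(spec, rng, c, 0, "568", pos_ref)
        frames.append(ref_rows)
        frames.append(_rows(spec, rng, c, 0, "488", pos_query))
        labels.append(
            pd.DataFrame(
                {
                    "kinetochore_id": ref_rows["kinetochore_id"],
                    "component": comp,
                    "mu_true": mus[comp],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    meta = {
        "generator": "generate_mixture",
        "mu_true": list(map(float, mus)),
        "weights": list(map(float, weights)),
        "seed": spec.seed,
    }
    return SpotTable(data=df, metadata=meta), pd.concat(labels, ignore_index=True)
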