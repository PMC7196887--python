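"""Inferential statistics on ensemble distance estimates.

All quantities operate on (mean, sd, n) triples produced by the Bayesian
distance correction, where sd is the posterior SD of the separation.
Comparisons use normal-theory z-tests (the posterior SDs play the role of
standard errors). The collinearity test asks whether three pairwise
distances among markers A, B, C are consistent with B lying on the A-C
axis: under collinearity d_AB + d_BC = d_AC, so the absolute excess
|d_AB + d_BC − d_AC| scaled by the propagated uncertainty is an upper-tail
z statistic (one-sided — only a positive excess indicates an off-axis
marker; the absolute value makes the statistic invariant to which short
side carries the estimation error).

Also here: the nematic order parameter N = Δ_EC / Δ_structural that maps a
measured ensemble separation onto the alignment of the underlying rod-like
complexes (N = 1 fully aligned, N = 0 isotropic), its hinge-angle
constraint curve, the effective cell number (inverse Simpson index of
per-cell kinetochore counts, a pseudo-replication guard), and the contour
length of a disordered polypeptide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DistanceEstimate",
    "TriangleMeasurement",
    "NematicEstimate",
    "collinearity_test",
    "compare_conditions",
    "difference",
    "percent_reduction",
    "nematic_order",
    "nematic_hinge_curve",
    "structural_end_to_end",
    "effective_cell_number",
    "predicted_path_length",
]

#: Contour length per residue (nm) for a maximally extended disordered
#: chain, the scale under which 300 aa span ~64 nm.
NM_PER_RESIDUE = 64.0 / 300.0


@dataclass(frozen=True)
class DistanceEstimate:
    """A labeled ensemble separation: mean ± sd (nm), n kinetochores."""

    mean: float
    sd: float
    n: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class TriangleMeasurement:
    """Three pairwise distances AB, BC, AC from a 3-fluorophore experiment.

    AC is the candidate long side (A—B—C ordering asserted by the caller).
    """

    ab: DistanceEstimate
    bc: DistanceEstimate
    ac: DistanceEstimate

    @property
    def sides(self) -> tuple[DistanceEstimate, DistanceEstimate, DistanceEstimate]:
        return (self.ab, self.bc, self.ac)


@dataclass(frozen=True)
class NematicEstimate:
    order: float
    se: float
    structural_distance: float


def _upper_tail(z: float) -> float:
    """P(Z > z) for standard normal Z (shared kernel for all z-tests)."""
    return float(stats.norm.sf(z))


def collinearity_test(t: TriangleMeasurement) -> tuple[float, float]:
    """One-sided z-test of collinearity for a 3-marker triangle.

    z = |mean_AB + mean_BC − mean_AC| / sqrt(sd_AB² + sd_BC² + sd_AC²),
    p = upper-tail standard normal probability. Small p rejects
    collinearity (the middle marker is off the A-C axis).
    """
    dev = abs(t.ab.mean + t.bc.mean - t.ac.mean)
    se = float(np.sqrt(t.ab.sd**2 + t.bc.sd**2 + t.ac.sd**2))
    z = dev / se
    return z, _upper_tail(z)


def compare_conditions(
    a: DistanceEstimate, b: DistanceEstimate
) -> tuple[DistanceEstimate, float, float]:
    """Two-sided z-test for a difference between two independent estimates.

    Returns (difference ± propagated sd, z, two-sided p).
    """
    d = difference(a, b)
    z = abs(d.mean) / d.sd
    return d, z, 2.0 * _upper_tail(z)


def difference(a: DistanceEstimate, b: DistanceEstimate) -> DistanceEstimate:
    """Signed offset a − b with root-sum-square uncertainty."""
    return DistanceEstimate(
        mean=a.mean - b.mean,
        sd=float(np.hypot(a.sd, b.sd)),
        label=f"{a.label} - {b.label}".strip(" -"),
    )


def percent_reduction(before: DistanceEstimate, after: DistanceEstimate) -> float:
    """Relative reduction (before − after)/before, as a percentage."""
    if before.mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (before.mean - after.mean) / before.mean


def nematic_order(
    delta_ec: DistanceEstimate, structural_distance: float
) -> NematicEstimate:
    """Nematic order N = Δ_EC / Δ_structural with propagated uncertainty.

    Δ_structural is the end-to-end distance of a single complex in the
    assumed conformation; the measured ensemble separation shrinks by the
    alignment factor N of the rod population.
    """
    if structural_distance <= 0:
        raise ValueError("structural distance must be positive")
    return NematicEstimate(
        order=delta_ec.mean / structural_distance,
        se=delta_ec.sd / structural_distance,
        structural_distance=structural_distance,
    )


def structural_end_to_end(arm_short: float, arm_long: float, hinge_deg) -> np.ndarray:
    """End-to-end distance of a two-arm rod at hinge angle θ (law of cosines).

    θ is the inter-arm angle at the hinge: 180° straight, 0° fully folded.
    Angles beyond 180° (over-straightened) are handled by the evenness of
    the cosine — d(θ) is symmetric about 180° and periodic in 360°.
    """
    theta = np.deg2rad(np.asarray(hinge_deg, dtype=float))
    d2 = (
        arm_short**2
        + arm_long**2
        - 2.0 * arm_short * arm_long * np.cos(theta)
    )
    return np.sqrt(np.maximum(d2, 0.0))


def nematic_hinge_curve(
    delta_ec: DistanceEstimate,
    arm_short: float = 16.0,
    arm_long: float = 35.0,
    hinge_grid=None,
) -> dict[str, np.ndarray]:
    """Nematic order consistent with a measured Δ_EC at each hinge angle.

    For each hinge angle θ the structural end-to-end distance d(θ) follows
    the law of cosines; the order that reconciles the measurement with that
    conformation is N(θ) = Δ_EC/d(θ), with a 95% band (mean ± 1.96 sd)/d(θ).
    Angles where d(θ) = 0 (equal arms fully folded) are flagged undefined.

    Default arms 16/35 nm are the unique pair giving 51 nm straight and
    19 nm fully folded.
    """
    if arm_short <= 0 or arm_long <= 0:
        raise ValueError("arm lengths must be positive")
    grid = (
        np.arange(0.0, 360.0, 1.0) if hinge_grid is None
        else np.asarray(hinge_grid, dtype=float)
    )
    d = structural_end_to_end(arm_short, arm_long, grid)
    undefined = d <= 1e-12
    with np.errstate(divide="ignore"):
        n = np.where(undefined, np.nan, delta_ec.mean / np.where(undefined, 1, d))
        lo = np.where(
            undefined, np.nan, (delta_ec.mean - 1.96 * delta_ec.sd) / np.where(undefined, 1, d)
        )
        hi = np.where(
            undefined, np.nan, (delta_ec.mean + 1.96 * delta_ec.sd) / np.where(undefined, 1, d)
        )
    return {
        "hinge_deg": grid,
        "structural_nm": d,
        "order": n,
        "ci_low": lo,
        "ci_high": hi,
        "undefined": undefined,
    }


def effective_cell_number(counts) -> float:
    """Inverse Simpson index 1/Σ p_i² of per-cell kinetochore counts.

    Equals the cell count when kinetochores are spread evenly and degrades
    toward 1 when a single cell dominates — the effective number of
    independent cells behind a pooled estimate.
    """
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0:
        raise ValueError("no cells")
    if np.any(c <= 0):
        raise ValueError("counts must be positive")
    p = c / c.sum()
    return float(1.0 / np.sum(p**2))


def predicted_path_length(n_residues: int, nm_per_residue: float = NM_PER_RESIDUE) -> float:
    """Contour length of a disordered region: residues × scale (nm)."""
    if n_residues < 0:
        raise ValueError("residue count must be non-negative")
    return float(n_residues * nm_per_residue)
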