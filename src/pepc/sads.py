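"""Species-associated difference scattering curves and their PEPC distortion.

Removing the trivial span from the data also removes the in-span part of every
species curve: the SADS extracted from PEPC-treated data is the perpendicular
component SADS_⊥ = SADS − Σᵢ dᵢ·trvᵢ of the true curve.  This module

* decomposes a SADS against the trivial space (the d coefficients),
* undoes the distortion for a *candidate* true curve by the analytic linear
  solve for correction weights α (ideally α = d), with a χ² that discriminates
  candidate structures, and
* provides a toy Debye-equation calculator (q-independent scattering factors)
  for generating candidate and synthetic species curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .dataset import Curve, ScatteringDataset, TrivialSet, ValidationError
from .projection import pepc_multi

__all__ = [
    "SADSSet",
    "SADSDecomposition",
    "CorrectionResult",
    "ToyStructure",
    "decompose_sads",
    "correct_sads",
    "rank_candidates",
    "debye_scattering",
    "sads_from_structures",
    "cage_curve",
]


@dataclass
class SADSSet:
    """One difference curve per species, all on a shared q-grid.

    ``kind`` distinguishes true curves (``real``), curves extracted from
    PEPC-treated data (``pepc``) and distortion-corrected curves
    (``corrected``).
    """

    species: list
    curves: list
    kind: str = "real"
    residual_norms: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.species) != len(self.curves):
            raise ValidationError("one curve per species required")
        if len(self.curves) == 0:
            raise ValidationError("empty SADS set")
        q0 = self.curves[0].q
        for c in self.curves:
            if not np.array_equal(c.q, q0):
                raise ValidationError("SADS curves must share one q-grid")
        if self.kind not in ("real", "pepc", "corrected"):
            raise ValidationError(f"unknown SADS kind {self.kind!r}")

    @property
    def q(self) -> np.ndarray:
        return self.curves[0].q

    @property
    def n_species(self) -> int:
        return len(self.species)

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([c.values for c in self.curves])


@dataclass
class SADSDecomposition:
    parallel: Curve
    perpendicular: Curve
    d_coeffs: np.ndarray


@dataclass
class CorrectionResult:
    corrected: Curve
    alpha: np.ndarray
    chi2: float
    dof: int


@dataclass
class ToyStructure:
    """Point-atom structure with q-independent scattering factors f (≈ Z)."""

    atoms: list  # (label, f, (x, y, z) in Å)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValidationError("structure needs at least one atom")
        for label, f, pos in self.atoms:
            if not np.isfinite(f) or f <= 0:
                raise ValueError(f"atom {label!r}: scattering factor must be positive")
            if not np.all(np.isfinite(np.asarray(pos, dtype=float))):
                raise ValidationError(f"atom {label!r}: non-finite coordinates")

    def factors(self) -> np.ndarray:
        return np.array([f for _, f, _ in self.atoms], dtype=float)

    def positions(self) -> np.ndarray:
        return np.array([pos for _, _, pos in self.atoms], dtype=float).reshape(-1, 3)


def decompose_sads(sads: Curve, trivials: TrivialSet) -> SADSDecomposition:
    """Split a SADS into its in-span and perpendicular parts.

    The parallel part is the minimum-norm least squares projection onto
    span(trivials); d_coeffs are the projection weights — the same solve as
    :func:`pepc.projection.pepc_multi` restricted to one column.
    """
    if not np.array_equal(sads.q, trivials.q):
        raise ValidationError("SADS and trivial set are not on the same q-grid")
    T = trivials.as_matrix()
    d, _, _, _ = scipy.linalg.lstsq(T, sads.values[:, None], cond=1e-10)
    d = d[:, 0]
    par = T @ d
    return SADSDecomposition(
        parallel=Curve(sads.q.copy(), par, label=f"{sads.label} (parallel)"),
        perpendicular=Curve(sads.q.copy(), sads.values - par, label=f"{sads.label} (perp)"),
        d_coeffs=d,
    )


def correct_sads(
    sads_pepc: Curve,
    trivials: TrivialSet,
    candidate: Curve,
    sigma: Optional[Curve] = None,
) -> CorrectionResult:
    """Correct a PEPC-distorted SADS against a candidate true curve.

    Solves the *linear* least squares  min_α ‖sads_pepc + Σᵢ αᵢ·trvᵢ −
    candidate‖ (σ-weighted when ``sigma`` is given).  The correction weights
    are determined analytically per candidate — they are never free nonlinear
    fitting parameters.  χ² is the (weighted) residual sum of squares per
    degree of freedom, dof = n_q − m.
    """
    if not (np.array_equal(sads_pepc.q, trivials.q) and np.array_equal(sads_pepc.q, candidate.q)):
        raise ValidationError("inputs are not on the same q-grid")
    m = trivials.m
    n_q = sads_pepc.n_q
    if m >= n_q:
        raise ValidationError(f"underdetermined correction: m = {m} ≥ n_q = {n_q}")
    T = trivials.as_matrix()
    rhs = candidate.values - sads_pepc.values
    if sigma is not None:
        w = 1.0 / np.where(sigma.values > 0, sigma.values, np.inf)
        Tw = T * w[:, None]
        rhsw = rhs * w
    else:
        Tw, rhsw = T, rhs
    alpha, _, _, _ = scipy.linalg.lstsq(Tw, rhsw[:, None], cond=1e-10)
    alpha = alpha[:, 0]
    corrected_vals = sads_pepc.values + T @ alpha
    resid = corrected_vals - candidate.values
    if sigma is not None:
        resid = resid * w
    dof = n_q - m
    chi2 = float(resid @ resid) / dof
    return CorrectionResult(
        corrected=Curve(sads_pepc.q.copy(), corrected_vals, label=f"{sads_pepc.label} (corrected)"),
        alpha=alpha,
        chi2=chi2,
        dof=dof,
    )


def rank_candidates(
    sads_pepc: Curve,
    trivials: TrivialSet,
    candidates: SADSSet,
    sigma: Optional[Curve] = None,
) -> list:
    """Rank candidate species curves by correction χ², ascending.

    Only the correct structure can be reconciled with the PEPC-distorted
    curve by an in-span correction, so the generating structure attains the
    smallest χ².  Ties break by candidate order.
    """
    if candidates.n_species < 2:
        raise ValueError("need at least 2 candidates to rank")
    scored = []
    for idx, (label, cand) in enumerate(zip(candidates.species, candidates.curves)):
        res = correct_sads(sads_pepc, trivials, cand, sigma=sigma)
        scored.append((res.chi2, idx, label))
    scored.sort(key=lambda s: (s[0], s[1]))
    return [(label, chi2) for chi2, _, label in scored]


def debye_scattering(structure: ToyStructure, q: np.ndarray) -> Curve:
    """Orientation-averaged scattering of a rigid structure (Debye equation).

    S(q) = Σᵢ Σⱼ fᵢ fⱼ sin(q·rᵢⱼ)/(q·rᵢⱼ), with the r → 0 limit taken as 1.
    Exact q → 0⁺ limit: (Σ fᵢ)².
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be strictly positive")
    f = structure.factors()
    pos = structure.positions()
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))  # [n, n]
    qr = q[:, None, None] * r[None, :, :]
    sinc = np.where(qr == 0.0, 1.0, np.sin(np.where(qr == 0.0, 1.0, qr)) / np.where(qr == 0.0, 1.0, qr))
    ff = f[:, None] * f[None, :]
    s = np.einsum("qij,ij->q", sinc, ff)
    return Curve(q.copy(), s, label="S(q)")


def sads_from_structures(
    excited: ToyStructure,
    ground: ToyStructure,
    q: np.ndarray,
    cage: Optional[Curve] = None,
) -> Curve:
    """Difference curve of an excited species: S_exc(q) − S_gnd(q) [+ cage]."""
    s = debye_scattering(excited, q).values - debye_scattering(ground, q).values
    if cage is not None:
        if not np.array_equal(np.asarray(q, dtype=float), cage.q):
            raise ValidationError("cage curve not on the requested q-grid")
        s = s + cage.values
    return Curve(np.asarray(q, dtype=float).copy(), s, label="SADS")


def cage_curve(q: np.ndarray, amplitude: float, r0: float, width: float) -> Curve:
    """Parameterized solute–solvent cage term: damped sinusoid in q.

    A·exp(−q²w²)·sin(q·r₀)/(q·r₀) — a stand-in with the oscillation period of
    a characteristic solute–solvent distance r₀ (Å), used where pair
    distribution functions from molecular dynamics would otherwise enter.
    """
    q = np.asarray(q, dtype=float)
    qr = q * r0
    vals = amplitude * np.exp(-(q * width) ** 2) * np.where(qr == 0, 1.0, np.sin(qr) / np.where(qr == 0, 1.0, qr))
    return Curve(q.copy(), vals, label="cage")
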