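"""Solvent hydrodynamics reconstruction.

Once the solute kinetics f_k(t) and the (corrected) species curves SADS_k(q)
are known, the solvent-only term is what is left of the experimental data:

    ΔS_solvent(q, t) = ΔS_exp(q, t) − (1/R)·Σ_k f_k(t)·SADS_k(q)
                     = ΔT(t)·(∂S/∂T)ρ + Δρ(t)·(∂S/∂ρ)T.

A per-delay linear solve (non-orthogonal decomposition, NOD) on the two
solvent differentials then yields the temperature and density time courses.
For solvents whose two differentials are nearly parallel (water), the
two-term solve is ill-conditioned; a temperature-only mode fits a single
differential, as is common practice for aqueous data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset import ScatteringDataset, TrivialSet, ValidationError
from .kinetics import ConcentrationMatrix
from .sads import SADSSet

__all__ = ["HydroTrace", "subtract_solute_related", "nod_solvent"]


@dataclass
class HydroTrace:
    """Time traces of solvent temperature and density change.

    Units follow the basis curves: if (∂S/∂T)ρ is per kelvin, ``dT`` is in K;
    likewise for ``drho``.  ``condition_number`` is the singular-value ratio
    of the column-normalized basis matrix (geometry only);
    ``ill_conditioned`` flags values above the warning threshold.
    """

    t: np.ndarray
    dT: np.ndarray
    drho: np.ndarray
    condition_number: float
    mode: str
    ill_conditioned: bool = False
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dT = np.asarray(self.dT, dtype=float)
        self.drho = np.asarray(self.drho, dtype=float)
        if self.dT.size != self.t.size or self.drho.size != self.t.size:
            raise ValidationError("trace lengths must match t")
        if self.condition_number < 1.0:
            raise ValidationError("condition number must be ≥ 1")


def subtract_solute_related(
    ds_exp: ScatteringDataset, sads: SADSSet, conc: ConcentrationMatrix
) -> ScatteringDataset:
    """Remove the solute-related term (1/R)·Σ_k f_k(t)·SADS_k(q) from the data."""
    if sads.kind not in ("real", "corrected"):
        raise ValueError("subtraction requires true (real/corrected) SADS curves")
    if conc.species is not None and list(conc.species) != list(sads.species):
        raise ValueError(
            f"species mismatch: SADS {list(sads.species)} vs kinetics {list(conc.species)}"
        )
    if sads.n_species != conc.C.shape[1]:
        raise ValueError("number of SADS curves and concentration columns differ")
    if not np.array_equal(ds_exp.q, sads.q):
        raise ValidationError("SADS and dataset are not on the same q-grid")
    if conc.t.size != ds_exp.n_t or not np.allclose(conc.t, ds_exp.t, rtol=1e-9, atol=1e-12):
        raise ValueError("time axes differ")
    S = sads.as_matrix()
    residual = ds_exp.matrix - (S @ conc.C.T) / conc.R
    return ScatteringDataset(
        ds_exp.q.copy(), ds_exp.t.copy(), residual,
        sigma=None if ds_exp.sigma is None else ds_exp.sigma.copy(),
        meta=dict(ds_exp.meta),
    )


def nod_solvent(
    residual: ScatteringDataset,
    basis: TrivialSet,
    sigma_weighted: bool = False,
    mode: str = "two_term",
    cond_warn: float = 100.0,
) -> HydroTrace:
    """Per-delay linear decomposition of the solvent term onto its differentials.

    ``two_term`` fits ΔT and Δρ simultaneously on a basis of two curves;
    ``temperature_only`` fits a single amplitude on the first curve, the
    standard treatment for water where the two differentials are nearly
    indistinguishable.  No coupling across delays is imposed.
    """
    if mode not in ("two_term", "temperature_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if basis.m not in (1, 2):
        raise ValueError("solvent basis must hold 1 or 2 curves")
    if mode == "two_term" and basis.m != 2:
        raise ValueError("two_term mode needs exactly 2 basis curves")
    if not np.array_equal(residual.q, basis.q):
        raise ValidationError("basis and residual are not on the same q-grid")

    n_terms = 2 if mode == "two_term" else 1
    B = basis.as_matrix()[:, :n_terms]
    norms = np.linalg.norm(B, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate (zero) basis curve")
    svals = np.linalg.svd(B / norms, compute_uv=False)
    cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else math.inf

    n_t = residual.n_t
    coeffs = np.zeros((n_terms, n_t))
    if sigma_weighted and residual.sigma is not None:
        for j in range(n_t):
            w = 1.0 / np.where(residual.sigma[:, j] > 0, residual.sigma[:, j], np.inf)
            Bw = B * w[:, None]
            coeffs[:, j], *_ = np.linalg.lstsq(Bw, residual.matrix[:, j] * w, rcond=None)
    else:
        coeffs, *_ = np.linalg.lstsq(B, residual.matrix, rcond=None)
        coeffs = np.atleast_2d(coeffs)

    dT = coeffs[0]
    drho = coeffs[1] if n_terms == 2 else np.zeros(n_t)
    return HydroTrace(
        t=residual.t.copy(), dT=dT, drho=drho,
        condition_number=cond, mode=mode,
        ill_conditioned=bool(cond > cond_warn),
        units={"dT": "K (per basis-curve unit)", "drho": "kg m^-3 (per basis-curve unit)"},
    )
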