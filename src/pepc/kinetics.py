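"""Solute kinetics from PEPC-treated data.

The analysis chain is the one standard in time-resolved solution scattering:
decompose ΔS(q, t) by SVD, keep the components whose singular values and
lag-1 autocorrelations indicate signal rather than noise, fit the surviving
right singular vectors globally with a sum of exponentials sharing common
time constants (each convolved with a Gaussian instrument response), and
finally extract species-associated difference curves (SADS) under a fixed
first-order kinetic model (kinetics-constrained analysis, KCA).

The global fit is a variable-projection least squares: for trial time
constants the per-RSV amplitudes are eliminated analytically by a linear
solve, and only the log-τ (optionally t0) remain nonlinear.  This keeps the
fit deterministic and immune to amplitude/constant degeneracies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.special

from .dataset import ScatteringDataset, ValidationError
from .sads import Curve, SADSSet

__all__ = [
    "SVDResult",
    "KineticModel",
    "GlobalFitResult",
    "ConcentrationMatrix",
    "FitFailureError",
    "ConditioningError",
    "svd_decompose",
    "low_rank_approximation",
    "autocorrelation",
    "select_rank",
    "irf_exp",
    "global_fit_rsvs",
    "concentration_profiles",
    "extract_sads",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class FitFailureError(RuntimeError):
    """Every multi-start of the global fit failed to converge."""


class ConditioningError(RuntimeError):
    """A linear system is too ill-conditioned to invert meaningfully."""


# ---------------------------------------------------------------------------
# SVD and rank diagnostics


@dataclass
class SVDResult:
    """Economy SVD of a dataset with autocorrelation diagnostics.

    ``lsv``/``rsv`` hold the left/right singular vectors as columns,
    sign-fixed so each LSV's largest-magnitude element is positive.
    ``q`` and ``t`` are carried along so downstream fits know the axes.
    """

    q: np.ndarray
    t: np.ndarray
    lsv: np.ndarray
    sv: np.ndarray
    rsv: np.ndarray
    lsv_autocorr: np.ndarray
    rsv_autocorr: np.ndarray


def autocorrelation(v: np.ndarray) -> float:
    """Lag-1 autocorrelation Σ vᵢvᵢ₊₁ / Σ vᵢ² used as a signal/noise score.

    Smooth singular vectors score near 1, white noise near 0.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("autocorrelation needs a 1-D vector of length ≥ 2")
    denom = float(v @ v)
    if denom == 0.0:
        raise ValueError("autocorrelation of the zero vector is undefined")
    return float(v[:-1] @ v[1:]) / denom


def svd_decompose(ds: ScatteringDataset) -> SVDResult:
    """Economy SVD of ΔS(q, t) with a deterministic sign convention."""
    if not np.all(np.isfinite(ds.matrix)):
        raise ValidationError("non-finite entries in matrix")
    U, s, Vt = np.linalg.svd(ds.matrix, full_matrices=False)
    V = Vt.T
    # sign fix: largest-|.| element of each LSV made positive
    for i in range(s.size):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    lsv_ac = np.array([autocorrelation(U[:, i]) for i in range(s.size)])
    rsv_ac = np.array([autocorrelation(V[:, i]) for i in range(s.size)])
    return SVDResult(
        q=ds.q.copy(), t=ds.t.copy(), lsv=U, sv=s, rsv=V,
        lsv_autocorr=lsv_ac, rsv_autocorr=rsv_ac,
    )


def low_rank_approximation(svd: SVDResult, k: int) -> np.ndarray:
    """Rank-k reconstruction lsv[:, :k] · diag(sv[:k]) · rsv[:, :k]ᵀ."""
    k = int(k)
    return (svd.lsv[:, :k] * svd.sv[:k]) @ svd.rsv[:, :k].T


def select_rank(
    svd: SVDResult,
    ac_threshold: float = 0.6,
    sv_ratio_floor: float = 1e-3,
    override: Optional[int] = None,
) -> int:
    """Number of significant SVD components.

    Largest k such that components 1..k *all* pass the LSV and RSV
    autocorrelation threshold and the singular-value ratio floor; an explicit
    ``override`` wins.  k = 0 means the data are indistinguishable from noise.
    """
    if override is not None:
        return int(override)
    if not (0.0 < ac_threshold < 1.0) or not (0.0 < sv_ratio_floor < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    k = 0
    sv0 = svd.sv[0] if svd.sv.size else 0.0
    for i in range(svd.sv.size):
        ok = (
            svd.lsv_autocorr[i] > ac_threshold
            and svd.rsv_autocorr[i] > ac_threshold
            and sv0 > 0
            and svd.sv[i] / sv0 > sv_ratio_floor
        )
        if not ok:
            break
        k = i + 1
    return k


# ---------------------------------------------------------------------------
# IRF-convolved exponential


def irf_exp(t, tau: float, t0: float = 0.0, irf_fwhm: float = 0.0) -> np.ndarray:
    """Causal exponential decay convolved with a Gaussian IRF, evaluated exactly.

    With σ = irf_fwhm / (2√(2 ln 2)):

        h(t) = ½ exp(σ²/(2τ²) − (t−t0)/τ) · erfc(σ/(τ√2) − (t−t0)/(σ√2))

    τ = inf gives the IRF-broadened step ½·erfc(−(t−t0)/(σ√2)); irf_fwhm = 0
    gives the sharp exponential exp(−(t−t0)/τ) for t ≥ t0, else 0.  The
    evaluation switches to the scaled complement erfcx where the direct
    exponent would overflow, so the result is stable over arbitrarily wide
    delay ranges.
    """
    t = np.asarray(t, dtype=float)
    if irf_fwhm < 0:
        raise ValueError("irf_fwhm must be nonnegative")
    finite_tau = np.isfinite(tau)
    if finite_tau and tau <= 0:
        raise ValueError("tau must be positive (or inf for a step)")
    dt = t - t0
    if irf_fwhm == 0.0:
        if not finite_tau:
            return np.where(dt >= 0, 1.0, 0.0)
        out = np.zeros_like(dt)
        pos = dt >= 0
        out[pos] = np.exp(-dt[pos] / tau)
        return out
    sigma = irf_fwhm * _FWHM_TO_SIGMA
    b = dt / (sigma * math.sqrt(2.0))
    if not finite_tau:
        return 0.5 * scipy.special.erfc(-b)
    a = sigma / (tau * math.sqrt(2.0))
    z = a - b
    out = np.empty_like(dt)
    neg = z < 0
    # z < 0: exponent a² − 2ab < −a²/2 ⇒ no overflow in the direct form
    out[neg] = 0.5 * np.exp(a * a - 2.0 * a * b[neg]) * scipy.special.erfc(z[neg])
    # z ≥ 0: erfcx(z)·exp(−b²) — both factors ≤ 1
    out[~neg] = 0.5 * scipy.special.erfcx(z[~neg]) * np.exp(-b[~neg] ** 2)
    return out


# ---------------------------------------------------------------------------
# global multiexponential fit of RSVs


@dataclass
class GlobalFitResult:
    """Shared time constants fitted simultaneously to several RSVs."""

    taus: np.ndarray            # ps, ascending
    tau_stderr: np.ndarray      # ps, same order
    amplitudes: np.ndarray      # [n_rsv × n_exp]
    offsets: Optional[np.ndarray]  # per-RSV constant, or None
    t0: float
    irf_fwhm: float
    residual_norm: float
    covariance: np.ndarray      # over free nonlinear params (log10 τ [, t0])
    n_starts: int


def _design_matrix(t, taus, t0, irf_fwhm, offset):
    cols = [irf_exp(t, tau, t0, irf_fwhm) for tau in taus]
    if offset:
        cols.append(np.ones_like(np.asarray(t, dtype=float)))
    return np.column_stack(cols)


def global_fit_rsvs(
    svd: SVDResult,
    k: int,
    n_exp: int,
    irf_fwhm: float = 0.0,
    t0: float = 0.0,
    fit_t0: bool = False,
    sv_weighted: bool = False,
    offset: bool = False,
    n_starts: int = 5,
) -> GlobalFitResult:
    """Fit the first k RSVs with Σⱼ Aᵢⱼ·irf_exp(t; τⱼ, t0, irf) globally.

    Time constants are shared across RSVs; amplitudes are free per RSV and
    eliminated analytically (variable projection).  τ is optimized in
    log10-space with bounds [0.1·Δt_min, 10·t_max] over a deterministic grid
    of ``n_starts`` log-shifted initial vectors; the best start wins, ties
    broken by the lexicographically smallest τ vector.
    """
    if k < 1 or k > svd.sv.size:
        raise ValueError(f"k = {k} out of range for {svd.sv.size} components")
    if n_exp < 1:
        raise ValueError("n_exp must be ≥ 1")
    t = svd.t
    Y = svd.rsv[:, :k].copy()
    if sv_weighted:
        Y = Y * svd.sv[:k]

    dts = np.diff(t)
    lo = 0.1 * float(np.min(dts))
    hi = 10.0 * float(np.max(t))
    if lo <= 0 or hi <= lo:
        raise ValueError("time axis cannot bracket positive time constants")
    llo, lhi = math.log10(lo), math.log10(hi)
    span = lhi - llo

    def residuals(p):
        taus = 10.0 ** p[:n_exp]
        t0_val = p[n_exp] if fit_t0 else t0
        M = _design_matrix(t, taus, t0_val, irf_fwhm, offset)
        A, *_ = np.linalg.lstsq(M, Y, rcond=None)
        return (M @ A - Y).ravel()

    base_frac = (np.arange(1, n_exp + 1)) / (n_exp + 1.0)
    shifts = np.linspace(-span / 8.0, span / 8.0, n_starts) if n_starts > 1 else [0.0]
    lower = np.full(n_exp, llo)
    upper = np.full(n_exp, lhi)
    if fit_t0:
        lower = np.append(lower, t0 - 10.0 * max(irf_fwhm, lo))
        upper = np.append(upper, t0 + 10.0 * max(irf_fwhm, lo))

    best = None
    diagnostics = []
    for s in shifts:
        p0 = llo + base_frac * span + s
        p0 = np.clip(p0, llo + 1e-6, lhi - 1e-6)
        if fit_t0:
            p0 = np.append(p0, t0)
        try:
            res = scipy.optimize.least_squares(
                residuals, p0, bounds=(lower, upper), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception as exc:  # noqa: BLE001 — collected into diagnostics
            diagnostics.append(f"start {p0}: {exc}")
            continue
        if not np.isfinite(res.cost):
            diagnostics.append(f"start {p0}: non-finite cost")
            continue
        key = (res.cost, tuple(np.sort(res.x[:n_exp])))
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise FitFailureError("all multi-starts failed: " + "; ".join(diagnostics))
    res = best[1]

    taus = 10.0 ** res.x[:n_exp]
    t0_fit = float(res.x[n_exp]) if fit_t0 else t0
    order = np.argsort(taus)
    taus = taus[order]
    M = _design_matrix(t, taus, t0_fit, irf_fwhm, offset)
    A, *_ = np.linalg.lstsq(M, Y, rcond=None)
    amplitudes = A[:n_exp, :].T  # [k × n_exp], already in sorted-τ order via M
    offs = A[n_exp, :].copy() if offset else None
    resid = (M @ A - Y).ravel()
    rss = float(resid @ resid)

    # covariance of the nonlinear params from the varpro Jacobian
    J = res.jac
    n_free = J.shape[1]
    dof = max(resid.size - n_free - A.size, 1)
    s2 = rss / dof
    JtJ = J.T @ J
    cov = s2 * np.linalg.pinv(JtJ)
    # reorder the log10 τ block to ascending τ
    perm = list(order) + ([n_exp] if fit_t0 else [])
    cov = cov[np.ix_(perm, perm)]
    sig_log = np.sqrt(np.clip(np.diag(cov)[:n_exp], 0.0, None))
    tau_stderr = math.log(10.0) * taus * sig_log

    return GlobalFitResult(
        taus=taus, tau_stderr=tau_stderr, amplitudes=amplitudes, offsets=offs,
        t0=t0_fit, irf_fwhm=irf_fwhm, residual_norm=math.sqrt(rss),
        covariance=cov, n_starts=len(list(shifts)),
    )


# ---------------------------------------------------------------------------
# kinetic models and concentration profiles


@dataclass
class KineticModel:
    """First-order kinetic scheme with Gaussian IRF.

    ``sequential``: a chain A₁ → A₂ → ... → Aₙ → ground with one time
    constant per species (``taus``, ps).  ``rate_matrix``: an arbitrary
    first-order network given by K (ps⁻¹), df/dt = K f, columns summing to
    ≤ 0 (leakage to a non-scattering ground state).
    """

    species: list
    scheme: str = "sequential"
    taus: Optional[np.ndarray] = None
    K: Optional[np.ndarray] = None
    t0: float = 0.0
    irf_fwhm: float = 0.0
    initial_fractions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.species)
        if n == 0:
            raise ValidationError("model needs at least one species")
        if self.scheme == "sequential":
            if self.taus is None:
                raise ValidationError("sequential scheme requires taus")
            self.taus = np.asarray(self.taus, dtype=float)
            if self.taus.size != n:
                raise ValidationError("need one time constant per species")
            if np.any(self.taus <= 0):
                raise ValidationError("time constants must be strictly positive")
        elif self.scheme == "rate_matrix":
            if self.K is None:
                raise ValidationError("rate_matrix scheme requires K")
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (n, n):
                raise ValidationError("K must be n_species × n_species")
            if np.any(self.K.sum(axis=0) > 1e-12):
                raise ValidationError("columns of K must sum to ≤ 0 (mass conservation)")
        else:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if self.irf_fwhm < 0:
            raise ValidationError("irf_fwhm must be nonnegative")
        if self.initial_fractions is None:
            f0 = np.zeros(n)
            f0[0] = 1.0
            self.initial_fractions = f0
        else:
            self.initial_fractions = np.asarray(self.initial_fractions, dtype=float)
            if self.initial_fractions.size != n or abs(self.initial_fractions.sum() - 1.0) > 1e-9:
                raise ValidationError("initial_fractions must sum to 1")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def rate_matrix(self) -> np.ndarray:
        """The network's rate matrix in ps⁻¹ (built from taus when sequential)."""
        if self.scheme == "rate_matrix":
            return self.K
        n = self.n_species
        K = np.zeros((n, n))
        rates = 1.0 / self.taus
        for i in range(n):
            K[i, i] = -rates[i]
            if i + 1 < n:
                K[i + 1, i] = rates[i]
        return K


@dataclass
class ConcentrationMatrix:
    """Molar fractions f_k(t) under a kinetic model; rows sum to ≤ 1."""

    t: np.ndarray
    C: np.ndarray  # [n_t × n_s]
    R: float = 1.0
    species: Optional[list] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape[0] != self.t.size:
            raise ValidationError("C rows must match t")
        if self.R <= 0:
            raise ValidationError("R must be positive")
        if np.any(self.C < -1e-9) or np.any(self.C > 1.0 + 1e-9):
            raise ValidationError("fractions must lie in [0, 1]")
        if np.any(self.C.sum(axis=1) > 1.0 + 1e-9):
            raise ValidationError("row sums must be ≤ 1 (ground state implicit)")
        self.C = np.clip(self.C, 0.0, 1.0)


def _bateman_modes(rates: np.ndarray, start: int, j: int):
    """Coefficients cᵢ of the chain solution f_j(t) = Σᵢ cᵢ·exp(−kᵢ t) for a
    chain seeded at ``start`` with unit population (δ-pulse, no IRF)."""
    if j < start:
        return {}
    if j == start:
        return {start: 1.0}
    pref = np.prod(rates[start:j])
    out = {}
    for i in range(start, j + 1):
        denom = 1.0
        for l in range(start, j + 1):
            if l != i:
                denom *= rates[l] - rates[i]
        out[i] = pref / denom
    return out


def _ode_fallback(model: KineticModel, t: np.ndarray) -> np.ndarray:
    """Numerical route for degenerate eigenvalues: matrix exponential of the
    δ-pulse response, convolved with the Gaussian IRF by Gauss–Hermite
    quadrature."""
    K = model.rate_matrix()
    f0 = model.initial_fractions
    sigma = model.irf_fwhm * _FWHM_TO_SIGMA

    def f_delta(u):
        if u < 0:
            return np.zeros_like(f0)
        return scipy.linalg.expm(K * u) @ f0

    if sigma == 0.0:
        return np.array([f_delta(ti - model.t0) for ti in t])
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    # f(t) = ∫ N(s; 0, σ) f_δ(t − t0 − s) ds
    out = np.zeros((t.size, model.n_species))
    wsum = weights.sum()
    for x, w in zip(nodes, weights):
        shift = sigma * x
        out += (w / wsum) * np.array([f_delta(ti - model.t0 - shift) for ti in t])
    return out


def concentration_profiles(model: KineticModel, t) -> ConcentrationMatrix:
    """Evaluate f_k(t) for a kinetic model, IRF included analytically.

    Sequential chains use Bateman closed forms with every exponential mode
    replaced by its Gaussian-convolved counterpart (:func:`irf_exp`); rate
    matrices are eigendecomposed with per-mode convolution.  Rates repeated
    within 1e-9 relative (non-diagonalizable limit) fall back to dense
    numerical propagation plus numerical convolution.
    """
    t = np.asarray(t, dtype=float)
    n = model.n_species

    if model.scheme == "sequential":
        rates = 1.0 / model.taus
        scale = np.max(rates)
        degenerate = False
        for i in range(n):
            for j in range(i + 1, n):
                if abs(rates[i] - rates[j]) < 1e-9 * scale:
                    degenerate = True
        if degenerate:
            C = _ode_fallback(model, t)
        else:
            E = np.column_stack(
                [irf_exp(t, 1.0 / k, model.t0, model.irf_fwhm) for k in rates]
            )  # [n_t × n]
            C = np.zeros((t.size, n))
            for start in range(n):
                pop = model.initial_fractions[start]
                if pop == 0.0:
                    continue
                for j in range(start, n):
                    for i, c in _bateman_modes(rates, start, j).items():
                        C[:, j] += pop * c * E[:, i]
    else:
        K = model.rate_matrix()
        lam, V = np.linalg.eig(K)
        scale = np.max(np.abs(lam)) if np.max(np.abs(lam)) > 0 else 1.0
        distinct = all(
            abs(lam[i] - lam[j]) > 1e-9 * scale
            for i in range(n) for j in range(i + 1, n)
        )
        if distinct and np.all(np.abs(lam.imag) < 1e-12 * scale) and np.all(lam.real < 1e-12):
            lam = lam.real
            V = V.real
            coef = np.linalg.solve(V, model.initial_fractions)
            C = np.zeros((t.size, n))
            for m_idx in range(n):
                tau_m = math.inf if abs(lam[m_idx]) < 1e-15 * scale else -1.0 / lam[m_idx]
                mode = irf_exp(t, tau_m, model.t0, model.irf_fwhm)
                C += np.outer(mode, coef[m_idx] * V[:, m_idx])
        else:
            C = _ode_fallback(model, t)

    # tolerate rounding just outside [0, 1]
    if np.any(C < -1e-6) or np.any(C > 1.0 + 1e-6):
        raise ValidationError("kinetic model produced fractions far outside [0, 1]")
    C = np.clip(C, 0.0, 1.0)
    return ConcentrationMatrix(t=t, C=C, R=1.0, species=list(model.species))


# ---------------------------------------------------------------------------
# kinetics-constrained SADS extraction


def extract_sads(
    ds_pepc: ScatteringDataset,
    conc: ConcentrationMatrix,
    svd_rank: Optional[int] = None,
    cond_limit: float = 1e8,
) -> SADSSet:
    """Extract SADS under a fixed kinetic model (KCA).

    Solves ΔS_PEPC ≈ (1/R)·SADS·Cᵀ in the least squares sense over time
    delays.  With ``svd_rank`` the data are first replaced by their rank-k
    truncation so each SADS is exactly a linear combination of the retained
    LSVs.  Per-species residual norms report the misfit along each species'
    normalized concentration profile.
    """
    if conc.t.size != ds_pepc.n_t or not np.allclose(conc.t, ds_pepc.t, rtol=1e-9, atol=1e-12):
        raise ValueError("concentration profile and dataset time axes differ")
    C = conc.C
    if C.shape[1] > C.shape[0]:
        raise ConditioningError("more species than time delays")
    svals = np.linalg.svd(C, compute_uv=False)
    cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else math.inf
    if not math.isfinite(cond) or cond > cond_limit:
        raise ConditioningError(
            f"concentration matrix is rank-deficient (condition number {cond:.3g}); "
            "species kinetics are indistinguishable"
        )
    X = ds_pepc.matrix
    if svd_rank is not None:
        svd = svd_decompose(ds_pepc)
        X = low_rank_approximation(svd, svd_rank)
    # Sᵀ solves C Sᵀ = R Xᵀ
    St, *_ = np.linalg.lstsq(C, X.T * conc.R, rcond=None)
    S = St.T
    resid = X - S @ C.T / conc.R
    res_norms = np.array(
        [np.linalg.norm(resid @ (C[:, k] / np.linalg.norm(C[:, k]))) for k in range(C.shape[1])]
    )
    species = conc.species if conc.species is not None else [f"species_{k+1}" for k in range(C.shape[1])]
    curves = [
        Curve(ds_pepc.q.copy(), S[:, k], label=str(species[k])) for k in range(C.shape[1])
    ]
    return SADSSet(species=list(species), curves=curves, kind="pepc", residual_norms=res_norms)
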