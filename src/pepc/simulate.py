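"""Forward simulator for difference scattering datasets with full ground truth.

Every analysis stage in this package can be exercised without experimental
data: the simulator assembles

    ΔS(q, t) = (1/R)·Σ_k f_k(t)·SADS_k(q)
             + ΔT(t)·(∂S/∂T)ρ + Δρ(t)·(∂S/∂ρ)T  [+ noise]

from a first-order kinetic model (IRF-convolved), per-species difference
curves computed by the Debye equation from toy structures (or supplied
explicitly), parameterized solvent differentials with a controllable degree
of mutual similarity (water-like: nearly parallel; generic organic solvent:
distinct), and seeded additive Gaussian noise.  All constituents are stored
as ground truth, including the in-span/perpendicular split of each SADS.

Two ready-made scenarios mirror the demonstration regimes of the method:
a gold-trimer-like photocycle in a water-like solvent (three sequential
species, fs–ns–µs time constants) and an iodoform-like system in a distinct-
basis solvent with known-pathway components plus one hidden species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import Curve, ScatteringDataset, TrivialSet
from .hydro import HydroTrace
from .kinetics import ConcentrationMatrix, KineticModel, concentration_profiles, irf_exp
from .sads import SADSSet, ToyStructure, decompose_sads, sads_from_structures

__all__ = [
    "HeatingProfile",
    "SimulationConfig",
    "SimulationTruth",
    "SimulationOutput",
    "make_solvent_basis",
    "default_q_grid",
    "default_t_grid",
    "add_noise",
    "simulate_dataset",
    "scenario_gtc_like",
    "scenario_chi3_like",
]


def default_q_grid(q_min: float = 0.3, q_max: float = 9.0, n: int = 300) -> np.ndarray:
    """Uniform q-grid; the default range covers a typical liquidography window."""
    return np.linspace(q_min, q_max, n)


def default_t_grid(
    t_min: float = 0.1,
    t_max: float = 1e6,
    n: int = 60,
    negative: Sequence[float] = (-10.0, -5.0, -2.0, -1.0),
) -> np.ndarray:
    """Log-spaced positive delays plus a few negative reference delays (ps)."""
    pos = np.geomspace(t_min, t_max, n)
    return np.concatenate([np.asarray(negative, dtype=float), pos])


@dataclass
class HeatingProfile:
    """Parameterized time profile for ΔT(t) or Δρ(t).

    ``prompt`` is the amplitude of an IRF-limited step (energy deposited
    within the excitation pulse); ``slow`` rises with ``tau_slow``
    (vibrational cooling / thermalization, or the delayed density response).
    Evaluated as prompt·step + slow·(step − decay), both IRF-convolved.
    """

    prompt: float = 0.0
    slow: float = 0.0
    tau_slow: float = 100.0

    def evaluate(self, t, t0: float, irf_fwhm: float) -> np.ndarray:
        step = irf_exp(t, math.inf, t0, irf_fwhm)
        out = self.prompt * step
        if self.slow != 0.0:
            out = out + self.slow * (step - irf_exp(t, self.tau_slow, t0, irf_fwhm))
        return np.asarray(out, dtype=float)


def _gauss(q, center, width):
    return np.exp(-(((q - center) / width) ** 2))


def make_solvent_basis(
    q: np.ndarray,
    mode: str,
    similarity: Optional[float] = None,
    amplitudes: Sequence[float] = (1.0, 1.0),
) -> TrivialSet:
    """Two smooth solvent differentials with a prescribed mutual geometry.

    Both curves are sums of Gaussians in q, unit-normalized, and the second
    is mixed toward the first so their cosine similarity equals
    ``similarity`` exactly: near 1 for the water-like degenerate case
    (default 0.9999 — nearly indistinguishable, as for water), small for a
    generic solvent with distinct differentials (default 0.2).  ``amplitudes``
    rescale the unit shapes.
    """
    q = np.asarray(q, dtype=float)
    if mode == "water_like":
        c = 0.9999 if similarity is None else float(similarity)
    elif mode == "distinct":
        c = 0.2 if similarity is None else float(similarity)
    else:
        raise ValueError(f"unknown solvent-basis mode {mode!r}")
    if not (0.0 <= c < 1.0):
        raise ValueError("similarity must lie in [0, 1)")

    u_raw = (
        -1.2 * _gauss(q, 1.8, 0.45)
        + 0.9 * _gauss(q, 2.8, 0.60)
        + 0.25 * _gauss(q, 5.0, 1.20)
    )
    v_raw = (
        0.8 * _gauss(q, 1.2, 0.35)
        - 1.0 * _gauss(q, 2.2, 0.50)
        + 0.5 * _gauss(q, 4.0, 0.90)
    )
    u = u_raw / np.linalg.norm(u_raw)
    v_perp = v_raw - (u @ v_raw) * u
    v_perp /= np.linalg.norm(v_perp)
    v = c * u + math.sqrt(1.0 - c * c) * v_perp
    dT = Curve(q.copy(), amplitudes[0] * u, label="dS/dT_rho")
    drho = Curve(q.copy(), amplitudes[1] * v, label="dS/drho_T")
    return TrivialSet([dT, drho])


@dataclass
class SimulationConfig:
    """Everything needed to forward-simulate one dataset."""

    q: np.ndarray
    t: np.ndarray
    R: float
    model: KineticModel
    sads_real: SADSSet
    solvent_basis: TrivialSet
    dT_profile: HeatingProfile = field(default_factory=lambda: HeatingProfile(prompt=1.0, slow=0.5, tau_slow=20.0))
    drho_profile: HeatingProfile = field(default_factory=lambda: HeatingProfile(prompt=0.0, slow=1.0, tau_slow=200.0))
    noise_sigma: float = 0.0          # relative to the RMS of the noiseless matrix
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.noise_sigma > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise is requested")
        if self.sads_real.n_species != self.model.n_species:
            raise ValueError(
                f"{self.sads_real.n_species} SADS curves for "
                f"{self.model.n_species} kinetic species"
            )
        if not np.array_equal(self.sads_real.q, self.q) or not np.array_equal(
            self.solvent_basis.q, self.q
        ):
            raise ValueError("SADS and solvent basis must live on the configured q-grid")


@dataclass
class SimulationTruth:
    C: ConcentrationMatrix
    sads_real: SADSSet
    sads_perp: SADSSet
    d_coeffs: np.ndarray        # [n_species × 2]
    solvent_basis: TrivialSet
    hydro: HydroTrace
    noiseless: np.ndarray


@dataclass
class SimulationOutput:
    dataset: ScatteringDataset
    truth: SimulationTruth
    config: SimulationConfig


def add_noise(matrix: np.ndarray, sigma, seed: int) -> np.ndarray:
    """Seeded i.i.d. Gaussian noise; per-q scale when ``sigma`` is a Curve."""
    matrix = np.asarray(matrix, dtype=float)
    if isinstance(sigma, Curve):
        scale = sigma.values[:, None]
    else:
        scale = float(sigma)
        if scale < 0:
            raise ValueError("sigma must be nonnegative")
    if np.any(np.asarray(scale) < 0):
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    return matrix + scale * rng.standard_normal(matrix.shape)


def simulate_dataset(config: SimulationConfig) -> SimulationOutput:
    """Assemble the forward model and a full ground-truth record."""
    conc = concentration_profiles(config.model, config.t)
    conc = ConcentrationMatrix(t=conc.t, C=conc.C, R=config.R, species=conc.species)

    S = config.sads_real.as_matrix()
    dT = config.dT_profile.evaluate(config.t, config.model.t0, config.model.irf_fwhm)
    drho = config.drho_profile.evaluate(config.t, config.model.t0, config.model.irf_fwhm)
    B = config.solvent_basis.as_matrix()

    noiseless = (S @ conc.C.T) / config.R + np.outer(B[:, 0], dT) + np.outer(B[:, 1], drho)

    if config.noise_sigma > 0:
        sigma_abs = config.noise_sigma * float(np.sqrt(np.mean(noiseless**2)))
        matrix = add_noise(noiseless, sigma_abs, config.seed)
        sigma_mat = np.full_like(matrix, sigma_abs)
    else:
        matrix = noiseless.copy()
        sigma_mat = None

    decomps = [decompose_sads(c, config.solvent_basis) for c in config.sads_real.curves]
    sads_perp = SADSSet(
        species=list(config.sads_real.species),
        curves=[d.perpendicular for d in decomps],
        kind="pepc",
    )
    d_coeffs = np.vstack([d.d_coeffs for d in decomps])

    cond_b = np.linalg.cond(B / np.linalg.norm(B, axis=0))
    hydro = HydroTrace(
        t=config.t.copy(), dT=dT, drho=drho,
        condition_number=float(max(cond_b, 1.0)), mode="two_term",
        ill_conditioned=bool(cond_b > 100.0),
    )

    meta = {
        "provenance": "synthetic",
        "R": f"{config.R:g}",
        "seed": "none" if config.seed is None else str(config.seed),
        "noise_sigma_rel": f"{config.noise_sigma:g}",
    }
    dataset = ScatteringDataset(
        config.q.copy(), config.t.copy(), matrix, sigma=sigma_mat, meta=meta
    )
    truth = SimulationTruth(
        C=conc, sads_real=config.sads_real, sads_perp=sads_perp, d_coeffs=d_coeffs,
        solvent_basis=config.solvent_basis, hydro=hydro, noiseless=noiseless,
    )
    return SimulationOutput(dataset=dataset, truth=truth, config=config)


# ---------------------------------------------------------------------------
# ready-made scenarios


def _chain(n: int, spacing: float, f: float = 79.0, label: str = "Au") -> ToyStructure:
    return ToyStructure([(f"{label}{i+1}", f, (0.0, 0.0, i * spacing)) for i in range(n)])


def gtc_structures() -> dict:
    """Toy gold-trimer photocycle structures.

    Ground: loosely aggregated linear trimer.  The first excited species has
    a covalently contracted Au–Au bond, the second contracts further, and the
    long-lived product is a tetramer.  Distances are representative, not
    refined values.
    """
    return {
        "ground": _chain(3, 3.1),
        "T1_prime": _chain(3, 2.8),
        "T1": _chain(3, 2.6),
        "tetramer": _chain(4, 2.75),
    }


def scenario_gtc_like(
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
    n_q: int = 300,
    n_t: int = 60,
    basis_mode: str = "water_like",
) -> SimulationConfig:
    """Three sequential species (1.7 ps → 1.0 ns → 114 ns) in a water-like solvent.

    Time constants, the 0.48 ps IRF and the sequential scheme reproduce the
    gold-trimer demonstration regime; structures are toy chains.
    """
    q = default_q_grid(n=n_q)
    t = default_t_grid(n=n_t)
    structs = gtc_structures()
    species = ["T1_prime", "T1", "tetramer"]
    curves = [sads_from_structures(structs[s], structs["ground"], q) for s in species]
    # heavy-atom solute: early-time solute-related signal ~2x the heating term
    scale = 180.0 / max(c.norm() for c in curves)
    curves = [Curve(q.copy(), c.values * scale, label=s) for c, s in zip(curves, species)]
    sads = SADSSet(species=species, curves=curves, kind="real")
    model = KineticModel(
        species=species, scheme="sequential", taus=np.array([1.7, 1000.0, 114000.0]),
        t0=0.0, irf_fwhm=0.48,
    )
    basis = make_solvent_basis(q, basis_mode)
    return SimulationConfig(
        q=q, t=t, R=100.0, model=model, sads_real=sads, solvent_basis=basis,
        dT_profile=HeatingProfile(prompt=0.3, slow=0.7, tau_slow=20.0),
        drho_profile=HeatingProfile(prompt=0.0, slow=0.5, tau_slow=300.0),
        noise_sigma=noise_sigma, seed=seed,
    )


def scenario_chi3_like(
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
    hidden_scale: float = 1.0,
    n_q: int = 300,
    n_t: int = 50,
):
    """Iodoform-like null-hypothesis scenario: known pathways plus a hidden isomer.

    Returns ``(config, known_trivials)``.  The trivial set holds the two
    distinct solvent differentials and the two known-pathway difference
    curves; the third kinetic species (the hidden isomer) is NOT in the set,
    so its perpendicular component survives PEPC.  ``hidden_scale``
    multiplies the hidden species' curve, controlling detection power.
    """
    q = default_q_grid(n=n_q)
    t = default_t_grid(t_min=0.2, t_max=1e5, n=n_t)
    heavy = 53.0  # iodine-dominated toy structures
    ground = ToyStructure(
        [("C", 6.0, (0.0, 0.0, 0.0)),
         ("I1", heavy, (2.15, 0.0, 0.0)),
         ("I2", heavy, (-1.0, 1.9, 0.0)),
         ("I3", heavy, (-1.0, -1.9, 0.0))]
    )
    radical = ToyStructure(  # CHI2 + free I: one C–I bond broken
        [("C", 6.0, (0.0, 0.0, 0.0)),
         ("I1", heavy, (8.0, 0.0, 0.0)),
         ("I2", heavy, (-1.0, 1.9, 0.0)),
         ("I3", heavy, (-1.0, -1.9, 0.0))]
    )
    molecular = ToyStructure(  # CHI2 + ½ I2-like rearrangement
        [("C", 6.0, (0.0, 0.0, 0.0)),
         ("I1", heavy, (6.0, 2.7, 0.0)),
         ("I2", heavy, (-1.0, 1.9, 0.0)),
         ("I3", heavy, (-1.0, -1.9, 0.0))]
    )
    isomer = ToyStructure(  # iso form: I–I bound isomer
        [("C", 6.0, (0.0, 0.0, 0.0)),
         ("I1", heavy, (2.15, 0.0, 0.0)),
         ("I2", heavy, (3.1, 2.0, 0.0)),
         ("I3", heavy, (-1.0, -1.9, 0.0))]
    )
    species = ["radical_pathway", "molecular_pathway", "hidden_isomer"]
    curves = [
        sads_from_structures(radical, ground, q),
        sads_from_structures(molecular, ground, q),
        sads_from_structures(isomer, ground, q),
    ]
    scale = 40.0 / max(c.norm() for c in curves)
    vals = [c.values * scale for c in curves]
    vals[2] = vals[2] * hidden_scale
    curves = [Curve(q.copy(), v, label=s) for v, s in zip(vals, species)]
    sads = SADSSet(species=species, curves=curves, kind="real")
    model = KineticModel(
        species=species, scheme="sequential", taus=np.array([30.0, 2000.0, 40000.0]),
        t0=0.0, irf_fwhm=0.48,
    )
    basis = make_solvent_basis(q, "distinct")
    config = SimulationConfig(
        q=q, t=t, R=150.0, model=model, sads_real=sads, solvent_basis=basis,
        dT_profile=HeatingProfile(prompt=0.4, slow=0.6, tau_slow=50.0),
        drho_profile=HeatingProfile(prompt=0.0, slow=0.6, tau_slow=500.0),
        noise_sigma=noise_sigma, seed=seed,
    )
    known = TrivialSet(
        [basis.components[0].copy(), basis.components[1].copy(),
         curves[0].copy(), curves[1].copy()]
    )
    return config, known


def calibrate_hidden_scale(
    noise_sigma: float, multiple: float = 10.0, n_q: int = 300, n_t: int = 50
) -> float:
    """Hidden-species scale making its out-of-span signal ``multiple``× the noise.

    The detection power of the null test is controlled by the RMS of the
    hidden species' perpendicular component (relative to the known trivial
    set) against the noise amplitude; this solves for the curve scale that
    pins that ratio.
    """
    from .projection import pepc_multi

    cfg, known = scenario_chi3_like(noise_sigma=0.0, hidden_scale=1.0, n_q=n_q, n_t=n_t)
    out = simulate_dataset(cfg)
    hidden_mat = np.outer(out.truth.sads_real.curves[2].values, out.truth.C.C[:, 2]) / cfg.R
    hds = ScatteringDataset(cfg.q, cfg.t, hidden_mat)
    perp = pepc_multi(hds, known).pepc.matrix
    rms_perp = float(np.sqrt(np.mean(perp**2)))
    sigma_abs = noise_sigma * float(np.sqrt(np.mean(out.truth.noiseless**2)))
    return multiple * sigma_abs / rms_perp
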