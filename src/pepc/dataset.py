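"""Containers and plain-text I/O for difference scattering data.

Difference scattering curves ΔS(q) and matrices ΔS(q, t) are exchanged as
whitespace-delimited text with ``#`` comment headers, so every intermediate
product of an analysis is diffable and round-trips losslessly (15 significant
digits).  Conventions: q in Å⁻¹ (strictly increasing, positive), time delays
in ps (strictly increasing, negative reference delays allowed).

All projections and inner products downstream operate on ΔS itself, never on
the display-scaled qΔS.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "Curve",
    "ScatteringDataset",
    "TrivialSet",
    "ValidationError",
    "FormatError",
    "AlignmentError",
    "read_curve",
    "write_curve",
    "read_matrix",
    "write_matrix",
    "align_to_grid",
]

# emitted precision; 17 significant digits make write->read exact for float64
_FMT = "%.17g"


class ValidationError(ValueError):
    """An invariant of a container was violated."""


class FormatError(ValueError):
    """A file could not be parsed as the expected text layout."""


class AlignmentError(ValueError):
    """q-grids cannot be brought onto a common grid."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Curve:
    """A single difference scattering curve on a q-grid.

    Houses solvent differentials (∂S/∂T)ρ and (∂S/∂ρ)T, species-associated
    difference curves (SADS), and generic trivial components.
    """

    q: np.ndarray
    values: np.ndarray
    label: str = ""
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = _as_1d(self.q, "q")
        self.values = _as_1d(self.values, "values")
        if self.q.size != self.values.size:
            raise ValidationError(
                f"q and values length mismatch: {self.q.size} vs {self.values.size}"
            )
        if self.q.size < 2:
            raise ValidationError("a curve needs at least 2 q-points")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite entries in curve")
        if np.any(self.q <= 0):
            raise ValidationError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = _as_1d(self.sigma, "sigma")
            if self.sigma.size != self.q.size:
                raise ValidationError("sigma length mismatch")
            if np.any(self.sigma < 0) or not np.all(np.isfinite(self.sigma)):
                raise ValidationError("sigma must be finite and nonnegative")

    @property
    def n_q(self) -> int:
        return self.q.size

    def norm(self) -> float:
        """Euclidean norm of the value vector."""
        return float(np.linalg.norm(self.values))

    def unit(self) -> "Curve":
        """Unit-normalized copy (degenerate for a zero curve)."""
        n = self.norm()
        if n == 0.0:
            raise ValidationError(f"cannot normalize zero curve {self.label!r}")
        return Curve(self.q.copy(), self.values / n, label=self.label)

    def copy(self) -> "Curve":
        return Curve(
            self.q.copy(),
            self.values.copy(),
            label=self.label,
            sigma=None if self.sigma is None else self.sigma.copy(),
        )

    def interpolated(self, q_new: np.ndarray) -> "Curve":
        """Linear interpolation onto ``q_new`` (must lie within the q-range)."""
        q_new = _as_1d(q_new, "q_new")
        if q_new[0] < self.q[0] - 1e-12 or q_new[-1] > self.q[-1] + 1e-12:
            raise AlignmentError(
                f"target grid [{q_new[0]}, {q_new[-1]}] extends beyond "
                f"curve range [{self.q[0]}, {self.q[-1]}]"
            )
        vals = np.interp(q_new, self.q, self.values)
        sig = None if self.sigma is None else np.interp(q_new, self.q, self.sigma)
        return Curve(q_new.copy(), vals, label=self.label, sigma=sig)


@dataclass
class ScatteringDataset:
    """A difference scattering matrix ΔS(q, t) with optional uncertainties.

    ``matrix`` is [n_q × n_t]; column j is the difference curve at delay
    ``t[j]``.  ``meta`` carries free-form provenance (solvent, R ratio, ...).
    """

    q: np.ndarray
    t: np.ndarray
    matrix: np.ndarray
    sigma: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = _as_1d(self.q, "q")
        self.t = _as_1d(self.t, "t")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.q.size, self.t.size):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} != (n_q, n_t) = "
                f"({self.q.size}, {self.t.size})"
            )
        if np.any(self.q <= 0):
            raise ValidationError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be strictly increasing")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("t must be strictly increasing")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("non-finite entries in matrix")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.matrix.shape:
                raise ValidationError("sigma shape mismatch")
            if np.any(self.sigma < 0) or not np.all(np.isfinite(self.sigma)):
                raise ValidationError("sigma must be finite and nonnegative")

    @property
    def n_q(self) -> int:
        return self.q.size

    @property
    def n_t(self) -> int:
        return self.t.size

    def column(self, j: int) -> Curve:
        """The difference curve at delay index ``j``."""
        sig = None if self.sigma is None else self.sigma[:, j]
        return Curve(self.q, self.matrix[:, j], label=f"t={self.t[j]:g} ps", sigma=sig)

    def copy(self) -> "ScatteringDataset":
        return ScatteringDataset(
            self.q.copy(),
            self.t.copy(),
            self.matrix.copy(),
            sigma=None if self.sigma is None else self.sigma.copy(),
            meta=dict(self.meta),
        )


@dataclass
class TrivialSet:
    """Ordered known basis curves spanning the trivial space to be removed."""

    components: list

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValidationError("trivial set needs at least one component")
        q0 = self.components[0].q
        for c in self.components:
            if c.q.size != q0.size or not np.array_equal(c.q, q0):
                raise ValidationError("trivial components must share one q-grid")
            if c.norm() == 0.0:
                raise ValidationError(f"trivial component {c.label!r} is the zero vector")

    @property
    def q(self) -> np.ndarray:
        return self.components[0].q

    @property
    def m(self) -> int:
        return len(self.components)

    @property
    def labels(self) -> list:
        return [c.label for c in self.components]

    def as_matrix(self) -> np.ndarray:
        """Stack components as columns of an [n_q × m] matrix."""
        return np.column_stack([c.values for c in self.components])


# ---------------------------------------------------------------------------
# text I/O


def _parse_comment_meta(lines):
    meta = {}
    t = None
    for ln in lines:
        body = ln.lstrip("#").strip()
        if not body:
            continue
        if ":" in body:
            key, _, rest = body.partition(":")
            key = key.strip()
            rest = rest.strip()
            if key == "t":
                try:
                    t = np.array([float(x) for x in rest.split()])
                except ValueError as exc:
                    raise FormatError(f"malformed time-delay header: {rest!r}") from exc
            else:
                meta[key] = rest
        else:
            meta.setdefault("comment", body)
    return meta, t


def read_matrix(path, fmt: str = "auto") -> ScatteringDataset:
    """Read a ΔS(q, t) matrix from delimited text.

    Layout: '#'-prefixed comment lines (one of which must be
    ``# t: <t1> <t2> ...``), then one row per q-point:
    ``<q> <ΔS(q,t1)> <ΔS(q,t2)> ...``.
    """
    with open(path, "rt") as fh:
        raw = fh.readlines()
    comments = [ln for ln in raw if ln.lstrip().startswith("#")]
    meta, t = _parse_comment_meta(comments)
    if t is None:
        raise FormatError(f"{path}: missing '# t: ...' header row")
    rows = []
    for idx, ln in enumerate(raw, start=1):
        s = ln.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        try:
            rows.append([float(x) for x in parts])
        except ValueError:
            bad = next(p for p in parts if not _is_float(p))
            raise FormatError(
                f"{path}: malformed numeric cell {bad!r} at line {idx}, "
                f"column {parts.index(bad) + 1}"
            ) from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    arr = np.array(rows)
    if arr.shape[1] != t.size + 1:
        raise FormatError(
            f"{path}: {arr.shape[1] - 1} value columns but {t.size} time delays in header"
        )
    return ScatteringDataset(q=arr[:, 0], t=t, matrix=arr[:, 1:], meta=meta)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_matrix(ds: ScatteringDataset, path) -> None:
    with open(path, "wt") as fh:
        for key, val in ds.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# t: " + " ".join(_FMT % x for x in ds.t) + "\n")
        for i in range(ds.n_q):
            fh.write(
                _FMT % ds.q[i]
                + " "
                + " ".join(_FMT % x for x in ds.matrix[i])
                + "\n"
            )


def read_curve(path) -> Curve:
    """Read a two- or three-column (q, value[, sigma]) curve file."""
    label = ""
    rows = []
    with open(path, "rt") as fh:
        for idx, ln in enumerate(fh, start=1):
            s = ln.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if body.startswith("label:"):
                    label = body.partition(":")[2].strip()
                continue
            parts = s.split()
            if len(parts) not in (2, 3):
                raise FormatError(
                    f"{path}: expected 2 or 3 columns at line {idx}, got {len(parts)}"
                )
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise FormatError(f"{path}: malformed numeric cell at line {idx}") from exc
    if not rows:
        raise FormatError(f"{path}: empty curve file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: inconsistent column count")
    arr = np.array(rows)
    sigma = arr[:, 2] if arr.shape[1] == 3 else None
    return Curve(q=arr[:, 0], values=arr[:, 1], label=label, sigma=sigma)


def write_curve(curve: Curve, path) -> None:
    with open(path, "wt") as fh:
        if curve.label:
            fh.write(f"# label: {curve.label}\n")
        for i in range(curve.n_q):
            cols = [_FMT % curve.q[i], _FMT % curve.values[i]]
            if curve.sigma is not None:
                cols.append(_FMT % curve.sigma[i])
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# grid alignment


def _grids_equal(a: np.ndarray, b: np.ndarray, rtol: float = 1e-9) -> bool:
    return a.size == b.size and np.allclose(a, b, rtol=rtol, atol=0.0)


def align_to_grid(items: Sequence, policy: str = "strict") -> list:
    """Bring curves and/or datasets onto one shared q-grid.

    ``strict`` requires all grids identical (1e-9 relative) and returns the
    items unchanged; ``interpolate`` linearly interpolates every item onto the
    first item's grid restricted to the common overlapping q-range.
    """
    if policy not in ("strict", "interpolate"):
        raise ValueError(f"unknown policy {policy!r}")
    if not items:
        return []
    grids = [it.q for it in items]
    lo = max(g[0] for g in grids)
    hi = min(g[-1] for g in grids)
    if lo > hi:
        raise AlignmentError("q-ranges are disjoint; no common grid exists")
    if policy == "strict":
        for g in grids[1:]:
            if not _grids_equal(grids[0], g):
                raise AlignmentError("grids differ; use policy='interpolate'")
        return list(items)
    g0 = grids[0]
    target = g0[(g0 >= lo - 1e-12) & (g0 <= hi + 1e-12)]
    if target.size < 2:
        raise AlignmentError("overlap region contains fewer than 2 grid points")
    out = []
    for it in items:
        if isinstance(it, Curve):
            out.append(it.interpolated(target))
        elif isinstance(it, ScatteringDataset):
            mat = np.empty((target.size, it.n_t))
            for j in range(it.n_t):
                mat[:, j] = np.interp(target, it.q, it.matrix[:, j])
            sig = None
            if it.sigma is not None:
                sig = np.empty_like(mat)
                for j in range(it.n_t):
                    sig[:, j] = np.interp(target, it.q, it.sigma[:, j])
            out.append(
                ScatteringDataset(target.copy(), it.t.copy(), mat, sigma=sig, meta=dict(it.meta))
            )
        else:
            raise TypeError(f"cannot align object of type {type(it).__name__}")
    return out
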