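"""Multi-shell acquisition schemes and the FSL .bval/.bvec dialect.

b-values are stored in s/mm² as read from disk; the fitting code converts
to ms/µm² internally so diffusivities come out in µm²/ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .directions import scheme_directions

#: b-values closer than this (s/mm²) are treated as the same shell
SHELL_TOL = 1.0
#: a b-value below this (s/mm²) counts as b=0
B0_TOL = 1.0
#: unknowns of the diffusion+kurtosis linear model (lnS0 + 6 + 15)
N_UNKNOWNS = 22


class SchemeError(ValueError):
    """Invalid or degenerate acquisition scheme."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-factors and unit gradient directions.

    Parameters
    ----------
    bvalues : (V,) array, s/mm².
    bvectors : (V, 3) array; unit vectors for b>0, anything (conventionally
        zero) for b=0 volumes.
    """

    bvalues: np.ndarray
    bvectors: np.ndarray

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        g = np.asarray(self.bvectors, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3 or g.shape[0] != b.shape[0]:
            raise SchemeError("bval/bvec mismatch")
        if np.any(b < 0):
            raise SchemeError("invalid b-factor")
        nz = b > B0_TOL
        norms = np.linalg.norm(g[nz], axis=1)
        if np.any(norms < 1e-12):
            raise SchemeError("zero direction on nonzero shell")
        if np.any(np.abs(norms - 1.0) > 1e-6):
            if np.any(np.abs(norms - 1.0) > 1e-3):
                warnings.warn("non-unit gradient directions normalized", stacklevel=2)
            g = g.copy()
            g[nz] /= norms[:, None]
        if not np.any(~nz):
            raise SchemeError("scheme requires at least one b=0 volume")
        if len(self.shells) < 2:
            raise SchemeError("insufficient shells for kurtosis")
        if int(np.sum(nz)) < N_UNKNOWNS - 1:
            raise SchemeError("under-determined")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "bvectors", g)

    def __len__(self) -> int:
        return int(self.bvalues.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return np.asarray(self.bvalues) <= B0_TOL

    @property
    def shells(self) -> tuple[float, ...]:
        """Distinct nonzero b-values, ascending."""
        b = np.asarray(self.bvalues, dtype=float)
        nz = sorted(b[b > B0_TOL])
        out: list[float] = []
        for v in nz:
            if not out or v - out[-1] > SHELL_TOL:
                out.append(float(v))
        return tuple(out)


def make_scheme(n_dirs: int, shells, seed: int = 0) -> AcquisitionScheme:
    """Build a multi-shell scheme: one b=0 plus ``n_dirs`` directions per shell.

    Directions are an approximately uniform deterministic spiral set,
    seed-rotated, shared across shells (standard multi-shell practice).
    """
    shells = [float(s) for s in shells]
    nonzero = sorted({s for s in shells if s > B0_TOL})
    if len(nonzero) < 2:
        raise SchemeError("insufficient shells for kurtosis")
    if n_dirs < 6:
        raise SchemeError("under-determined")
    dirs = scheme_directions(n_dirs, seed=seed)
    bvals = [0.0]
    bvecs = [np.zeros(3)]
    for s in nonzero:
        bvals.extend([s] * n_dirs)
        bvecs.extend(dirs)
    return AcquisitionScheme(np.array(bvals), np.array(bvecs))


def read_bval_bvec(bval_path, bvec_path) -> AcquisitionScheme:
    """Read an FSL-dialect .bval/.bvec file pair."""
    bvals = _read_numeric_rows(bval_path)
    if bvals.ndim != 1:
        bvals = bvals.reshape(-1)
    bvecs = _read_numeric_rows(bvec_path)
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise SchemeError("bvec file must have 3 rows (x, y, z)")
    if bvecs.shape[1] != bvals.shape[0]:
        raise SchemeError("bval/bvec mismatch")
    return AcquisitionScheme(bvals, bvecs.T)


def write_bval_bvec(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write the FSL-dialect counterpart of :func:`read_bval_bvec`."""
    Path(bval_path).write_text(
        " ".join(repr(float(v)) for v in scheme.bvalues) + "\n"
    )
    rows = []
    for c in range(3):
        rows.append(" ".join(repr(float(v)) for v in scheme.bvectors[:, c]))
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def _read_numeric_rows(path) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        vals = []
        for tok in line.split():
            try:
                vals.append(float(tok))
            except ValueError:
                raise SchemeError(
                    f"{path}: non-numeric token {tok!r} on line {lineno}"
                ) from None
        rows.append(vals)
    if not rows:
        raise SchemeError(f"{path}: empty file")
    if len(rows) == 1:
        return np.array(rows[0])
    if len({len(r) for r in rows}) != 1:
        raise SchemeError(f"{path}: ragged rows")
    return np.array(rows)
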