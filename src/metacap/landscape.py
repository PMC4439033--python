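"""Generation and serialization of patch landscapes.

A landscape is a set of N habitat patches in a d-dimensional cube of side
L.  Each patch carries a positive "value" A_i (e.g. carrying capacity),
drawn i.i.d. from a distribution with mean one and variance sigma^2.
Three spatial arrangements are supported:

* ``random``  -- positions i.i.d. uniform on [0, L]^d,
* ``grid``    -- m^d patches at the centers of a regular grid of cells,
* ``jiggled`` -- cell-local perturbation of the grid,
  ``x_i = grid_i + eta * u_i`` with u_i uniform on the patch's own grid cell
  (side L/m, centered on the patch), so that eta = 0 reproduces the grid
  exactly and eta = 1 is a stratified-uniform sample: one patch per cell,
  with exactly uniform marginals on [0, L].
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Landscape",
    "ValueDistribution",
    "LandscapeParseError",
    "generate_random_landscape",
    "generate_grid_landscape",
    "generate_jiggled_landscape",
    "write_landscape",
    "read_landscape",
]

VALUE_FAMILIES = ("degenerate", "lognormal", "gamma", "uniform")
BOUNDARIES = ("hard", "periodic")


class LandscapeParseError(ValueError):
    """A landscape file violates the schema or an invariant."""


@dataclass(frozen=True)
class ValueDistribution:
    """Patch-value distribution with mean one and variance ``variance``.

    ``lognormal`` (default) is always positive for any variance; ``gamma``
    likewise; ``uniform`` is a symmetric interval around one and requires
    variance < 1/3 to keep all values positive; ``degenerate`` pins every
    value to one and forces variance 0.
    """

    family: str = "lognormal"
    variance: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in VALUE_FAMILIES:
            raise ValueError(
                f"unknown value family {self.family!r}; expected one of {VALUE_FAMILIES}"
            )
        if self.variance < 0:
            raise ValueError(f"variance must be nonnegative, got {self.variance}")
        if self.family == "degenerate" and self.variance > 0:
            raise ValueError("degenerate value family is incompatible with variance > 0")
        if self.family == "uniform" and self.variance >= 1.0 / 3.0:
            raise ValueError(
                "uniform value family requires variance < 1/3 to keep patch values positive"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. patch values with mean 1 and the stated variance."""
        s2 = self.variance
        if self.family == "degenerate" or s2 == 0.0:
            return np.ones(n)
        if self.family == "lognormal":
            # E = exp(mu + t/2) = 1, Var = (exp(t) - 1) exp(2 mu + t) = s2
            t = math.log1p(s2)
            return rng.lognormal(mean=-0.5 * t, sigma=math.sqrt(t), size=n)
        if self.family == "gamma":
            return rng.gamma(shape=1.0 / s2, scale=s2, size=n)
        # uniform on [1 - h, 1 + h] with h = sqrt(3 s2)
        h = math.sqrt(3.0 * s2)
        return rng.uniform(1.0 - h, 1.0 + h, size=n)


@dataclass
class Landscape:
    """Patch positions and values in a d-cube with side ``box_length``."""

    positions: np.ndarray  # (n, d)
    values: np.ndarray  # (n,)
    box_length: float
    boundary: str = "hard"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}, got {self.boundary!r}")
        if self.box_length <= 0:
            raise ValueError(f"box_length must be positive, got {self.box_length}")
        if self.positions.shape[0] != self.values.shape[0]:
            raise ValueError(
                f"positions has {self.positions.shape[0]} rows but values has "
                f"length {self.values.shape[0]}"
            )
        if self.positions.shape[0] == 0:
            raise ValueError("a landscape must contain at least one patch")
        if np.any(self.values <= 0):
            raise ValueError("all patch values must be positive")
        if np.any(self.positions < 0) or np.any(self.positions > self.box_length):
            raise ValueError("all coordinates must lie in [0, box_length]")

    @property
    def n_patches(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


def _validate_common(n: int, d: int, L: float) -> None:
    if n < 1:
        raise ValueError(f"need at least one patch, got n={n}")
    if d < 1:
        raise ValueError(f"dimension must be >= 1, got d={d}")
    if L <= 0:
        raise ValueError(f"box length must be positive, got L={L}")


def _streams(seed: Optional[int]) -> tuple[np.random.Generator, np.random.Generator]:
    # Separate sub-streams for positions and values: changing the value
    # distribution never perturbs the positions at a fixed seed.
    pos_ss, val_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(pos_ss), np.random.default_rng(val_ss)


def generate_random_landscape(
    n: int,
    d: int,
    L: float,
    values: ValueDistribution = ValueDistribution(),
    seed: Optional[int] = None,
    boundary: str = "hard",
) -> Landscape:
    """Uniform-random landscape: positions i.i.d. uniform on [0, L]^d."""
    _validate_common(n, d, L)
    pos_rng, val_rng = _streams(seed)
    positions = pos_rng.uniform(0.0, L, size=(n, d))
    A = values.sample(n, val_rng)
    return Landscape(positions, A, L, boundary=boundary, seed=seed)


def _grid_positions(m: int, d: int, L: float) -> np.ndarray:
    """m^d cell centers: coordinate (i + 1/2) L / m along each axis."""
    axis = (np.arange(m) + 0.5) * (L / m)
    mesh = np.meshgrid(*([axis] * d), indexing="ij")
    return np.stack([g.ravel() for g in mesh], axis=1)


def generate_grid_landscape(
    m: int,
    d: int,
    L: float,
    values: ValueDistribution = ValueDistribution(),
    seed: Optional[int] = None,
    boundary: str = "hard",
) -> Landscape:
    """Regular grid of m^d patches at cell centers.

    Under a periodic boundary every nearest-neighbor distance equals L/m,
    so all row sums of the dispersal matrix coincide.
    """
    _validate_common(m, d, L)
    positions = _grid_positions(m, d, L)
    _, val_rng = _streams(seed)
    A = values.sample(positions.shape[0], val_rng)
    return Landscape(positions, A, L, boundary=boundary, seed=seed)


def generate_jiggled_landscape(
    m: int,
    d: int,
    L: float,
    eta: float,
    values: ValueDistribution = ValueDistribution(),
    seed: Optional[int] = None,
    boundary: str = "hard",
) -> Landscape:
    """Grid arrangement perturbed toward full disorder by cell-local jiggling.

    Each patch is displaced by ``eta * u_i`` with u_i uniform on its own
    grid cell, ``[-L/(2m), L/(2m)]^d``: eta = 0 is the exact grid, eta = 1
    scatters every patch uniformly within its cell (stratified-uniform
    sampling, with exactly uniform marginals on [0, L]).  Displacements are
    local — at most ``eta * L * sqrt(d) / (2m)`` — so the disorder grows
    continuously with eta.  Coordinates stay in [0, L] with no clamping.
    """
    _validate_common(m, d, L)
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    grid = _grid_positions(m, d, L)
    pos_rng, val_rng = _streams(seed)
    half_cell = L / (2.0 * m)
    u = pos_rng.uniform(-half_cell, half_cell, size=grid.shape)
    positions = grid + eta * u
    A = values.sample(grid.shape[0], val_rng)
    return Landscape(positions, A, L, boundary=boundary, seed=seed)


# ---------------------------------------------------------------------------
# Serialization: TSV with one metadata line, then a header row.
#   #dim=<d> box=<L> boundary=<hard|periodic>
#   id  x1 .. xd  value


def write_landscape(landscape: Landscape, path) -> None:
    d = landscape.dim
    cols = {"id": np.arange(landscape.n_patches)}
    for k in range(d):
        cols[f"x{k + 1}"] = landscape.positions[:, k]
    cols["value"] = landscape.values
    frame = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(
            f"#dim={d} box={landscape.box_length!r} boundary={landscape.boundary}\n"
        )
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_landscape(path, dim: Optional[int] = None) -> Landscape:
    """Read a landscape written by :func:`write_landscape`.

    ``dim`` optionally asserts the expected dimension; a mismatch with the
    file's declared or actual column count is an error.
    """
    with open(path) as fh:
        meta_line = fh.readline()
        rest = fh.read()
    if not meta_line.startswith("#"):
        raise LandscapeParseError(f"{path}: line 1: missing '#dim=... box=...' metadata line")
    meta: dict[str, str] = {}
    for tok in meta_line[1:].split():
        if "=" not in tok:
            raise LandscapeParseError(f"{path}: line 1: malformed metadata token {tok!r}")
        key, _, val = tok.partition("=")
        meta[key] = val
    try:
        file_dim = int(meta["dim"])
        L = float(meta["box"])
    except (KeyError, ValueError) as exc:
        raise LandscapeParseError(f"{path}: line 1: bad metadata ({exc})") from exc
    boundary = meta.get("boundary", "hard")
    if dim is not None and dim != file_dim:
        raise LandscapeParseError(
            f"{path}: declared dim={file_dim} but dim={dim} was requested"
        )
    try:
        frame = pd.read_csv(io.StringIO(rest), sep="\t")
    except Exception as exc:  # malformed table
        raise LandscapeParseError(f"{path}: cannot parse table: {exc}") from exc
    expected = ["id"] + [f"x{k + 1}" for k in range(file_dim)] + ["value"]
    if list(frame.columns) != expected:
        raise LandscapeParseError(
            f"{path}: line 2: expected columns {expected}, found {list(frame.columns)}"
        )
    positions = frame[[f"x{k + 1}" for k in range(file_dim)]].to_numpy(dtype=float)
    values = frame["value"].to_numpy(dtype=float)
    # data rows start on line 3 (after metadata and header)
    bad = np.flatnonzero(values <= 0)
    if bad.size:
        raise LandscapeParseError(f"{path}: line {bad[0] + 3}: nonpositive patch value")
    out = np.flatnonzero((positions < 0).any(axis=1) | (positions > L).any(axis=1))
    if out.size:
        raise LandscapeParseError(f"{path}: line {out[0] + 3}: coordinate outside [0, {L}]")
    return Landscape(positions, values, L, boundary=boundary)
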