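"""Uniform sampling of the steady-state flux polytope.

The feasible set of a bounded metabolic model is the polytope
``P = {v : S v = 0, lb <= v <= ub}``.  Sampling proceeds by coordinate
hit-and-run with rounding (CHRR): the polytope is parameterized on an
orthonormal null-space basis of ``S`` (optionally fixed bounds are folded
in as extra equality rows), a pilot chain estimates the covariance of the
null-space coordinates, and its Cholesky factor re-scales ("rounds") the
coordinate system so chords in different directions have comparable
lengths.  Each step picks one rounded coordinate direction uniformly at
random, intersects the line through the current point with every bound
constraint to get the feasible chord, and jumps to a uniform point on that
chord.  Every ``thinning``-th point is stored, so ``total_iterations``
iterations yield ``floor(total_iterations / thinning)`` stored flux
vectors (e.g. 50,000,000 iterations stored every 10,000 give 5000 points
per reaction per model).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxPolytope",
    "FluxSampleSet",
    "InfeasiblePolytopeError",
    "SamplerStuckError",
    "n_stored_for",
    "build_polytope",
    "round_polytope",
    "sample_fluxes",
    "sample_model",
    "validate_samples",
]

logger = logging.getLogger(__name__)

BASIS_TOL = 1e-9       # ||S N||_max on the null-space basis
SAMPLE_TOL = 1e-6      # steady-state / bound slack allowed on stored rows
CHORD_CLIP = 1e-12     # chord endpoints pulled inward to avoid boundary sticking

try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


class InfeasiblePolytopeError(ValueError):
    """The bounds admit no steady-state flux vector."""


class SamplerStuckError(RuntimeError):
    """Every proposed chord had (numerically) zero length."""


def n_stored_for(total_iterations: int, thinning: int) -> int:
    """Number of solutions stored when keeping every ``thinning``-th of
    ``total_iterations`` iterations: ``floor(total / thinning)``."""
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    if total_iterations < thinning:
        raise ValueError("total_iterations must be >= thinning")
    return total_iterations // thinning


@dataclass
class FluxPolytope:
    """Null-space parameterization of ``{v : S v = 0, lb <= v <= ub}``.

    ``basis`` (n_reactions x k) spans the movable directions, ``anchor`` is
    an interior feasible point, and ``transform`` (k x k) is the rounding
    map; sampling moves along columns of ``basis @ transform``.
    """

    basis: np.ndarray
    anchor: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    transform: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.transform is None:
            self.transform = np.eye(self.dim)

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    @property
    def directions(self) -> np.ndarray:
        """Flux-space step directions, one per rounded coordinate."""
        return self.basis @ self.transform


@dataclass
class FluxSampleSet:
    """Stored flux vectors (n_stored x n_reactions, mmol/gDW/h) plus the
    sampling metadata needed to reproduce them."""

    samples: np.ndarray
    reaction_ids: list[str]
    seed: int
    total_iterations: int
    thinning: int
    phase: str = ""

    @property
    def n_stored(self) -> int:
        return self.samples.shape[0]

    def flux(self, reaction_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(reaction_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "samples.csv.gz", index=False)
        meta = {
            "seed": self.seed,
            "total_iterations": self.total_iterations,
            "thinning": self.thinning,
            "phase": self.phase,
            "n_stored": self.n_stored,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "FluxSampleSet":
        directory = Path(directory)
        frame = pd.read_csv(directory / "samples.csv.gz")
        meta = json.loads((directory / "metadata.json").read_text())
        return cls(
            samples=frame.to_numpy(),
            reaction_ids=list(frame.columns),
            seed=meta["seed"],
            total_iterations=meta["total_iterations"],
            thinning=meta["thinning"],
            phase=meta.get("phase", ""),
        )


# ---------------------------------------------------------------------------
# polytope construction


def find_feasible_point(model: MetabolicModel) -> np.ndarray:
    """Interior point via a maximum-slack LP.

    Maximizes the sum of per-reaction slacks ``s_j`` subject to
    ``S v = 0`` and ``lb_j + s_j <= v_j <= ub_j - s_j``.  Each slack is
    capped at a uniform small value (half the narrowest free reaction's
    half-span), so the optimum pulls *every* movable reaction strictly
    inside its bounds instead of trading narrow pathways away for large
    slacks on wide ones; reactions blocked to a single value by
    conservation simply get zero slack without pinning the rest to a
    vertex.  Raises :class:`InfeasiblePolytopeError` when the polytope is
    empty.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    free = np.flatnonzero(ub - lb > 0)
    k = len(free)
    s_cap = 0.5 * float(np.min((ub - lb)[free]) / 2.0) if k else 1.0

    # variables: [v (n), s (k)]
    c = np.zeros(n + k)
    c[n:] = -1.0
    A_eq = np.hstack([S, np.zeros((S.shape[0], k))]) if S.shape[0] else None
    b_eq = np.zeros(S.shape[0]) if S.shape[0] else None
    rows = []
    rhs = []
    for i, j in enumerate(free):
        row = np.zeros(n + k)
        row[j] = -1.0
        row[n + i] = 1.0
        rows.append(row)          # -v_j + s_j <= -lb_j
        rhs.append(-lb[j])
        row = np.zeros(n + k)
        row[j] = 1.0
        row[n + i] = 1.0
        rows.append(row)          # v_j + s_j <= ub_j
        rhs.append(ub[j])
    A_ub = np.array(rows) if rows else None
    b_ub = np.array(rhs) if rows else None
    bounds = [(lb[j], ub[j]) for j in range(n)] + [
        (0.0, min((ub[j] - lb[j]) / 2.0, s_cap)) for j in free
    ]

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise InfeasiblePolytopeError(
            f"model {model.id!r}: no steady-state flux vector satisfies the "
            f"bounds (LP status {res.status}: {res.message})"
        )
    return res.x[:n]


def build_polytope(model: MetabolicModel, basis_tol: float = BASIS_TOL) -> FluxPolytope:
    """Parameterize the model's steady-state polytope.

    Fixed reactions (lb == ub) are folded into the equality system so the
    null-space basis only spans genuinely movable directions.  The anchor
    comes from a maximum-slack feasibility LP.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    if np.any(lb > ub):
        bad = [model.reactions[j].id for j in np.flatnonzero(lb > ub)]
        raise InfeasiblePolytopeError(f"lower bound exceeds upper bound: {bad}")
    n = len(model.reactions)

    anchor = find_feasible_point(model)

    fixed = np.flatnonzero(ub - lb == 0)
    eq_rows = [S] if S.shape[0] else []
    for j in fixed:
        row = np.zeros((1, n))
        row[0, j] = 1.0
        eq_rows.append(row)
    A = np.vstack(eq_rows) if eq_rows else np.zeros((0, n))
    N = null_space(A) if A.shape[0] else np.eye(n)
    if N.size and S.shape[0]:
        resid = float(np.max(np.abs(S @ N)))
        if resid > basis_tol:  # pragma: no cover - defensive
            raise RuntimeError(f"null-space basis residual {resid:g} > {basis_tol:g}")
    if N.shape[1] == 0:
        raise InfeasiblePolytopeError(
            f"model {model.id!r}: polytope has dimension 0 (all fluxes fixed)"
        )
    return FluxPolytope(
        basis=N,
        anchor=anchor,
        lb=lb,
        ub=ub,
        reaction_ids=model.reaction_ids(),
    )


# ---------------------------------------------------------------------------
# the chain kernel


@njit(cache=False)
def _chrr_kernel(v, D, lb, ub, coords, uniforms, warmup, thinning, out):  # pragma: no cover
    n = v.shape[0]
    total = coords.shape[0]
    stored = 0
    moved = 0
    for it in range(total):
        c = coords[it]
        tmin = -1.0e30
        tmax = 1.0e30
        for j in range(n):
            d = D[j, c]
            if d > 1e-14 or d < -1e-14:
                a = (lb[j] - v[j]) / d
                b = (ub[j] - v[j]) / d
                if a > b:
                    a, b = b, a
                if a > tmin:
                    tmin = a
                if b < tmax:
                    tmax = b
        tmin += CHORD_CLIP
        tmax -= CHORD_CLIP
        if tmax > tmin:
            t = tmin + uniforms[it] * (tmax - tmin)
            for j in range(n):
                v[j] = v[j] + t * D[j, c]
            moved += 1
        if it >= warmup and (it - warmup + 1) % thinning == 0:
            if stored < out.shape[0]:
                for j in range(n):
                    out[stored, j] = v[j]
                stored += 1
    return moved


_py_kernel = _chrr_kernel.py_func if HAVE_NUMBA else _chrr_kernel


def sample_fluxes(
    polytope: FluxPolytope,
    total_iterations: int,
    thinning: int,
    seed: int,
    warmup: int | None = None,
    phase: str = "",
) -> FluxSampleSet:
    """Run coordinate hit-and-run on the (rounded) polytope.

    ``warmup`` extra iterations (default: one thinning interval) are run
    and discarded before storage begins; exactly
    ``floor(total_iterations / thinning)`` rows are stored.  Deterministic
    given ``seed``.
    """
    n_stored = n_stored_for(total_iterations, thinning)
    if warmup is None:
        warmup = thinning
    rng = np.random.default_rng(seed)
    steps = warmup + total_iterations
    coords = rng.integers(0, polytope.dim, size=steps).astype(np.int64)
    uniforms = rng.random(steps)

    D = np.ascontiguousarray(polytope.directions)
    v = polytope.anchor.copy()
    out = np.empty((n_stored, len(polytope.reaction_ids)))
    moved = _chrr_kernel(
        v, D, polytope.lb, polytope.ub, coords, uniforms, warmup, thinning, out
    )
    if moved == 0:
        raise SamplerStuckError(
            "every proposed chord had zero length; the polytope is degenerate "
            "along all coordinate directions (check for bound constraints "
            "pinning the anchor to a face)"
        )
    return FluxSampleSet(
        samples=out,
        reaction_ids=list(polytope.reaction_ids),
        seed=seed,
        total_iterations=total_iterations,
        thinning=thinning,
        phase=phase,
    )


def round_polytope(
    polytope: FluxPolytope,
    seed: int,
    pilot_points: int | None = None,
    max_rounds: int = 10,
    growth_tol: float = 1.25,
    cond_max: float = 1e14,
) -> FluxPolytope:
    """Estimate a rounding transform from adaptive pilot chains.

    Each round runs a pilot chain (default ``20 * k`` stored points,
    thinned by ``k``) under the current transform, takes the covariance of
    the null-space coordinates of the stored points, and replaces the
    transform with the covariance's Cholesky factor; the anchor is
    re-centered at the pilot sample mean (feasible by convexity).  Rounds
    stop once the explored scale stops growing (largest per-round variance
    growth below ``growth_tol``), so badly elongated polytopes are
    discovered progressively.  Falls back to the identity transform for
    k <= 2 or a near-singular covariance.
    """
    k = polytope.dim
    if k <= 2:
        return polytope
    if pilot_points is None:
        pilot_points = 20 * k
    pilot_thin = max(k, 1)
    seeds = np.random.SeedSequence(seed).generate_state(max_rounds) % (2**31)

    current = polytope
    prev_scale = None
    for rnd in range(max_rounds):
        pilot = sample_fluxes(
            current,
            total_iterations=pilot_points * pilot_thin,
            thinning=pilot_thin,
            seed=int(seeds[rnd]),
        )
        # null-space coordinates of the pilot points (basis is orthonormal)
        X = (pilot.samples - polytope.anchor) @ polytope.basis
        cov = np.atleast_2d(np.cov(X, rowvar=False))
        try:
            eigvals = np.linalg.eigvalsh(cov)
            if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > cond_max:
                logger.warning("pilot covariance near-singular; keeping previous transform")
                return current
            T = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            logger.warning("pilot covariance not factorizable; keeping previous transform")
            return current
        anchor = pilot.samples.mean(axis=0)
        current = FluxPolytope(
            basis=polytope.basis,
            anchor=anchor,
            lb=polytope.lb,
            ub=polytope.ub,
            reaction_ids=polytope.reaction_ids,
            transform=T,
        )
        scale = np.sqrt(np.maximum(eigvals, 1e-300))
        if prev_scale is not None:
            growth = float(np.max(scale) / np.max(prev_scale))
            if growth < growth_tol:
                break
        prev_scale = scale
    return current


def sample_model(
    model: MetabolicModel,
    total_iterations: int,
    thinning: int,
    seed: int,
    warmup: int | None = None,
    rounding: bool = True,
    phase: str = "",
) -> FluxSampleSet:
    """Build, round and sample a model's flux polytope in one call."""
    polytope = build_polytope(model)
    if rounding:
        # independent stream for the pilot chain
        pilot_seed = int(np.random.SeedSequence(seed).spawn(1)[0].generate_state(1)[0] % (2**31))
        polytope = round_polytope(polytope, seed=pilot_seed)
    return sample_fluxes(
        polytope, total_iterations, thinning, seed, warmup=warmup, phase=phase
    )


# ---------------------------------------------------------------------------
# validation


def validate_samples(
    samples: FluxSampleSet, model: MetabolicModel, tol: float = SAMPLE_TOL
) -> tuple[bool, dict]:
    """Check every stored row for steady state (``||S v||_max <= tol``) and
    bound satisfaction (slack ``tol``); returns (ok, report)."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    V = samples.samples
    ss_resid = np.abs(S @ V.T)
    max_resid = float(ss_resid.max()) if ss_resid.size else 0.0
    lb_viol = np.maximum(lb - V, 0.0)
    ub_viol = np.maximum(V - ub, 0.0)
    max_bound = float(max(lb_viol.max(initial=0.0), ub_viol.max(initial=0.0)))
    per_row = np.zeros(V.shape[0])
    if ss_resid.size:
        per_row = ss_resid.max(axis=0)
    per_row = np.maximum(per_row, np.maximum(lb_viol.max(axis=1), ub_viol.max(axis=1)))
    worst = int(np.argmax(per_row)) if len(per_row) else -1
    ok = bool(max_resid <= tol and max_bound <= tol)
    return ok, {
        "max_steady_state_residual": max_resid,
        "max_bound_violation": max_bound,
        "worst_row": worst,
        "n_rows": V.shape[0],
        "tol": tol,
    }
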