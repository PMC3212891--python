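"""Ensemble averaging and least-squares recovery of regional Young's moduli.

In the linear-elastic regime the displacement field scales with the applied
force, so replicate measurements taken at different forces are normalised
by their force magnitudes and averaged site by site, which suppresses the
large single-measurement PIV noise before inversion.

The inverse problem matches the forward model's displacement field,
interpolated to the measurement lattice, to the (averaged) measured field
by minimising the summed squared vector differences over valid lattice
sites; with two load cases (midline and area-pellucida forces) the
objective is the plain sum of the two case errors and the moduli are
common to both, which lifts the degeneracy a single field leaves.  Moduli
are optimised in log space under box bounds with a trust-region reflective
least-squares solver; the modulus Jacobian is computed exactly from the
factorised stiffness matrix, which keeps each iteration at roughly the
cost of one forward solve per case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .fields import DisplacementGrid, Lattice
from .forward import (
    Mesh,
    PlaneStressOperator,
    PointLoad,
    RegionGeometry,
    morph_mesh,
)

__all__ = [
    "EnsembleField",
    "LoadCase",
    "FitResult",
    "normalize_and_average",
    "objective",
    "fit_moduli",
    "fit_geometry_and_moduli",
    "bootstrap_fit",
    "DEFAULT_BOUNDS_PA",
]

#: default box bounds on each regional modulus, Pa
DEFAULT_BOUNDS_PA = (10.0, 1e6)


@dataclass
class EnsembleField:
    """Force-normalised ensemble average of replicate displacement fields.

    ``mean.u`` is in um/nN; ``sd`` holds the standard error of the mean per
    component (um/nN) on the same lattice; ``n`` is the replicate count.
    """

    mean: DisplacementGrid
    sd: Optional[np.ndarray]
    n: int

    def at_force(self, force_n: float) -> DisplacementGrid:
        """The averaged field rescaled to a force of ``force_n`` (N), um."""
        return self.mean.scaled(force_n * 1e9)


@dataclass
class LoadCase:
    """One load case: the applied load, the measured field, and its mesh."""

    load: PointLoad
    measured: Union[DisplacementGrid, EnsembleField]
    mesh: Mesh

    def target_grid(self) -> DisplacementGrid:
        """Measured displacement (um) at this case's applied force."""
        if isinstance(self.measured, EnsembleField):
            return self.measured.at_force(self.load.magnitude)
        return self.measured


@dataclass
class FitResult:
    """Outcome of a modulus (or joint geometry) fit."""

    youngs_moduli: Dict[str, float]
    uncertainties: Dict[str, float]
    error_trace: List[float]
    n_iterations: int
    converged: bool
    residual_rms_um: float
    n_sites: int
    meta: dict = field(default_factory=dict)

    @property
    def final_error_um2(self) -> float:
        return self.error_trace[-1] if self.error_trace else float("nan")


def normalize_and_average(
    fields: Sequence[DisplacementGrid], forces_n: Sequence[float]
) -> EnsembleField:
    """Average replicate fields after normalising each by its force.

    Site-wise mean and standard error of u_i / F_i are computed over the
    intersection of the replicates' valid masks.  Fields are in um and
    forces in N; the ensemble is expressed per nN.
    """
    if len(fields) != len(forces_n):
        raise ValueError("fields and forces must have equal length")
    if len(fields) == 0:
        raise ValueError("at least one field is required")
    first = fields[0]
    valid = first.valid.copy()
    for f in fields[1:]:
        if not first.same_lattice(f):
            raise ValueError("all fields must share one lattice geometry")
        valid &= f.valid
    forces_nN = np.asarray(forces_n, dtype=float) * 1e9
    if np.any(forces_nN <= 0):
        raise ValueError("forces must be positive")
    stack = np.stack([f.u / fn for f, fn in zip(fields, forces_nN)])
    mean = stack.mean(axis=0)
    n = len(fields)
    if n > 1:
        sd = stack.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sd = np.zeros_like(mean)
    grid = replace(first, u=mean, sd=sd, valid=valid, meta={"n_replicates": n})
    return EnsembleField(mean=grid, sd=sd, n=n)


# ---------------------------------------------------------------------------
# the joint objective
# ---------------------------------------------------------------------------

class _CaseProblem:
    """Forward operator plus measured target for one load case."""

    def __init__(self, case: LoadCase, geometry: RegionGeometry, nu: float):
        target = case.target_grid()
        self.lattice = target.lattice
        self.op = PlaneStressOperator(
            case.mesh, geometry, nu, case.load, lattice=self.lattice
        )
        self.mask = (target.valid & self.op.grid_valid.reshape(target.shape)).ravel()
        self.u_meas = target.u.reshape(-1, 2)[self.mask]
        self.n_sites = int(np.count_nonzero(self.mask))
        self.label = case.load.label

    def residuals(self, moduli: Dict[str, float]) -> np.ndarray:
        try:
            g = self.op.solve_grid(moduli)
        except Exception as err:  # propagate with the case label
            raise RuntimeError(f"forward solve failed for case {self.label!r}") from err
        return (g.u.reshape(-1, 2)[self.mask] - self.u_meas).ravel()

    def jacobian(self, moduli: Dict[str, float]) -> np.ndarray:
        J = self.op.grid_jacobian(moduli)  # (sites, 2, n_regions)
        return J[self.mask].reshape(-1, J.shape[-1])


def _problems(
    cases: Sequence[LoadCase], geometry: RegionGeometry, nu: float
) -> List[_CaseProblem]:
    if not cases:
        raise ValueError("at least one load case is required")
    return [_CaseProblem(c, geometry, nu) for c in cases]


def _as_moduli_map(moduli, regions: Sequence[str]) -> Dict[str, float]:
    if isinstance(moduli, dict):
        return {r: float(moduli[r]) for r in regions}
    vec = np.asarray(moduli, dtype=float)
    if vec.size != len(regions):
        raise ValueError(f"expected {len(regions)} moduli for regions {regions}")
    return dict(zip(regions, vec))


def objective(
    moduli, cases: Sequence[LoadCase], geometry: RegionGeometry, nu: float = 0.3
) -> float:
    """Summed squared displacement mismatch over all cases, um^2.

    ``moduli`` is a region->Pa map or a vector ordered as
    ``geometry.region_names``.  For each case the forward model is solved,
    interpolated to the case lattice, and the squared vector differences
    accumulated over valid sites; multiple cases contribute additively.
    """
    m = _as_moduli_map(moduli, geometry.region_names)
    probs = _problems(cases, geometry, nu)
    return float(sum(np.sum(p.residuals(m) ** 2) for p in probs))


# ---------------------------------------------------------------------------
# modulus fitting
# ---------------------------------------------------------------------------

def fit_moduli(
    cases: Sequence[LoadCase],
    geometry: RegionGeometry,
    nu: float = 0.3,
    init: Optional[Union[Dict[str, float], Sequence[float]]] = None,
    bounds: Tuple[float, float] = DEFAULT_BOUNDS_PA,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FitResult:
    """Bounded nonlinear least squares for the regional Young's moduli.

    Moduli are parameterised as log E (positivity; the expected spread is
    roughly 1-12 kPa) inside box bounds (Pa).  Convergence follows the
    trust-region reflective criteria: relative cost decrease below ``tol``
    or a relative parameter step below 1e-4; at most ``max_iter``
    iterations, after which the best point is returned with
    ``converged=False``.  Parameter uncertainties are linearised from the
    residual Jacobian at the solution.
    """
    regions = list(geometry.region_names)
    probs = _problems(cases, geometry, nu)
    if init is None:
        init = {r: 1000.0 for r in regions}
    m0 = _as_moduli_map(init, regions)
    z0 = np.log(np.array([m0[r] for r in regions]))
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    if np.any(z0 < lo) or np.any(z0 > hi):
        raise ValueError("initial moduli must lie within bounds")

    trace: List[float] = []
    cost_cache: Dict[bytes, float] = {}

    def resid(z):
        m = dict(zip(regions, np.exp(z)))
        r = np.concatenate([p.residuals(m) for p in probs])
        cost_cache[z.tobytes()] = float(np.sum(r**2))
        return r

    def jac(z):
        E = np.exp(z)
        m = dict(zip(regions, E))
        J = np.vstack([p.jacobian(m) for p in probs])
        key = z.tobytes()
        if key not in cost_cache:
            resid(z)
        trace.append(cost_cache[key])  # cost at each accepted iterate
        return J * E[None, :]  # chain rule: d r / d log E

    res = least_squares(
        resid, z0, jac=jac, bounds=(lo, hi), method="trf",
        ftol=tol, xtol=1e-4, gtol=1e-12, max_nfev=8 * max_iter,
    )
    n_iter = int(res.njev)
    error = float(2.0 * res.cost)  # um^2
    if not trace or trace[-1] > error:
        trace.append(error)
    # keep the accepted-step envelope monotone
    trace = list(np.minimum.accumulate(trace))

    E_hat = np.exp(res.x)
    n_sites = sum(p.n_sites for p in probs)
    m_resid = res.fun.size
    dof = max(m_resid - len(regions), 1)
    s2 = error / dof
    try:
        JTJ = res.jac.T @ res.jac
        cov_z = s2 * np.linalg.inv(JTJ)
        sd_E = E_hat * np.sqrt(np.clip(np.diag(cov_z), 0.0, None))
    except np.linalg.LinAlgError:
        sd_E = np.full(len(regions), np.nan)

    converged = bool(res.status > 0) and n_iter <= max_iter
    return FitResult(
        youngs_moduli=dict(zip(regions, E_hat)),
        uncertainties=dict(zip(regions, sd_E)),
        error_trace=trace,
        n_iterations=n_iter,
        converged=converged,
        residual_rms_um=float(np.sqrt(error / max(n_sites, 1))),
        n_sites=n_sites,
        meta={
            "status": int(res.status),
            "message": res.message,
            "nfev": int(res.nfev),
            "bounds_pa": tuple(bounds),
            "nu": nu,
        },
    )


def bootstrap_fit(
    replicate_sets: Sequence[Tuple[Sequence[DisplacementGrid], Sequence[float]]],
    loads: Sequence[PointLoad],
    meshes: Sequence[Mesh],
    geometry: RegionGeometry,
    nu: float = 0.3,
    n_bootstrap: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> Dict[str, np.ndarray]:
    """Replicate-bootstrap spread of the fitted moduli.

    Each draw resamples the replicates of every case with replacement,
    re-averages, and refits; returns region -> array of bootstrap moduli.
    This complements the linearised uncertainties of :func:`fit_moduli`
    when replicate scatter (not just lattice noise) dominates.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, List[float]] = {r: [] for r in geometry.region_names}
    for _ in range(n_bootstrap):
        cases = []
        for (fields, forces), load, mesh in zip(replicate_sets, loads, meshes):
            idx = rng.integers(0, len(fields), size=len(fields))
            ens = normalize_and_average(
                [fields[i] for i in idx], [forces[i] for i in idx]
            )
            cases.append(LoadCase(load=load, measured=ens, mesh=mesh))
        fit = fit_moduli(cases, geometry, nu=nu, **fit_kwargs)
        for r, e in fit.youngs_moduli.items():
            out[r].append(e)
    return {r: np.asarray(v) for r, v in out.items()}


# ---------------------------------------------------------------------------
# joint geometry + modulus fitting
# ---------------------------------------------------------------------------

_RADII_FIELDS = {
    "midline": "midline_semi_axes",
    "intermediate": "intermediate_semi_axes",
    "pellucida": "pellucida_semi_axes",
}


def _with_semi_axes(
    geometry: RegionGeometry, which: Sequence[str], values: np.ndarray
) -> RegionGeometry:
    kwargs = {
        "midline_semi_axes": geometry.midline_semi_axes,
        "pellucida_semi_axes": geometry.pellucida_semi_axes,
        "outer_radius": geometry.outer_radius,
        "thicknesses": geometry.thicknesses,
        "intermediate_semi_axes": geometry.intermediate_semi_axes,
    }
    k = 0
    for name in which:
        kwargs[_RADII_FIELDS[name]] = (float(values[k]), float(values[k + 1]))
        k += 2
    return RegionGeometry(**kwargs)


def _radii_bounds(
    geometry: RegionGeometry, which: Sequence[str], margin: float = 0.02
) -> Tuple[np.ndarray, np.ndarray]:
    """Nesting-safe box bounds for the selected semi-axis parameters (mm)."""
    chain = [name for name, _ in geometry.ellipse_chain]
    radii = {name: ax for name, ax in geometry.ellipse_chain}
    radii["outer"] = (geometry.outer_radius, geometry.outer_radius)
    lo, hi = [], []
    for name in which:
        key = {"pellucida": "area_pellucida"}.get(name, name)
        i = chain.index(key)
        inner = radii[chain[i - 1]] if i > 0 else (0.0, 0.0)
        outer = radii[chain[i + 1]] if i + 1 < len(chain) else radii["outer"]
        for k in range(2):
            lo.append(inner[k] + margin)
            hi.append(outer[k] - margin)
    return np.array(lo), np.array(hi)


def fit_geometry_and_moduli(
    cases: Sequence[LoadCase],
    geometry: RegionGeometry,
    nu: float = 0.3,
    init: Optional[Union[Dict[str, float], Sequence[float]]] = None,
    which_radii: Sequence[str] = ("pellucida",),
    bounds: Tuple[float, float] = DEFAULT_BOUNDS_PA,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Tuple[FitResult, RegionGeometry]:
    """Jointly fit regional moduli and selected region semi-axes.

    Requires exactly two load cases (the joint constraint that makes the
    extra geometric degrees of freedom identifiable).  Each ellipse named
    in ``which_radii`` ('midline' | 'intermediate' | 'pellucida')
    contributes its two semi-axes to the parameter vector; for every
    candidate the reference meshes are smoothly morphed onto the candidate
    geometry and the operators rebuilt, so the objective is deterministic
    and continuous in the radii.  Radii are box-constrained to preserve
    region nesting; fits that press against those bounds are noted in the
    result metadata.
    """
    if len(cases) != 2:
        raise ValueError("joint geometry fitting requires exactly 2 load cases")
    for name in which_radii:
        if name not in _RADII_FIELDS:
            raise ValueError(f"unknown radii selector {name!r}")
        if name == "intermediate" and geometry.intermediate_semi_axes is None:
            raise ValueError("3-region geometry has no intermediate radii")
    regions = list(geometry.region_names)
    if init is None:
        init = {r: 1000.0 for r in regions}
    m0 = _as_moduli_map(init, regions)
    z0 = np.log(np.array([m0[r] for r in regions]))
    r0 = np.concatenate([
        np.asarray(geometry.semi_axes_of(
            {"pellucida": "area_pellucida"}.get(n, n)), float)
        for n in which_radii
    ])
    lo_r, hi_r = _radii_bounds(geometry, which_radii)
    lo = np.concatenate([np.full(len(regions), np.log(bounds[0])), lo_r])
    hi = np.concatenate([np.full(len(regions), np.log(bounds[1])), hi_r])
    x0 = np.concatenate([z0, np.clip(r0, lo_r, hi_r)])

    targets = [c.target_grid() for c in cases]
    trace: List[float] = []

    def resid(x):
        z, rv = x[: len(regions)], x[len(regions):]
        geo = _with_semi_axes(geometry, which_radii, rv)
        m = dict(zip(regions, np.exp(z)))
        rs = []
        for case, tgt in zip(cases, targets):
            mesh = morph_mesh(case.mesh, geometry, geo)
            op = PlaneStressOperator(mesh, geo, nu, case.load, lattice=tgt.lattice)
            mask = (tgt.valid & op.grid_valid.reshape(tgt.shape)).ravel()
            g = op.solve_grid(m)
            rs.append((g.u.reshape(-1, 2)[mask] - tgt.u.reshape(-1, 2)[mask]).ravel())
        r = np.concatenate(rs)
        trace.append(float(np.sum(r**2)))
        return r

    res = least_squares(
        resid, x0, bounds=(lo, hi), method="trf",
        ftol=tol, xtol=1e-4, gtol=1e-12, max_nfev=max_iter * (len(x0) + 1) * 2,
        diff_step=1e-3,
    )
    z_hat = res.x[: len(regions)]
    r_hat = res.x[len(regions):]
    geo_hat = _with_semi_axes(geometry, which_radii, r_hat)
    at_bounds = bool(np.any(np.isclose(r_hat, lo_r)) or np.any(np.isclose(r_hat, hi_r)))
    error = float(2.0 * res.cost)
    n_sites = res.fun.size // 2
    mono = list(np.minimum.accumulate(trace)) if trace else [error]
    n_iter = int(res.njev)
    return (
        FitResult(
            youngs_moduli=dict(zip(regions, np.exp(z_hat))),
            uncertainties={r: float("nan") for r in regions},
            error_trace=mono,
            n_iterations=n_iter,
            converged=bool(res.status > 0),
            residual_rms_um=float(np.sqrt(error / max(n_sites, 1))),
            n_sites=n_sites,
            meta={
                "radii": {n: tuple(geo_hat.semi_axes_of(
                    {"pellucida": "area_pellucida"}.get(n, n)))
                    for n in which_radii},
                "radii_at_bounds": at_bounds,
                "status": int(res.status),
            },
        ),
        geo_hat,
    )
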