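"""Relative-stiffness reconstruction by density-based topology optimization.

The elastography core: given a measured displacement field, iteratively
update per-element densities ``rho_k`` (modulus ``E_k = rho_k**p * E0``,
p = 1) so that the forward model reproduces the measurement.  Measured
displacements are prescribed on all boundary nodes (Dirichlet data); the
design objective is the worst weighted displacement mismatch over internal
nodes,

    F = max_i  w_i * |dx_exp(P_i) - dx_sim(P_i)|,

optimized through a smooth p-norm surrogate with adjoint sensitivities,
cone-filtered element gradients, and a move-limited MMA-style update (a
projected-gradient update is selectable).  Under pure-Dirichlet data only
stiffness ratios are identifiable, so maps are reported normalized to mean
relative stiffness 0.5.

Usage follows the model/results convention::

    problem = InverseProblem.from_field(field)
    results = problem.fit()
    print(results.summary())
    rho = results.relative_stiffness
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .fem import CachedSolver, DirichletBC, MaterialField
from .fields import DisplacementField
from .meshing import FEMesh, GridMeshMap, grid_mesh_map, interpolate_to_mesh, mesh_from_mask


@dataclass
class OptimizerSettings:
    """Iteration, aggregation, filtering and step-size controls.

    max_iterations : hard iteration cap; default (None) resolves per problem
        to 100 (move-limited methods, 2D), 400 (move-limited, 3D: slower
        per-iteration convergence with volumetric elements) or 200
        (quasi-Newton).
    objective_tolerance : relative objective change below which an iteration
        counts as stationary; ``patience`` consecutive stationary iterations
        terminate the run.
    aggregation_exponent : exponent of the smooth p-norm surrogate for the
        min-max objective (default 12).
    filter_radius : sensitivity-filter radius in mm; default (None) is twice
        the element size.
    move_limit : per-iteration density change cap (mma/pg).
    method : 'auto' (default), 'mma', 'pg' or 'lbfgs'.  'mma' takes
        move-limited separable-convex-approximation steps accepted only when
        the true min-max objective improves — the conservative choice for
        noisy data, paired with the discrepancy stopping floor; 'pg' is a
        Barzilai-Borwein projected gradient with the same acceptance;
        'lbfgs' is bound-constrained quasi-Newton descent of the filtered
        surrogate, which converges much deeper and suits clean data.
        'auto' selects 'lbfgs' when the problem has no noise floor and
        'mma' otherwise.
    seed : seed for any stochastic restart (the default methods are
        deterministic; kept for reproducibility bookkeeping).
    """

    max_iterations: int | None = None
    objective_tolerance: float = 1e-4
    aggregation_exponent: float = 12.0
    filter_radius: float | None = None
    move_limit: float = 0.1
    seed: int = 0
    method: str = "auto"
    patience: int = 5
    rho_init: float = 0.5
    objective_atol: float = 1e-9  # mm; measured==simulated to solver tolerance
    surrogate_guard: float = 1.05  # accepted steps may raise the surrogate by <=5%

    def __post_init__(self):
        if self.max_iterations is not None and self.max_iterations <= 0:
            raise ValueError("max_iterations must be positive")
        if self.objective_tolerance <= 0:
            raise ValueError("objective_tolerance must be positive")
        if self.aggregation_exponent <= 1:
            raise ValueError("aggregation_exponent must exceed 1")
        if not (0 < self.move_limit < 1):
            raise ValueError("move_limit must be in (0, 1)")


@dataclass
class OptimizationState:
    """Trajectory of one inversion run."""

    iteration: int
    rho: np.ndarray
    objective: float
    surrogate: float
    history: list
    surrogate_history: list
    converged: bool
    n_rejected: int = 0


# ---------------------------------------------------------------------------
# objective and sensitivities


def objective(measured, simulated, weights=None, exponent: float = 12.0):
    """Min-max displacement-mismatch objective and its smooth surrogate.

    Returns ``(F, F_surrogate)`` where ``F = max w_i |r_i|`` over all rows
    (nodes) and components and the surrogate is the weighted p-norm that the
    gradients differentiate.  Rows are the internal target nodes.
    """
    measured = np.atleast_2d(np.asarray(measured, dtype=float))
    simulated = np.atleast_2d(np.asarray(simulated, dtype=float))
    if measured.shape != simulated.shape:
        raise ValueError("measured and simulated shapes differ")
    if measured.size == 0:
        raise ValueError("empty node set")
    if weights is None:
        weights = np.ones(len(measured))
    a = np.abs(measured - simulated) * np.asarray(weights, dtype=float)[:, None]
    m = a.max()
    if m == 0:
        return 0.0, 0.0
    surr = m * ((a / m) ** exponent).sum() ** (1.0 / exponent)
    return float(m), float(surr)


def _surrogate_and_grad(resid: np.ndarray, w_dof: np.ndarray, exponent: float):
    """Surrogate value and d(surrogate)/d(residual) on flat DOF vectors."""
    a = np.abs(resid) * w_dof
    m = a.max()
    if m == 0:
        return 0.0, np.zeros_like(resid)
    s = ((a / m) ** exponent).sum()
    surr = m * s ** (1.0 / exponent)
    g = (a / m) ** (exponent - 1) / s ** ((exponent - 1) / exponent)
    return float(surr), g * w_dof * np.sign(resid)


def objective_gradient(solver: CachedSolver, u: np.ndarray, lu, dFdu: np.ndarray,
                       dE: np.ndarray) -> np.ndarray:
    """Adjoint sensitivity dF/drho_k of the surrogate.

    One adjoint solve with the already-factorized stiffness:
    ``K_ff lam = dF/du_f``, then ``dF/drho_k = -dE_k * lam_e^T K0_e u_e``.
    """
    lam = np.zeros_like(u)
    lam[solver.free] = lu.solve(dFdu[solver.free])
    ue = u[solver.edof]
    le = lam[solver.edof]
    ku = np.einsum("eij,ej->ei", solver.Ke0, ue)
    return -dE * np.einsum("ei,ei->e", le, ku)


def build_filter(mesh: FEMesh, radius: float) -> sp.csr_matrix:
    """Cone-weighted (linear decay) neighbourhood-average matrix over elements.

    Weights ``max(0, 1 - d/r)`` over centroid distances, rows normalized to
    sum 1; radius below the inter-element distance reduces to the identity.
    """
    cent = mesh.centroids
    tree = cKDTree(cent)
    coo = tree.sparse_distance_matrix(tree, radius, output_type="coo_matrix")
    w = np.maximum(0.0, 1.0 - coo.data / radius)
    H = sp.csr_matrix((w, (coo.row, coo.col)), shape=coo.shape)
    H = H + sp.eye(mesh.n_elements, format="csr") * 0.0  # ensure diagonal slots
    H.setdiag(np.maximum(H.diagonal(), 1.0))
    rowsum = np.asarray(H.sum(axis=1)).ravel()
    return sp.diags(1.0 / rowsum) @ H


def filter_sensitivities(gradient: np.ndarray, mesh: FEMesh, radius: float,
                         H: sp.csr_matrix | None = None) -> np.ndarray:
    """Apply the cone sensitivity filter (regularizes and de-meshes the problem)."""
    if H is None:
        H = build_filter(mesh, radius)
    return H @ gradient


# ---------------------------------------------------------------------------
# density updates


def update_densities(rho, gradient, settings: OptimizerSettings, rho_min: float,
                     state: dict | None = None, move_scale: float | None = None):
    """One move-limited density update from the filtered gradient.

    ``method='mma'`` solves the separable convex (method-of-moving-asymptotes)
    approximation in closed form (no constraints beyond the box);
    ``method='pg'`` takes a Barzilai-Borwein projected-gradient step.  A zero
    gradient returns ``rho`` unchanged; results are clipped to
    ``[rho_min, 1]`` and to the move limit.
    """
    state = {} if state is None else state
    move = settings.move_limit if move_scale is None else move_scale
    g = np.asarray(gradient, dtype=float)
    if not np.any(g):
        return rho.copy()
    lo_b = np.maximum(rho_min, rho - move)
    up_b = np.minimum(1.0, rho + move)
    if settings.method == "pg":
        gnorm = np.abs(g).max()
        t = state.get("bb_step", move / gnorm)
        return np.clip(rho - t * g, lo_b, up_b)
    # MMA asymptotes
    span = 1.0 - rho_min
    it = state.get("iteration", 0)
    if it < 2 or "low" not in state:
        low = rho - 0.5 * span
        upp = rho + 0.5 * span
    else:
        x1, x2 = state["rho_prev1"], state["rho_prev2"]
        osc = (rho - x1) * (x1 - x2)
        gamma = np.where(osc > 0, 1.2, np.where(osc < 0, 0.7, 1.0))
        low = rho - gamma * (x1 - state["low"])
        upp = rho + gamma * (state["upp"] - x1)
        low = np.clip(low, rho - 10 * span, rho - 0.01 * span)
        upp = np.clip(upp, rho + 0.01 * span, rho + 10 * span)
    state["low"], state["upp"] = low, upp
    alpha = np.maximum(lo_b, low + 0.1 * (rho - low))
    beta = np.minimum(up_b, upp - 0.1 * (upp - rho))
    gp = np.maximum(g, 0.0)
    gm = np.maximum(-g, 0.0)
    raa = 1e-6 * np.abs(g).mean() + 1e-30
    p = (upp - rho) ** 2 * (1.001 * gp + 0.001 * gm + raa)
    q = (rho - low) ** 2 * (0.001 * gp + 1.001 * gm + raa)
    sp_, sq = np.sqrt(p), np.sqrt(q)
    x = (low * sp_ + upp * sq) / (sp_ + sq)
    return np.clip(x, alpha, beta)


# ---------------------------------------------------------------------------
# post-processing


def normalize_relative_stiffness(rho: np.ndarray, measures: np.ndarray | None = None
                                 ) -> np.ndarray:
    """Rescale a density map to mean relative stiffness 0.5 (ratios preserved).

    The absolute scale is unidentifiable under pure-Dirichlet data, so maps
    are reported on the convention mean = 0.5; values are clipped to (0, 1].
    ``measures`` (element areas/volumes) weight the mean on irregular meshes.
    """
    rho = np.asarray(rho, dtype=float)
    mean = np.average(rho, weights=measures)
    if mean <= 0:
        raise ValueError("density map has non-positive mean")
    return np.clip(rho * (0.5 / mean), np.finfo(float).tiny, 1.0)


def region_ratio(values: np.ndarray, labels: np.ndarray,
                 measures: np.ndarray | None = None):
    """Mean stiffness per labeled region and all pairwise region-mean ratios.

    Returns ``(means, ratios)``: ``means[label]`` and
    ``ratios[(a, b)] = means[a] / means[b]``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 1:
        raise ValueError("no regions")
    means = {}
    for lab in uniq:
        sel = labels == lab
        if not sel.any():
            raise ValueError(f"region {lab} is empty")
        w = None if measures is None else measures[sel]
        means[lab] = float(np.average(values[sel], weights=w))
    ratios = {
        (a, b): means[a] / means[b] for a in uniq for b in uniq if a != b
    }
    return means, ratios


def bc_from_measured(mesh: FEMesh, nodal_values: np.ndarray) -> DirichletBC:
    """Inversion boundary preset: measured displacements prescribed (all
    components) at every boundary node."""
    return DirichletBC(mesh.boundary_nodes, nodal_values[mesh.boundary_nodes])


def outlier_weights(raw: DisplacementField, smoothed: DisplacementField,
                    threshold: float = 3.0) -> np.ndarray:
    """Optional pre-pass: down-weight pixels whose raw-minus-smoothed residual
    exceeds ``threshold`` robust standard deviations (weight = thr*sd/|r|)."""
    resid = np.abs(raw.components - smoothed.components).max(axis=0)
    r = resid[raw.mask]
    sd = 1.4826 * np.median(np.abs(r - np.median(r)))
    w = np.ones_like(resid)
    if sd > 0:
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, threshold * sd / np.where(resid > 0, resid, np.inf))
    return np.where(raw.mask, w, 0.0)


# ---------------------------------------------------------------------------
# model / results


@dataclass
class InverseProblem:
    """Elastography inverse model: mesh + targets + Dirichlet data + settings.

    Build from arrays, or from a :class:`DisplacementField` with
    :meth:`from_field`.  ``fit`` runs the topology-optimization loop and
    returns an :class:`InversionResults`.
    """

    mesh: FEMesh
    measured: np.ndarray              # (n_nodes, dim) target displacements, mm
    bc: DirichletBC
    material: MaterialField | None = None
    weights: np.ndarray | None = None  # per-node objective weights
    target_nodes: np.ndarray | None = None
    settings: OptimizerSettings = dfield(default_factory=OptimizerSettings)
    thickness: float = 1.0
    sri: bool = False
    gmap: GridMeshMap | None = None
    objective_floor: float = 0.0  # mm; discrepancy stopping level (noise floor)

    def __post_init__(self):
        self.measured = np.asarray(self.measured, dtype=float)
        if self.measured.shape != (self.mesh.n_nodes, self.mesh.dimension):
            raise ValueError("measured must be (n_nodes, dim)")
        if self.material is None:
            self.material = MaterialField.uniform(
                self.mesh.n_elements, self.settings.rho_init
            )
        if self.weights is None:
            self.weights = np.ones(self.mesh.n_nodes)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.target_nodes is None:
            self.target_nodes = self.mesh.interior_nodes
        self.target_nodes = np.asarray(self.target_nodes, dtype=np.int64)
        bset = set(self.mesh.boundary_nodes.tolist())
        if any(int(t) in bset for t in self.target_nodes):
            raise ValueError("target nodes must exclude boundary nodes")
        if len(self.target_nodes) == 0:
            raise ValueError("at least one internal target node is required")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_field(
        cls,
        field: DisplacementField,
        mesh: FEMesh | None = None,
        target_element_size: float | None = None,
        family: str | None = None,
        settings: OptimizerSettings | None = None,
        E0: float = 500.0,
        nu: float = 0.49,
        rho_min: float = 0.01,
        penal: float = 1.0,
        thickness: float = 1.0,
        sri: bool = False,
        gmap: GridMeshMap | None = None,
        noise_weighting: bool = True,
        weight_cap: float = 20.0,
    ) -> "InverseProblem":
        """Build the inverse model from a measured displacement field.

        The mesh is built from the field mask unless given; measured values
        are interpolated to nodes, boundary nodes become Dirichlet data and
        interior nodes become objective targets.  Per-pixel field weights are
        carried to the nodes.

        When the field carries an ``uncertainty`` map (set by the smoothers)
        and ``noise_weighting`` is on, nodes are additionally weighted by the
        median-normalized reciprocal of their local uncertainty (unreliable
        nodes are down-voted) and the objective's discrepancy floor is set to
        the median uncertainty: the fit stops once the worst weighted misfit
        is within the data's own error band.
        """
        settings = settings or OptimizerSettings()
        if mesh is None:
            mesh = mesh_from_mask(field.mask, field.spacing, field.origin,
                                  target_element_size, family)
        if gmap is None:
            gmap = grid_mesh_map(mesh, field)
        measured, flagged = interpolate_to_mesh(field, mesh, gmap)
        wpix = field.weights.copy()
        floor = 0.0
        if noise_weighting and field.uncertainty is not None:
            u = field.uncertainty.max(axis=0)
            u_med = float(np.median(u[field.mask]))
            if u_med > 0:
                floor = u_med
                wpix = wpix * np.minimum(
                    u_med / np.maximum(u, u_med / (2 * weight_cap)), weight_cap
                )
        wfield = DisplacementField(
            components=wpix[None].repeat(field.dim, axis=0),
            spacing=field.spacing, origin=field.origin, mask=field.mask,
        )
        wnodes = interpolate_to_mesh(wfield, mesh, gmap)[0][:, 0]
        material = MaterialField.uniform(
            mesh.n_elements, settings.rho_init, rho_min=rho_min, penal=penal,
            E0=E0, nu=nu,
        )
        return cls(
            mesh=mesh, measured=measured, bc=bc_from_measured(mesh, measured),
            material=material, weights=wnodes, settings=settings,
            thickness=thickness, sri=sri, gmap=gmap, objective_floor=floor,
        )

    # -- fitting ------------------------------------------------------------
    def fit(self, solver: CachedSolver | None = None) -> "InversionResults":
        """Run the forward/adjoint/filter/update loop.

        Each trial step must reduce the true min-max objective (the p-norm
        surrogate, which generates the gradients, may rise by at most
        ``surrogate_guard``); steps are backtracked along the update
        direction otherwise.  The loop terminates when (a) the objective
        reaches its discrepancy floor (the data's own noise level, if
        known), (b) the relative objective change stays below
        ``objective_tolerance`` for ``patience`` consecutive iterations,
        (c) no backtracked step improves the objective (stationary), or
        (d) ``max_iterations`` — in which case the best-so-far densities are
        returned with ``converged=False``.
        """
        s = self.settings
        mesh = self.mesh
        dim = mesh.dimension
        prescribed, presc_vals = self.bc.dof_arrays(mesh.n_nodes)
        if solver is None:
            solver = CachedSolver(mesh, self.material.nu, prescribed,
                                  self.thickness, self.sri)
        radius = s.filter_radius or 2.0 * mesh.typical_edge
        H = build_filter(mesh, radius)
        # per-DOF weights: node weight on each component of target nodes
        w_dof = np.zeros(mesh.n_nodes * dim)
        for c in range(dim):
            w_dof[self.target_nodes * dim + c] = self.weights[self.target_nodes]
        meas_flat = self.measured.ravel()
        rho_min = self.material.rho_min
        penal = self.material.penal
        E0 = self.material.E0
        exponent = s.aggregation_exponent
        atol = max(s.objective_atol, self.objective_floor)

        def forward(rho):
            E = rho ** penal * E0
            u, lu, diag = solver.solve(E, presc_vals)
            resid = u - meas_flat
            surr, dFdu = _surrogate_and_grad(resid, w_dof, exponent)
            f_true = float((np.abs(resid) * w_dof).max())
            return u, lu, surr, dFdu, f_true

        method = s.method
        if method == "auto":
            method = "lbfgs" if self.objective_floor == 0.0 else "mma"
        max_iter = s.max_iterations
        if max_iter is None:
            max_iter = 200 if method == "lbfgs" else (100 if dim == 2 else 400)

        rho = self.material.rho.copy()
        u, lu, surr, dFdu, f_true = forward(rho)

        if method == "lbfgs":
            return self._fit_lbfgs(solver, forward, H, w_dof, atol, max_iter,
                                   rho, u, lu, surr, dFdu, f_true)

        history, surr_history = [f_true], [surr]
        mma_state: dict = {"iteration": 0}
        best_rho, best_surr, best_f = rho.copy(), surr, f_true
        converged = False
        n_rejected = 0
        stationary = 0
        move_scale = s.move_limit
        it = 0
        for it in range(1, max_iter + 1):
            if f_true <= atol:
                converged = True
                break
            dE = penal * rho ** (penal - 1) * E0
            grad = objective_gradient(solver, u, lu, dFdu, dE)
            gradf = H @ grad
            mma_state["iteration"] = it
            cand = update_densities(rho, gradf, s, rho_min, mma_state, move_scale)
            d = cand - rho
            t, accepted = 1.0, False
            # when fitting noisy data (a floor is known) only steps improving
            # the true min-max objective are accepted: descending the
            # surrogate alone would fit noise below the data's error band
            allow_surrogate_step = self.objective_floor == 0.0
            for _ in range(8):
                trial = rho + t * d
                u_c, lu_c, surr_c, dFdu_c, f_c = forward(trial)
                if (f_c < f_true and surr_c < s.surrogate_guard * surr) or (
                    allow_surrogate_step and surr_c < surr
                    and f_c <= s.surrogate_guard * f_true
                ):
                    accepted = True
                    break
                n_rejected += 1
                t *= 0.5
            if method == "pg" and accepted:
                gmax = np.abs(gradf).max()
                if gmax > 0:
                    mma_state["bb_step"] = max(np.abs(t * d).max(), 1e-6) / gmax
            if not accepted:
                # no step improves the worst-node misfit: stationary point of
                # the filtered update (the filter bars unsmooth fixes)
                converged = True
                break
            rel = max(0.0, f_true - f_c) / max(f_true, 1e-300)
            mma_state["rho_prev2"] = mma_state.get("rho_prev1", rho)
            mma_state["rho_prev1"] = rho
            rho, u, lu, surr, dFdu, f_true = trial, u_c, lu_c, surr_c, dFdu_c, f_c
            history.append(f_true)
            surr_history.append(surr)
            if f_true <= best_f:
                best_rho, best_surr, best_f = rho.copy(), surr, f_true
            # trust-scale: grow after full steps, keep the backtracked scale
            move_scale = min(s.move_limit, move_scale * 1.3) if t == 1.0 \
                else max(1e-4, move_scale * t)
            stationary = stationary + 1 if rel < s.objective_tolerance else 0
            if stationary >= s.patience:
                converged = True
                break
        state = OptimizationState(
            iteration=it, rho=best_rho, objective=best_f, surrogate=best_surr,
            history=history, surrogate_history=surr_history, converged=converged,
            n_rejected=n_rejected,
        )
        material = MaterialField(
            rho=best_rho, rho_min=rho_min, penal=penal, E0=E0, nu=self.material.nu
        )
        return InversionResults(problem=self, material=material, state=state)


    def _fit_lbfgs(self, solver, forward, H, w_dof, atol, max_iter,
                   rho0, u0, lu0, surr0, dFdu0, f0) -> "InversionResults":
        """Bound-constrained quasi-Newton descent of the filtered surrogate."""
        from scipy.optimize import minimize

        s = self.settings
        rho_min = self.material.rho_min
        penal = self.material.penal
        E0 = self.material.E0
        last = {"rho": rho0, "surr": surr0, "f": f0}
        history, surr_history = [f0], [surr0]

        def fg(rho):
            u, lu, surr, dFdu, f_true = forward(rho)
            dE = penal * rho ** (penal - 1) * E0
            grad = H @ objective_gradient(solver, u, lu, dFdu, dE)
            last.update(rho=rho.copy(), surr=surr, f=f_true)
            return surr, grad

        def callback(xk):
            history.append(last["f"])
            surr_history.append(last["surr"])
            if last["f"] <= atol:
                raise StopIteration

        if f0 <= atol:
            res_x, nit = rho0, 0
        else:
            opt = minimize(
                fg, rho0, jac=True, method="L-BFGS-B",
                bounds=[(rho_min, 1.0)] * self.mesh.n_elements,
                options={"maxiter": max_iter, "ftol": s.objective_tolerance * 1e-8,
                         "gtol": 1e-12},
                callback=callback,
            )
            res_x, nit = np.clip(opt.x, rho_min, 1.0), opt.nit
        u, lu, surr, dFdu, f_true = forward(res_x)
        converged = f_true <= atol or nit < max_iter
        state = OptimizationState(
            iteration=nit, rho=res_x, objective=f_true, surrogate=surr,
            history=history, surrogate_history=surr_history, converged=converged,
        )
        material = MaterialField(rho=res_x, rho_min=rho_min, penal=penal,
                                 E0=E0, nu=self.material.nu)
        return InversionResults(problem=self, material=material, state=state)


def run_inversion(problem: InverseProblem):
    """Functional wrapper: returns ``(MaterialField, OptimizationState)``."""
    res = problem.fit()
    return res.material, res.state


class InversionResults:
    """Fitted relative-stiffness map with its optimization trajectory.

    Attributes
    ----------
    material : MaterialField
        Final per-element densities.
    state : OptimizationState
        Objective history and convergence flag.
    relative_stiffness : ndarray
        Densities normalized to mean relative stiffness 0.5.
    """

    def __init__(self, problem: InverseProblem, material: MaterialField,
                 state: OptimizationState):
        self.problem = problem
        self.material = material
        self.state = state

    @property
    def relative_stiffness(self) -> np.ndarray:
        return normalize_relative_stiffness(
            self.material.rho, self.problem.mesh.measures
        )

    def region_ratio(self, labels: np.ndarray):
        """Region means and pairwise ratios of the normalized map."""
        return region_ratio(self.relative_stiffness, labels,
                            self.problem.mesh.measures)

    def summary(self) -> str:
        s = self.state
        p = self.problem
        rho = self.relative_stiffness
        lines = [
            "Relative-stiffness inversion",
            "=" * 60,
            f"{'elements':<28}{p.mesh.n_elements}",
            f"{'nodes':<28}{p.mesh.n_nodes}",
            f"{'element family':<28}{p.mesh.family}",
            f"{'target nodes':<28}{len(p.target_nodes)}",
            f"{'Poisson ratio':<28}{self.material.nu}",
            f"{'SIMP exponent p':<28}{self.material.penal}",
            f"{'baseline modulus E0 (Pa)':<28}{self.material.E0}",
            f"{'iterations':<28}{s.iteration}",
            f"{'converged':<28}{s.converged}",
            f"{'rejected trial steps':<28}{s.n_rejected}",
            f"{'objective max|du| (mm)':<28}{s.objective:.6g}",
            f"{'surrogate p-norm (mm)':<28}{s.surrogate:.6g}",
            f"{'relative stiffness mean':<28}{rho.mean():.4g} (normalized to 0.5)",
            f"{'relative stiffness range':<28}[{rho.min():.4g}, {rho.max():.4g}]",
            "=" * 60,
        ]
        return "\n".join(lines)

    def to_vtk(self, path, extra_cell_data: dict | None = None):
        """Export the mesh with the normalized stiffness map as cell data."""
        from .meshing import write_vtk

        cell_data = {"relative_stiffness": self.relative_stiffness,
                     "rho": self.material.rho}
        if extra_cell_data:
            cell_data.update(extra_cell_data)
        point_data = {"measured": self.problem.measured}
        return write_vtk(path, self.problem.mesh, point_data, cell_data)
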