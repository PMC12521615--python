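"""Maximum-likelihood fitting of energy models to count tables.

The loss minimized is ``-l_data + l_reg`` where ``l_data`` is the scaled
binomial log-likelihood of :func:`pepfer.model.log_likelihood` and ``l_reg``
the regularization of :func:`pepfer.model.penalty`.  All free parameters —
unfrozen coefficients of both binding modes, the non-specific position bias,
and per-table log-activities and depth ratios — are optimized jointly with
L-BFGS using analytic gradients.

Gauge fixing: the fitted model has a shift redundancy (adding a constant to
a specific-mode column while rescaling alpha_S leaves every kappa
unchanged); :func:`normalize` resolves it so that each column's maximum is
zero and the optimal sequence has relative affinity one.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError
from .library import AA_INDEX, CountTable, LibraryDesign
from .model import (
    N_AA,
    BindingMode,
    EnergyModel,
    RegularizationConfig,
    RoundParams,
    encode_peptides,
    extend_with_flanks,
)


@dataclass
class FitConfig:
    """Settings for :func:`fit`.

    ``constrained_central`` freezes the central specific-mode column to score
    ``constrained_residue`` at zero and every other residue at
    ``constrained_value``; frozen cells are excluded from the gradient and
    from regularization.
    """

    constrained_central: bool = True
    constrained_residue: str = "Y"
    constrained_value: float = -10.0
    ns_width: int = 3
    flank_depth: int = 5
    max_iterations: int = 500
    convergence_tol: float = 1e-9
    seed: int = 0
    regularization: RegularizationConfig = field(
        default_factory=RegularizationConfig
    )
    optimizer_name: str = "L-BFGS-B"

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ConfigurationError("convergence_tol must be > 0")
        if self.ns_width < 1:
            raise ConfigurationError("ns_width must be >= 1")
        if self.constrained_residue not in AA_INDEX:
            raise ConfigurationError(
                f"constrained_residue {self.constrained_residue!r} not in alphabet"
            )


@dataclass
class FitReport:
    trajectory: list[float]
    final_loss: float
    n_iterations: int
    converged: bool
    message: str
    grad_norm: float
    seed: int
    wall_seconds: float
    per_start: list[float] | None = None


class _TableData:
    """Pre-encoded arrays for one count table."""

    def __init__(self, table: CountTable, design: LibraryDesign, flank_depth: int):
        self.pep_idx = encode_peptides(table.sequences)
        self.ext = extend_with_flanks(self.pep_idx, design, flank_depth)
        self.k_in = table.counts_input.astype(np.float64)
        self.k_bd = table.counts_bound.astype(np.float64)
        self.k_row = self.k_in + self.k_bd
        self.k_total = float(table.k_total)
        self.n_unique = table.n_unique


class _Problem:
    """Parameter packing and joint loss/gradient over all tables."""

    def __init__(
        self,
        tables: Sequence[CountTable],
        design: LibraryDesign,
        config: FitConfig,
    ):
        self.design = design
        self.config = config
        self.w_s = design.length
        self.w_ns = config.ns_width
        self.flank_depth = min(
            config.flank_depth,
            len(design.protein_flank_left),
            len(design.protein_flank_right),
        )
        self.n_gamma = design.length - self.w_ns + 1
        if self.n_gamma < 1:
            raise ConfigurationError("ns_width exceeds design length")

        self.frozen: dict[tuple[int, int], float] = {}
        if config.constrained_central:
            center = design.central_position() - 1
            res_idx = AA_INDEX[config.constrained_residue]
            for a in range(N_AA):
                self.frozen[(center, a)] = (
                    0.0 if a == res_idx else config.constrained_value
                )
        self.free_mask = np.ones((self.w_s, N_AA), dtype=bool)
        for row, col in self.frozen:
            self.free_mask[row, col] = False
        self.n_spec_free = int(self.free_mask.sum())
        self.n_ns = self.w_ns * N_AA
        self.n_tables = len(tables)
        self.n_params = (
            self.n_spec_free + self.n_ns + self.n_gamma + 3 * self.n_tables
        )

        self.data = [_TableData(t, design, self.flank_depth) for t in tables]

        # frozen cells materialized once; free cells overwritten per eval
        self._beta_s = np.zeros((self.w_s, N_AA))
        for (row, col), value in self.frozen.items():
            self._beta_s[row, col] = value

    # -- packing -----------------------------------------------------------

    def initial_theta(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(self.n_params)
        n_coef = self.n_spec_free + self.n_ns + self.n_gamma
        theta[:n_coef] = rng.normal(0.0, 0.01, size=n_coef)
        off = n_coef
        for t, data in enumerate(self.data):
            # log-activities start at 0; depth at the observed column ratio
            theta[off + 3 * t + 2] = float(
                np.log(max(data.k_bd.sum(), 1.0) / max(data.k_in.sum(), 1.0))
            )
        return theta

    def split(self, theta: np.ndarray):
        a = self.n_spec_free
        b = a + self.n_ns
        c = b + self.n_gamma
        spec_free = theta[:a]
        beta_ns = theta[a:b].reshape(self.w_ns, N_AA)
        gamma = theta[b:c]
        per_table = theta[c:].reshape(self.n_tables, 3)
        return spec_free, beta_ns, gamma, per_table

    def build_model(self, theta: np.ndarray, metadata: dict) -> EnergyModel:
        spec_free, beta_ns, gamma, per_table = self.split(theta)
        beta_s = self._beta_s.copy()
        beta_s[self.free_mask] = spec_free
        specific = BindingMode(
            width=self.w_s,
            coeffs=beta_s,
            flank_depth=self.flank_depth,
            constrained_cells=dict(self.frozen),
        )
        nonspecific = BindingMode(
            width=self.w_ns,
            coeffs=beta_ns.copy(),
            position_bias=gamma.copy(),
        )
        per_round = [
            RoundParams(float(p[0]), float(p[1]), float(p[2])) for p in per_table
        ]
        return EnergyModel(
            design=self.design,
            specific=specific,
            nonspecific=nonspecific,
            per_round=per_round,
            metadata=metadata,
        )

    # -- loss --------------------------------------------------------------

    def loss_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        spec_free, beta_ns, gamma, per_table = self.split(theta)
        beta_s = self._beta_s
        beta_s[self.free_mask] = spec_free
        beta_ns = np.ascontiguousarray(beta_ns)

        reg = self.config.regularization
        dir_count = reg.dirichlet_count

        loss = 0.0
        g_spec = np.zeros((self.w_s, N_AA))
        g_ns = np.zeros((self.w_ns, N_AA))
        g_gamma = np.zeros(self.n_gamma)
        g_table = np.zeros((self.n_tables, 3))

        with np.errstate(over="ignore", invalid="ignore"):
            for t, data in enumerate(self.data):
                log_ans, log_as, depth = per_table[t]
                a_ns, a_s, rho = np.exp(log_ans), np.exp(log_as), np.exp(depth)
                dir_scale = dir_count / data.n_unique if dir_count > 0 else 0.0

                if HAVE_NUMBA:
                    t_loss, g_lan, g_las, g_depth = _table_kernel_nb(
                        data.ext,
                        data.pep_idx,
                        data.k_in,
                        data.k_bd,
                        data.k_row,
                        1.0 / data.k_total,
                        dir_scale,
                        beta_s,
                        beta_ns,
                        gamma,
                        a_ns,
                        a_s,
                        rho,
                        g_spec,
                        g_ns,
                        g_gamma,
                    )
                    loss += t_loss
                    g_table[t] = (g_lan, g_las, g_depth)
                    if not np.isfinite(loss):
                        return np.inf, np.zeros_like(theta)
                    continue

                s_scores = _windows(data.ext, beta_s)
                e_s = np.exp(s_scores)
                S = e_s.sum(axis=1)

                n_scores = _windows(data.pep_idx, beta_ns) + gamma[None, :]
                e_n = np.exp(n_scores)
                Nn = e_n.sum(axis=1)

                kappa = a_ns * Nn + a_s * S
                q = rho * kappa
                log_q = np.log(q)
                log1pq = np.log1p(q)
                p_b = q / (1.0 + q)

                data_ll = (
                    data.k_bd @ (log_q - log1pq) - data.k_in @ log1pq
                ) / data.k_total
                loss -= data_ll
                # d(loss)/d ln q per row
                g = -(data.k_bd - data.k_row * p_b) / data.k_total
                if dir_count > 0:
                    scale = dir_count / data.n_unique
                    loss -= scale * float((log_q - 2.0 * log1pq).sum())
                    g -= scale * (1.0 - 2.0 * p_b)

                if not np.isfinite(loss):
                    return np.inf, np.zeros_like(theta)

                g_table[t, 2] = g.sum()
                g_table[t, 1] = g @ (a_s * S / kappa)
                g_table[t, 0] = g @ (a_ns * Nn / kappa)

                u_s = (g * a_s / kappa)[:, None] * e_s
                _scatter(data.ext, u_s, g_spec)
                u_n = (g * a_ns / kappa)[:, None] * e_n
                g_gamma += u_n.sum(axis=0)
                _scatter(data.pep_idx, u_n, g_ns)

        g_spec_free = g_spec[self.free_mask]
        grad = np.concatenate(
            [g_spec_free, g_ns.ravel(), g_gamma, g_table.ravel()]
        )

        # regularization on free coefficients (both modes + gamma)
        n_coef = self.n_spec_free + self.n_ns + self.n_gamma
        beta = theta[:n_coef]
        loss += reg.lambda_l2 * float(beta @ beta)
        grad[:n_coef] += 2.0 * reg.lambda_l2 * beta
        if reg.barrier_weight > 0:
            up = np.exp(beta - reg.barrier_cap)
            dn = np.exp(-beta - reg.barrier_cap)
            loss += reg.barrier_weight * float(up.sum() + dn.sum())
            grad[:n_coef] += reg.barrier_weight * (up - dn)

        return float(loss), grad


try:  # optional fused kernel; the numpy path below is the reference
    from numba import njit

    @njit(cache=True)
    def _table_kernel_nb(
        ext,
        pep_idx,
        k_in,
        k_bd,
        k_row,
        inv_k_total,
        dir_scale,
        beta_s,
        beta_ns,
        gamma,
        a_ns,
        a_s,
        rho,
        g_spec,
        g_ns,
        g_gamma,
    ):
        n = ext.shape[0]
        w_s = beta_s.shape[0]
        o_s = ext.shape[1] - w_s + 1
        w_ns = beta_ns.shape[0]
        o_ns = pep_idx.shape[1] - w_ns + 1
        loss = 0.0
        g_depth = 0.0
        g_las = 0.0
        g_lan = 0.0
        e_s = np.empty(o_s)
        e_n = np.empty(o_ns)
        for i in range(n):
            S = 0.0
            for x in range(o_s):
                sc = 0.0
                for j in range(w_s):
                    sc += beta_s[j, ext[i, x + j]]
                v = np.exp(sc)
                e_s[x] = v
                S += v
            N = 0.0
            for x in range(o_ns):
                sc = gamma[x]
                for j in range(w_ns):
                    sc += beta_ns[j, pep_idx[i, x + j]]
                v = np.exp(sc)
                e_n[x] = v
                N += v
            kappa = a_ns * N + a_s * S
            if not np.isfinite(kappa) or kappa <= 0.0:
                return np.nan, 0.0, 0.0, 0.0
            q = rho * kappa
            log_q = np.log(q)
            log1pq = np.log1p(q)
            p_b = q / (1.0 + q)
            loss -= (k_bd[i] * (log_q - log1pq) - k_in[i] * log1pq) * inv_k_total
            g = -(k_bd[i] - k_row[i] * p_b) * inv_k_total
            if dir_scale > 0.0:
                loss -= dir_scale * (log_q - 2.0 * log1pq)
                g -= dir_scale * (1.0 - 2.0 * p_b)
            g_depth += g
            g_las += g * (a_s * S / kappa)
            g_lan += g * (a_ns * N / kappa)
            cs = g * a_s / kappa
            for x in range(o_s):
                u = cs * e_s[x]
                for j in range(w_s):
                    g_spec[j, ext[i, x + j]] += u
            cn = g * a_ns / kappa
            for x in range(o_ns):
                u = cn * e_n[x]
                g_gamma[x] += u
                for j in range(w_ns):
                    g_ns[j, pep_idx[i, x + j]] += u
        return loss, g_lan, g_las, g_depth

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False


def _windows(ext: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    w = coeffs.shape[0]
    n_off = ext.shape[1] - w + 1
    s = np.zeros((ext.shape[0], n_off))
    for j in range(w):
        s += coeffs[j, ext[:, j : j + n_off]]
    return s


def _scatter(ext: np.ndarray, weights: np.ndarray, out: np.ndarray) -> None:
    """Accumulate per-window weights into a (w, 20) coefficient gradient."""
    w = out.shape[0]
    n_off = weights.shape[1]
    flat_w = weights.ravel()
    for j in range(w):
        out[j] += np.bincount(
            ext[:, j : j + n_off].ravel(), weights=flat_w, minlength=out.shape[1]
        )[: out.shape[1]]


def _check_tables(tables: Sequence[CountTable]) -> LibraryDesign:
    if not tables:
        raise ConfigurationError("need at least one count table")
    design = tables[0].design
    for t in tables[1:]:
        if t.design != design:
            raise ConfigurationError("all count tables must share one design")
    return design


def fit(
    tables: Sequence[CountTable], config: FitConfig | None = None
) -> tuple[EnergyModel, FitReport]:
    """Fit one shared coefficient set with independent per-table activities.

    Returns the model at a local optimum of the loss together with a report
    holding the (non-increasing) loss trajectory.  Constrained cells hold
    their frozen values exactly; the returned model is *not* yet
    gauge-normalized.
    """
    config = config or FitConfig()
    design = _check_tables(tables)
    problem = _Problem(tables, design, config)

    rng = np.random.default_rng(config.seed)
    theta0 = problem.initial_theta(rng)

    f0, _ = problem.loss_grad(theta0)
    if not np.isfinite(f0):
        raise ConfigurationError(
            "loss is non-finite at initialization; check counts and config"
        )

    cache: dict[bytes, float] = {}

    def fun(theta: np.ndarray) -> tuple[float, np.ndarray]:
        value, grad = problem.loss_grad(theta)
        if len(cache) > 8:
            cache.clear()
        cache[theta.tobytes()] = value
        return value, grad

    trajectory = [f0]

    def callback(xk: np.ndarray) -> None:
        value = cache.get(xk.tobytes())
        if value is None:
            value, _ = problem.loss_grad(xk)
        trajectory.append(value)

    start = time.time()
    result = minimize(
        fun,
        theta0,
        jac=True,
        method=config.optimizer_name,
        callback=callback,
        options={
            "maxiter": config.max_iterations,
            "ftol": config.convergence_tol,
            "gtol": 1e-8,
        },
    )
    wall = time.time() - start

    metadata = {
        "seed": config.seed,
        "rounds": [t.round_id for t in tables],
        "design": design.name,
        "normalized": False,
        "fit": {
            "constrained_central": config.constrained_central,
            "constrained_residue": config.constrained_residue,
            "constrained_value": config.constrained_value,
            "ns_width": config.ns_width,
            "flank_depth": problem.flank_depth,
            "max_iterations": config.max_iterations,
            "convergence_tol": config.convergence_tol,
            "optimizer_name": config.optimizer_name,
        },
    }
    model = problem.build_model(result.x, metadata)
    report = FitReport(
        trajectory=trajectory,
        final_loss=float(result.fun),
        n_iterations=int(result.nit),
        converged=bool(result.success),
        message=str(result.message),
        grad_norm=float(np.max(np.abs(result.jac))),
        seed=config.seed,
        wall_seconds=wall,
    )
    return model, report


def normalize(model: EnergyModel) -> EnergyModel:
    """Gauge-fix so every specific-mode column has maximum zero.

    The compensating factor is absorbed into every per-round alpha_S, leaving
    all kappa values unchanged.  Idempotent; frozen cells are unaffected
    because a frozen column's maximum is already zero.
    """
    out = model.copy()
    shifts = out.specific.coeffs.max(axis=1)
    frozen_rows = {row for row, _ in out.specific.constrained_cells}
    for row in frozen_rows:
        if abs(shifts[row]) > 1e-12:
            raise ConfigurationError(
                "constrained column maximum is nonzero; cannot normalize "
                "without moving frozen cells"
            )
        shifts[row] = 0.0
    out.specific.coeffs -= shifts[:, None]
    out.specific.apply_frozen()
    total = float(shifts.sum())
    for rp in out.per_round:
        rp.log_alpha_s += total
    out.metadata["normalized"] = True
    return out


def fit_multistart(
    tables: Sequence[CountTable],
    config: FitConfig | None = None,
    n_starts: int = 3,
) -> tuple[EnergyModel, FitReport]:
    """Run :func:`fit` from several seeded starts, keep the best loss."""
    config = config or FitConfig()
    if n_starts < 1:
        raise ConfigurationError("n_starts must be >= 1")
    best: tuple[EnergyModel, FitReport] | None = None
    losses: list[float] = []
    errors: list[str] = []
    for i in range(n_starts):
        sub = replace(config, seed=config.seed + 7919 * i)
        try:
            model, report = fit(tables, sub)
        except Exception as exc:  # aggregate and re-raise if all starts fail
            errors.append(f"start {i}: {exc}")
            continue
        losses.append(report.final_loss)
        if best is None or report.final_loss < best[1].final_loss:
            best = (model, report)
    if best is None:
        raise ConfigurationError(
            "all starts failed: " + "; ".join(errors)
        )
    best[1].per_start = losses
    return best
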