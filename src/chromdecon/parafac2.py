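"""PARAFAC2 alternating least squares with non-negativity constraints.

The direct-fitting PARAFAC2 model for K slabs X_k (elution x mass) is

    X_k  ~=  P_k H diag(c_k) S^T,   P_k^T P_k = I,

where P_k (I_k x R) is a per-sample orthonormal elution basis, H (R x R) is
a common factor shared by all samples, S (J x R) holds the resolved mass
spectra, and c_k (row k of the K x R matrix C) the per-sample relative
amounts. The per-sample elution profiles are B_k = P_k H; their
cross-product B_k^T B_k = H^T H is identical across samples, which is the
defining PARAFAC2 constraint.

Identifiability with pseudo-replicates
--------------------------------------
A pseudo-replicate set scales every component of member k by the same
multiplier, so C is rank one by construction. The classic direct-fit model
is then rotationally ambiguous: any invertible mixing of the spectral
columns can be absorbed by the unconstrained H without changing the fit,
and plain ALS converges to an arbitrary perfect-fit mixture. What restores
uniqueness is non-negativity of the elution profiles themselves: mixing
spectra forces compensating *negative* elution contributions in the scan
regions where only one compound elutes. The default fitting path therefore

1. seeds per-member elution profiles from the purest m/z channels of the
   cube (a SIMPLISMA-style pure-variable start),
2. refines them with a flexible-coupling ALS, minimizing
   sum_k ||X_k - B_k diag(c_k) S^T||^2 + mu ||B_k - P_k H||^2 with
   B_k >= 0 and a geometrically ramped penalty mu pulling the profiles
   onto the PARAFAC2 manifold, and
3. finishes on the exact constraint with H frozen (Procrustes updates of
   P_k plus non-negative updates of S and C), so the reported model
   satisfies B_k^T B_k = H^T H identically and cannot drift back along
   the rotational valley.

``FitSettings(nonneg_elution=False)`` selects the classic Kiers-ten
Berge-Bro direct fit (multi-start, best SSE) with non-negativity on the
spectral and sample modes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, svd
from scipy.optimize import nnls

from .intervals import IntervalCube

__all__ = [
    "FitSettings",
    "Parafac2Model",
    "fit_parafac2",
    "core_consistency",
    "residual_summary",
]

# sample-mode singular-value ratio below which a replicate set is treated
# as rank-one by design (see core_consistency)
SAMPLE_RANK_TOL = 1e-3


@dataclass
class FitSettings:
    """ALS controls.

    max_iterations bounds the total ALS sweeps (default 50,000);
    convergence_tol is the relative SSE change below which a stage stops.
    n_starts applies to the classic path (one SVD-seeded start plus seeded
    random restarts, best SSE kept). coupling_sweeps bounds the
    flexible-coupling stage of the default path.
    """

    max_iterations: int = 50_000
    convergence_tol: float = 1e-8
    n_starts: int = 3
    nonneg_spectral: bool = True
    nonneg_sample: bool = True
    nonneg_elution: bool = True
    coupling_sweeps: int = 1000
    coupling_ramp: float = 1.03
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass
class Parafac2Model:
    """Fitted decomposition of one interval cube plus diagnostics."""

    n_components: int
    spectral_loadings: np.ndarray  # J x R, >= 0, unit-norm columns
    sample_loadings: np.ndarray  # K x R, >= 0 (carries the scale)
    common_factor: np.ndarray  # H, R x R
    orthobases: list  # K orthonormal I_int x R matrices P_k
    sse: float
    fit_percent: float
    core_consistency: float | None
    iterations: int
    converged: bool
    rng_seed: int
    sse_history: np.ndarray = field(repr=False, default=None)

    def elution_profiles(self) -> list:
        """Per-member elution profiles B_k = P_k H (I_int x R)."""
        return [P @ self.common_factor for P in self.orthobases]

    def reconstruct(self) -> list:
        """Model slabs P_k H diag(c_k) S^T."""
        return [
            P @ self.common_factor @ np.diag(self.sample_loadings[k])
            @ self.spectral_loadings.T
            for k, P in enumerate(self.orthobases)
        ]

    def to_dict(self) -> dict:
        """Portable JSON-ready bundle (loadings, diagnostics, seed)."""
        return {
            "n_components": self.n_components,
            "spectral_loadings": self.spectral_loadings.tolist(),
            "sample_loadings": self.sample_loadings.tolist(),
            "common_factor": self.common_factor.tolist(),
            "sse": self.sse,
            "fit_percent": self.fit_percent,
            "core_consistency": self.core_consistency,
            "iterations": self.iterations,
            "converged": self.converged,
            "rng_seed": self.rng_seed,
        }


# ---------------------------------------------------------------------------
# constrained least-squares helpers
# ---------------------------------------------------------------------------


def _nnls_gram(gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve min ||A x - b||, x >= 0, per row of rhs, given A^T A and A^T b.

    Uses the Cholesky reduction ||A x - b||^2 = ||L^T x - L^-1 A^T b||^2 + c
    so each row solve is an R x R problem regardless of the data size. Rows
    whose unconstrained optimum is already non-negative (the common case)
    skip the active-set solver entirely.
    """
    r = gram.shape[0]
    low = None
    for jitter in (0.0, 1e-12, 1e-9, 1e-6):
        try:
            low = np.linalg.cholesky(
                gram + jitter * (np.trace(gram) / r + 1e-300) * np.eye(r)
            )
            break
        except np.linalg.LinAlgError:
            continue
    if low is None:  # pragma: no cover - pathological
        low = np.linalg.cholesky(
            gram + 1e-3 * (np.trace(gram) / r + 1e-300) * np.eye(r)
        )
    lt = low.T
    b_all = np.linalg.solve(low, rhs.T).T
    out = np.linalg.solve(lt, b_all.T).T  # unconstrained solutions
    violating = np.nonzero((out < -1e-12).any(axis=1))[0]
    out[out < 0] = 0.0
    for i in violating:
        out[i], _ = nnls(lt, b_all[i])
    return out


def _solve_gram(gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Unconstrained least squares given Gram matrix and cross products."""
    try:
        c = cho_factor(gram)
        return cho_solve(c, rhs.T).T
    except np.linalg.LinAlgError:
        return rhs @ np.linalg.pinv(gram)


def _maybe_nnls(gram, rhs, constrained: bool):
    return _nnls_gram(gram, rhs) if constrained else _solve_gram(gram, rhs)


def _model_sse(slabs, y, h, s, c) -> float:
    """SSE of the exact-constraint model via the transformed slabs.

    For orthonormal P_k, ||X_k - P_k M_k||^2 =
    ||X_k||^2 - ||Y_k||^2 + ||Y_k - M_k||^2 with Y_k = P_k^T X_k.
    """
    sse = 0.0
    for kk, xk in enumerate(slabs):
        m = h @ np.diag(c[kk]) @ s.T
        sse += (
            float(np.sum(xk * xk))
            - float(np.sum(y[kk] * y[kk]))
            + float(np.sum((y[kk] - m) ** 2))
        )
    return max(sse, 0.0)


# ---------------------------------------------------------------------------
# classic direct-fitting ALS (exact constraint, free H)
# ---------------------------------------------------------------------------


def _init_factors(slabs, r, rng, svd_init):
    j = slabs[0].shape[1]
    k = len(slabs)
    if svd_init:
        stacked = np.vstack(slabs)  # (K I) x J
        _, _, vt = svd(stacked, full_matrices=False)
        s0 = np.abs(vt[:r].T)  # J x R, non-negative start
    else:
        s0 = rng.uniform(0.1, 1.0, size=(j, r))
    return np.eye(r), s0, np.ones((k, r))


def _classic_als(slabs, r, settings: FitSettings, rng, svd_init: bool,
                 init=None, fix_h: bool = False, max_sweeps=None):
    """Direct-fit ALS. With fix_h=True, H stays frozen (finishing mode)."""
    k = len(slabs)
    total_ss = sum(float(np.sum(x * x)) for x in slabs)
    if init is not None:
        h, s, c = (np.array(m, dtype=float) for m in init)
    else:
        h, s, c = _init_factors(slabs, r, rng, svd_init)

    limit = max_sweeps if max_sweeps is not None else settings.max_iterations
    sse_prev = np.inf
    history = []
    iterations = 0
    converged = False
    orth = [None] * k
    y = np.empty((k, r, slabs[0].shape[1]))

    for iterations in range(1, limit + 1):
        for kk in range(k):
            f = h @ np.diag(c[kk]) @ s.T
            u, _, vt = svd(slabs[kk] @ f.T, full_matrices=False)
            orth[kk] = u @ vt
            y[kk] = orth[kk].T @ slabs[kk]

        if not fix_h:
            sts = s.T @ s
            ctc = c.T @ c
            rhs_h = np.einsum("krj,jp,kp->rp", y, s, c)
            h = _solve_gram(sts * ctc, rhs_h)

        hth = h.T @ h
        rhs_s = np.einsum("krj,rp,kp->jp", y, h, c)
        s = _maybe_nnls(hth * (c.T @ c), rhs_s, settings.nonneg_spectral)

        rhs_c = np.einsum("krj,rp,jp->kp", y, h, s)
        c = _maybe_nnls(hth * (s.T @ s), rhs_c, settings.nonneg_sample)

        sse = _model_sse(slabs, y, h, s, c)
        history.append(sse)
        if sse_prev - sse <= settings.convergence_tol * max(total_ss, 1e-300):
            converged = True
            break
        sse_prev = sse

    return h, s, c, orth, sse, iterations, converged, np.array(history)


# ---------------------------------------------------------------------------
# pure-variable seeding and flexible coupling (non-negative elution mode)
# ---------------------------------------------------------------------------


def _pure_channel_indices(slabs, r) -> list:
    """Greedy SIMPLISMA-style selection of R selective m/z channels.

    Channels are scored by purity (std over mean, offset-damped so weak
    channels do not dominate) times the norm of their component orthogonal
    to already-chosen channels, so each pick adds a new elution shape.
    """
    x = np.vstack(slabs)  # (K I) x J
    norm = np.linalg.norm(x, axis=0)
    mean = x.mean(axis=0)
    offset = 0.03 * mean.max() if mean.max() > 0 else 1.0
    purity = x.std(axis=0) / (mean + offset)
    xn = x / np.maximum(norm, 1e-12)
    resid = xn.copy()
    chosen = []
    for _ in range(r):
        score = purity * np.linalg.norm(resid, axis=0)
        score[chosen] = -np.inf
        j = int(np.argmax(score))
        chosen.append(j)
        v = resid[:, j]
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            v = v / nv
            resid = resid - np.outer(v, v @ resid)
    return chosen


def _flexible_coupling(slabs, r, settings: FitSettings):
    """Pure-channel-seeded coupled fit with non-negative elution profiles.

    Minimizes sum_k ||X_k - B_k diag(c_k) S^T||^2 + mu ||B_k - P_k H||^2
    with B_k >= 0, ramping mu geometrically so the profiles end on the
    PARAFAC2 cross-product manifold. Returns (H, S, C) for the exact-
    constraint finish.
    """
    k = len(slabs)
    total_ss = sum(float(np.sum(x * x)) for x in slabs)
    eye = np.eye(r)

    chosen = _pure_channel_indices(slabs, r)
    b = [np.maximum(x[:, chosen], 0.0) for x in slabs]
    c = np.ones((k, r))
    gram0 = sum(bk.T @ bk for bk in b)
    rhs0 = sum(x.T @ bk for x, bk in zip(slabs, b))
    s = _maybe_nnls(gram0, rhs0, settings.nonneg_spectral)

    # initial common factor from the seeded profiles
    h = None
    orth = [None] * k
    mu = None
    for sweep in range(max(settings.coupling_sweeps, 1)):
        if h is None:
            for kk in range(k):
                u, _, vt = svd(b[kk], full_matrices=False)
                orth[kk] = u @ vt
            h = np.mean([p.T @ bk for p, bk in zip(orth, b)], axis=0)
        if mu is None:
            sse = sum(
                float(np.sum((x - bk @ np.diag(ck) @ s.T) ** 2))
                for x, bk, ck in zip(slabs, b, c)
            )
            coup = sum(
                float(np.sum((bk - p @ h) ** 2)) for bk, p in zip(b, orth)
            )
            mu = (sse + 1e-9 * total_ss) / (coup + 1e-9 * total_ss)
        # B_k update: rows solve (F F^T + mu I) b_i = F x_i + mu (P_k H)_i
        for kk in range(k):
            f = np.diag(c[kk]) @ s.T  # R x J
            gram = f @ f.T + mu * eye
            rhs = slabs[kk] @ f.T + mu * (orth[kk] @ h)
            b[kk] = _nnls_gram(gram, rhs)
        for kk in range(k):
            u, _, vt = svd(b[kk] @ h.T, full_matrices=False)
            orth[kk] = u @ vt
        h = np.mean([p.T @ bk for p, bk in zip(orth, b)], axis=0)
        # S over all members, then C per member
        gram_s = np.zeros((r, r))
        rhs_s = np.zeros((s.shape[0], r))
        for kk in range(k):
            bd = b[kk] @ np.diag(c[kk])
            gram_s += bd.T @ bd
            rhs_s += slabs[kk].T @ bd
        s = _maybe_nnls(gram_s, rhs_s, settings.nonneg_spectral)
        for kk in range(k):
            gram_c = (b[kk].T @ b[kk]) * (s.T @ s)
            rhs_c = np.einsum("ir,ij,jr->r", b[kk], slabs[kk], s)[None, :]
            c[kk] = _maybe_nnls(gram_c, rhs_c, settings.nonneg_sample)[0]
        coup = sum(float(np.sum((bk - p @ h) ** 2)) for bk, p in zip(b, orth))
        b_norm = sum(float(np.sum(bk * bk)) for bk in b)
        if coup <= 1e-14 * max(b_norm, 1e-300):
            break
        mu *= settings.coupling_ramp
    return h, s, c, sweep + 1


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def fit_parafac2(cube: IntervalCube, r: int,
                 settings: FitSettings | None = None) -> Parafac2Model:
    """Fit an R-component non-negative PARAFAC2 model to an interval cube.

    Default path: pure-channel seeding, flexible-coupling refinement with
    non-negative elution profiles, exact-constraint finish with H frozen
    (see module docstring). Deterministic given ``settings.rng_seed``; the
    seed only matters for the classic path's random restarts. After the
    fit, spectral columns and the columns of H are normalized to unit
    Euclidean length with all magnitude absorbed into the sample loadings.
    """
    settings = settings or FitSettings()
    slabs = [np.asarray(s, dtype=float) for s in cube.slabs]
    i_int, j = slabs[0].shape
    if not 1 <= r <= min(i_int, j):
        raise ValueError(
            f"n_components {r} outside [1, min(I={i_int}, J={j})]"
        )
    total_ss = sum(float(np.sum(x * x)) for x in slabs)
    if total_ss == 0:
        raise ValueError("all-zero cube: nothing to model")

    if settings.nonneg_elution:
        h0, s0, c0, coupling_iters = _flexible_coupling(slabs, r, settings)
        rng = np.random.default_rng([settings.rng_seed, 0])
        h, s, c, orth, sse, finish_iters, converged, history = _classic_als(
            slabs, r, settings, rng, svd_init=False, init=(h0, s0, c0),
            fix_h=True,
        )
        iterations = coupling_iters + finish_iters
    else:
        best = None
        for start in range(max(settings.n_starts, 1)):
            rng = np.random.default_rng([settings.rng_seed, start])
            result = _classic_als(
                slabs, r, settings, rng, svd_init=(start == 0)
            )
            if best is None or result[4] < best[4]:
                best = result
        h, s, c, orth, sse, iterations, converged, history = best

    # fix scale indeterminacy: unit-norm spectral and elution-factor columns
    s_norm = np.linalg.norm(s, axis=0)
    s_norm[s_norm == 0] = 1.0
    h_norm = np.linalg.norm(h, axis=0)
    h_norm[h_norm == 0] = 1.0
    s = s / s_norm
    h = h / h_norm
    c = c * s_norm * h_norm

    fit_percent = 100.0 * (1.0 - sse / total_ss)
    model = Parafac2Model(
        n_components=r,
        spectral_loadings=s,
        sample_loadings=c,
        common_factor=h,
        orthobases=orth,
        sse=sse,
        fit_percent=fit_percent,
        core_consistency=None,
        iterations=iterations,
        converged=converged,
        rng_seed=settings.rng_seed,
        sse_history=history,
    )
    model.core_consistency = core_consistency(model, cube)
    return model


def core_consistency(model: Parafac2Model, cube: IntervalCube) -> float:
    """Core consistency diagnostic (CORCONDIA) of a fitted model.

    Computed on the PARAFAC representation implied by PARAFAC2: the
    transformed slabs Y_k = P_k^T X_k form an R x J x K array modelled by
    the CP triple (H, S, C). When the sample mode is informative
    (numerical rank of C equal to R), this is the standard diagnostic:
    the least-squares Tucker3 core G given the loadings is compared with
    the superdiagonal target T, 100 * (1 - ||G - T||^2 / ||T||^2).

    A pseudo-replicate set, however, has a rank-one sample mode by
    construction (one global multiplier per member), so C carries no
    component-separating information and its pseudo-inverse is undefined
    in all but one direction. In that regime (sigma_2/sigma_1 of C below
    ``SAMPLE_RANK_TOL``) the diagnostic is evaluated on the
    sample-collapsed bilinear representation: the slabs are projected onto
    the leading sample direction u, Ybar = sum_k u_k Y_k, the
    least-squares core G2 = H^+ Ybar (S^+)^T is normalized per component
    by the sample-loading column norms, and compared with the identity
    target. Components with (numerically) zero sample loadings cannot
    reproduce their superdiagonal entry and count as full misses, which
    keeps the diagnostic's overfactoring sensitivity: splitting one true
    component into R factors still drives the value far below 100. The
    two branches coincide in behaviour wherever both are defined.

    For R = 1 the core is the single optimal scale, so the value is 100
    at any ALS fixed point.
    """
    r = model.n_components
    if r == 0:
        raise ValueError("model has no components")
    y = np.stack([P.T @ x for P, x in zip(model.orthobases, cube.slabs)])
    a, b, c = model.common_factor, model.spectral_loadings, model.sample_loadings

    sv = np.linalg.svd(c, compute_uv=False)
    informative = r == 1 or (sv.size >= 2 and sv[1] > SAMPLE_RANK_TOL * sv[0])

    if informative:
        a_p, b_p, c_p = (np.linalg.pinv(m) for m in (a, b, c))
        core = np.einsum("pr,qj,sk,krj->pqs", a_p, b_p, c_p, y)
        target = np.zeros((r, r, r))
        idx = np.arange(r)
        target[idx, idx, idx] = 1.0
        return float(100.0 * (1.0 - np.sum((core - target) ** 2) / r))

    # rank-one sample mode: collapse onto the leading sample direction
    u, sig, vt = np.linalg.svd(c, full_matrices=False)
    u0 = u[:, 0] if u[:, 0].sum() >= 0 else -u[:, 0]  # C >= 0: keep u >= 0
    ybar = np.einsum("k,krj->rj", u0, y)
    g2 = np.linalg.pinv(a) @ ybar @ np.linalg.pinv(b).T  # R x R
    lam = np.linalg.norm(c, axis=0)  # per-component scale
    alive = lam > 1e-9 * (lam.max() + 1e-300)
    ghat = np.zeros_like(g2)
    ghat[:, alive] = g2[:, alive] / lam[alive]
    # dead components miss their superdiagonal entry entirely
    target = np.eye(r)
    mismatch = float(np.sum((ghat[:, alive] - target[:, alive]) ** 2))
    mismatch += float(np.sum(~alive))
    return float(100.0 * (1.0 - mismatch / r))


def residual_summary(model: Parafac2Model, cube: IntervalCube,
                     imbalance_ratio: float = 3.0) -> dict:
    """Residual norms by member and by m/z channel.

    Returns squared residual norms per member, residual norms per m/z
    channel (summed over members), the overall relative residual
    1 - fit/100, and whether the per-member residuals are balanced (no
    member above 3x the median).
    """
    recon = model.reconstruct()
    per_member_sq = np.array(
        [float(np.sum((x - m) ** 2)) for x, m in zip(cube.slabs, recon)]
    )
    per_channel = np.sqrt(
        sum(((x - m) ** 2).sum(axis=0) for x, m in zip(cube.slabs, recon))
    )
    member_norms = np.sqrt(per_member_sq)
    median = float(np.median(member_norms))
    # the imbalance rule targets outlier members in noisy fits; a fit whose
    # total residual is below 0.01% of the data is balanced by definition
    # (the leftover structure is numerical, not chemical)
    negligible = per_member_sq.sum() <= 1e-4 * cube.total_sumsq()
    if negligible or median == 0.0:
        balanced = True
    else:
        balanced = bool(np.all(member_norms <= imbalance_ratio * median))
    return {
        "per_member_sq": per_member_sq,
        "per_member_norm": member_norms,
        "per_channel_norm": per_channel,
        "relative_residual": 1.0 - model.fit_percent / 100.0,
        "balanced": balanced,
    }
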