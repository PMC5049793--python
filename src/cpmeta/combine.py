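"""Correlation-aware combined association statistics.

Two statistics are computed from a vector of panel Z scores ``T`` with null
correlation ``R`` and diagonal weights ``W``:

* ``s_hom`` — the homogeneous-effect combination
  ``[e'(RW)^-1 T]^2 / [e'(WRW)^-1 e]``, chi-square with 1 df under the null.
* ``s_het`` — the maximum over thresholds ``tau`` of the same quadratic
  restricted to components with ``|T| > tau`` and sign-aligned weights
  ``w = sqrt(n) * sign(T)``; its null distribution is obtained by Monte
  Carlo (multivariate-normal draws) with a fitted beta tail for extreme
  p-values.

Both accept missing entries (NaN) by subsetting ``T``, ``R`` and ``W`` to
the observed panels.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "WeightSpec",
    "HomResult",
    "HetResult",
    "HetNull",
    "SingularCorrelationError",
    "panel_weights",
    "s_hom",
    "s_tau",
    "s_het",
    "s_hom_batch",
    "s_het_batch",
    "build_shet_null",
    "p_het",
    "p_het_batch",
]

_TAU_EPS = 1e-8
_EMPIRICAL_MIN_TAIL = 10


class SingularCorrelationError(np.linalg.LinAlgError):
    """R (or a subset of it) is singular for this SNP."""


@dataclass(frozen=True)
class WeightSpec:
    """Weight convention for the diagonal matrix W.

    ``sqrt_n`` (default) sets w_jk = sqrt(n_j); ``n`` uses n_j directly;
    ``unit`` ignores sample sizes.  ``per_snp`` selects per-SNP sample
    sizes over the panel maxima when both are available.
    """

    scheme: str = "sqrt_n"
    per_snp: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("sqrt_n", "n", "unit"):
            raise ValueError(f"unknown weight scheme {self.scheme!r}")


def panel_weights(n: np.ndarray, scheme: str = "sqrt_n") -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if scheme == "sqrt_n":
        return np.sqrt(n)
    if scheme == "n":
        return n
    if scheme == "unit":
        return np.ones_like(n)
    raise ValueError(f"unknown weight scheme {scheme!r}")


class HomResult(NamedTuple):
    statistic: float
    p_value: float
    n_panels_used: int


class HetResult(NamedTuple):
    statistic: float
    tau_star: float
    active_set: tuple
    n_panels_used: int


def _quad_form(t: np.ndarray, r: np.ndarray, a: np.ndarray) -> float:
    """(a' R^-1 t)^2 / (a' R^-1 a); raises on singular R."""
    try:
        x = np.linalg.solve(r, np.column_stack([t, a]))
    except np.linalg.LinAlgError as exc:
        raise SingularCorrelationError(str(exc)) from exc
    num = float(a @ x[:, 0])
    den = float(a @ x[:, 1])
    if den <= 0 or not np.isfinite(den):
        raise SingularCorrelationError("non-positive quadratic denominator")
    return num * num / den


def _observed(T: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.isfinite(np.asarray(T, dtype=float)))


def s_hom(T, n, R, scheme: str = "sqrt_n") -> HomResult:
    """Homogeneous combined statistic and its chi-square(1) p-value.

    Missing entries (NaN in T) cause the corresponding rows/columns of R
    and W to be dropped.  Returns NaNs when every entry is missing.
    """
    T = np.asarray(T, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), T.shape)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    obs = _observed(T)
    if obs.size == 0:
        return HomResult(float("nan"), float("nan"), 0)
    t = T[obs]
    a = 1.0 / panel_weights(n[obs], scheme)
    r = R[np.ix_(obs, obs)]
    stat = _quad_form(t, r, a)
    return HomResult(stat, float(stats.chi2.sf(stat, df=1)), obs.size)


def s_tau(T, n, R, scheme: str = "sqrt_n", tau: float = 0.0) -> float:
    """Threshold-restricted statistic S(tau); NaN when the active set is
    empty or the restricted correlation is singular."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    T = np.asarray(T, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), T.shape)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    obs = _observed(T)
    act = obs[np.abs(T[obs]) > tau]
    if act.size == 0:
        return float("nan")
    t = T[act]
    a = np.sign(t) / panel_weights(n[act], scheme)
    try:
        return _quad_form(t, R[np.ix_(act, act)], a)
    except SingularCorrelationError:
        warnings.warn(f"singular restricted correlation at tau={tau:g}; skipped")
        return float("nan")


def s_het(T, n, R, scheme: str = "sqrt_n") -> HetResult:
    """Maximum of S(tau) over the finite candidate grid.

    S(tau) is piecewise constant between the order statistics of |T|, so
    evaluating tau just below each distinct non-zero |T| value is
    exhaustive.  Ties favour the smaller tau (larger active set).
    """
    T = np.asarray(T, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), T.shape)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    obs = _observed(T)
    if obs.size == 0:
        return HetResult(float("nan"), float("nan"), (), 0)
    mags = np.abs(T[obs])
    distinct = np.unique(mags[mags > 0])
    if distinct.size == 0:
        return HetResult(0.0, float("nan"), (), obs.size)
    best, best_tau, best_act = -np.inf, float("nan"), ()
    for v in distinct:  # ascending: smallest tau first, strict > keeps it on ties
        tau = v - _TAU_EPS
        val = s_tau(T, n, R, scheme, tau)
        if np.isfinite(val) and val > best:
            act = obs[np.abs(T[obs]) > tau]
            best, best_tau, best_act = val, tau, tuple(int(i) for i in act)
    if not np.isfinite(best):
        return HetResult(float("nan"), float("nan"), (), obs.size)
    return HetResult(float(best), float(best_tau), best_act, obs.size)


# ---------------------------------------------------------------------------
# vectorized scans


def s_hom_batch(Z: np.ndarray, n, R, scheme: str = "sqrt_n"):
    """Row-wise ``s_hom`` over an (M, P) matrix of Z scores.

    ``n`` may be a (P,) vector or an (M, P) matrix of per-SNP sample sizes.
    Rows are grouped by missingness pattern so complete data costs a single
    matrix product.  Returns (statistics, p_values, n_panels_used).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    m, p = Z.shape
    n = np.broadcast_to(np.asarray(n, dtype=float), Z.shape)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    stats_out = np.full(m, np.nan)
    used = np.isfinite(Z).sum(axis=1)

    finite = np.isfinite(Z)
    patterns, inverse = np.unique(finite, axis=0, return_inverse=True)
    for pi, pat in enumerate(patterns):
        rows = np.flatnonzero(inverse == pi)
        cols = np.flatnonzero(pat)
        if cols.size == 0:
            continue
        rsub = R[np.ix_(cols, cols)]
        try:
            rinv = np.linalg.inv(rsub)
        except np.linalg.LinAlgError as exc:
            raise SingularCorrelationError(
                f"singular correlation for missingness pattern {pat}"
            ) from exc
        a = 1.0 / panel_weights(n[np.ix_(rows, cols)], scheme)  # (rows, k)
        b = a @ rinv
        num = np.einsum("ij,ij->i", b, Z[np.ix_(rows, cols)])
        den = np.einsum("ij,ij->i", b, a)
        stats_out[rows] = num * num / den
    pvals = stats.chi2.sf(stats_out, df=1)
    return stats_out, pvals, used


def s_het_batch(Z: np.ndarray, n, R, scheme: str = "sqrt_n"):
    """Row-wise ``s_het`` with cached restricted-inverse reuse.

    The active sets visited by the tau grid are the top-m components by
    |Z|, so each row only evaluates prefix subsets of its magnitude order.
    Returns (statistics, tau_star, n_panels_used).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    m, p = Z.shape
    n = np.broadcast_to(np.asarray(n, dtype=float), Z.shape)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    cache: dict[tuple, np.ndarray | None] = {}

    def rinv_for(cols: tuple):
        got = cache.get(cols)
        if got is None and cols not in cache:
            sub = R[np.ix_(cols, cols)]
            try:
                got = np.linalg.inv(sub)
            except np.linalg.LinAlgError:
                got = None
            cache[cols] = got
        return got

    stats_out = np.full(m, np.nan)
    taus_out = np.full(m, np.nan)
    used = np.isfinite(Z).sum(axis=1)
    weights_all = panel_weights(n, scheme)

    for i in range(m):
        zi = Z[i]
        obs = np.flatnonzero(np.isfinite(zi))
        if obs.size == 0:
            continue
        mags = np.abs(zi[obs])
        if not (mags > 0).any():
            stats_out[i] = 0.0
            continue
        order = obs[np.argsort(-mags, kind="mergesort")]
        sorted_mags = np.abs(zi[order])
        # prefix lengths ending at strict drops in |Z| (tie-safe grid)
        prefix_ends = [
            k + 1
            for k in range(order.size)
            if sorted_mags[k] > 0
            and (k == order.size - 1 or sorted_mags[k + 1] < sorted_mags[k])
        ]
        best, best_tau = -np.inf, np.nan
        for k in reversed(prefix_ends):  # largest active set (smallest tau) first
            cols = tuple(sorted(int(c) for c in order[:k]))
            rinv = rinv_for(cols)
            if rinv is None:
                continue
            t = zi[list(cols)]
            a = np.sign(t) / weights_all[i, list(cols)]
            b = a @ rinv
            den = float(b @ a)
            if den <= 0:
                continue
            num = float(b @ t)
            val = num * num / den
            if val > best:
                best, best_tau = val, sorted_mags[k - 1] - _TAU_EPS
        if np.isfinite(best):
            stats_out[i] = best
            taus_out[i] = best_tau
    return stats_out, taus_out, used


# ---------------------------------------------------------------------------
# Monte-Carlo null for s_het


@dataclass
class HetNull:
    """Simulated null distribution of ``s_het`` for a fixed R and weights.

    ``draws`` is sorted ascending.  ``tail_alpha``/``tail_beta`` are the
    maximum-likelihood beta parameters fitted to ``V = exp(-S/2)``, used
    for p-values beyond the empirical tail.
    """

    draws: np.ndarray
    seed: int
    scheme: str
    n: np.ndarray
    labels: list[str] = field(default_factory=list)
    tail_alpha: float = float("nan")
    tail_beta: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        draws_path = prefix.with_suffix(".draws.tsv.gz")
        with gzip.open(draws_path, "wt") as fh:
            fh.write("s_het\n")
            for v in self.draws:
                fh.write(f"{v:.17g}\n")
        header = {
            "seed": self.seed,
            "B": self.n_draws,
            "scheme": self.scheme,
            "n": np.asarray(self.n, dtype=float).tolist(),
            "labels": self.labels,
            "tail_alpha": self.tail_alpha,
            "tail_beta": self.tail_beta,
            "diagnostics": self.diagnostics,
        }
        prefix.with_suffix(".null.json").write_text(json.dumps(header, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "HetNull":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".null.json").read_text())
        with gzip.open(prefix.with_suffix(".draws.tsv.gz"), "rt") as fh:
            next(fh)
            draws = np.array([float(line) for line in fh])
        return cls(
            draws=draws,
            seed=meta["seed"],
            scheme=meta["scheme"],
            n=np.asarray(meta["n"], dtype=float),
            labels=meta.get("labels", []),
            tail_alpha=meta.get("tail_alpha", float("nan")),
            tail_beta=meta.get("tail_beta", float("nan")),
            diagnostics=meta.get("diagnostics", {}),
        )


def _fit_beta_tail(draws: np.ndarray) -> tuple[float, float, dict]:
    v = np.clip(np.exp(-draws / 2.0), 1e-300, 1.0 - 1e-12)
    try:
        alpha, beta_par, _, _ = stats.beta.fit(v, floc=0, fscale=1)
    except Exception:  # fit failure leaves the tail model unusable but recorded
        return float("nan"), float("nan"), {"fit_failed": True}
    q99_emp = float(np.quantile(draws, 0.99))
    q99_fit = float(-2.0 * np.log(stats.beta.ppf(0.01, alpha, beta_par)))
    rel_err = abs(q99_fit - q99_emp) / q99_emp if q99_emp > 0 else float("nan")
    diag = {"q99_empirical": q99_emp, "q99_fitted": q99_fit, "q99_rel_err": rel_err}
    return float(alpha), float(beta_par), diag


def build_shet_null(
    R,
    n,
    scheme: str = "sqrt_n",
    B: int = 100_000,
    seed: int = 0,
    labels: list[str] | None = None,
) -> HetNull:
    """Simulate the null distribution of ``s_het``.

    Draws T ~ MVN(0, R) through the Cholesky factor (with one PSD-repair
    retry), evaluates ``s_het`` on each draw and fits the beta tail model.
    Fully reproducible from ``seed``.
    """
    if B < 1_000:
        raise ValueError("B must be >= 1000")
    R = np.atleast_2d(np.asarray(R, dtype=float))
    p = R.shape[0]
    n = np.broadcast_to(np.asarray(n, dtype=float), (p,))
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        from .nullcorr import nearest_psd

        repaired = nearest_psd(R) + 1e-12 * np.eye(p)
        try:
            chol = np.linalg.cholesky(repaired)
        except np.linalg.LinAlgError as exc:
            raise SingularCorrelationError("R not factorizable even after repair") from exc
    rng = np.random.default_rng(seed)
    draws = np.empty(B)
    chunk = 50_000
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        T = rng.standard_normal((hi - lo, p)) @ chol.T
        draws[lo:hi], _, _ = s_het_batch(T, n, R, scheme)
    draws.sort()
    alpha, beta_par, diag = _fit_beta_tail(draws)
    return HetNull(
        draws=draws,
        seed=seed,
        scheme=scheme,
        n=n,
        labels=labels or [],
        tail_alpha=alpha,
        tail_beta=beta_par,
        diagnostics=diag,
    )


def p_het_batch(statistics, null: HetNull) -> np.ndarray:
    """Monte-Carlo p-values with a fitted beta tail for extreme statistics.

    Empirical p = (1 + #{draws >= s}) / (B + 1) while at least
    ``_EMPIRICAL_MIN_TAIL`` draws exceed the statistic; beyond that the
    beta tail model takes over (kept in (0, 1]).
    """
    s = np.atleast_1d(np.asarray(statistics, dtype=float))
    if np.any(s[np.isfinite(s)] < 0):
        raise ValueError("statistic must be non-negative")
    B = null.n_draws
    n_ge = B - np.searchsorted(null.draws, s, side="left")
    p_emp = (1.0 + n_ge) / (B + 1.0)
    out = p_emp.copy()
    need_tail = (n_ge < _EMPIRICAL_MIN_TAIL) & np.isfinite(s)
    if need_tail.any():
        if not np.isfinite(null.tail_alpha):
            # no usable tail model: fall back to the empirical bound
            out[need_tail] = p_emp[need_tail]
        else:
            v = np.exp(-s[need_tail] / 2.0)
            out[need_tail] = stats.beta.cdf(v, null.tail_alpha, null.tail_beta)
    out[~np.isfinite(s)] = np.nan
    with np.errstate(invalid="ignore"):
        out = np.where(np.isfinite(out), np.clip(out, np.nextafter(0, 1), 1.0), out)
    return out


def p_het(statistic: float, null: HetNull) -> float:
    if not np.isfinite(statistic):
        return float("nan")
    if statistic < 0:
        raise ValueError("statistic must be non-negative")
    return float(p_het_batch([statistic], null)[0])
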