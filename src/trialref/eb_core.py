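"""Empirical-Bayes denoising of 2x2-table log odds ratios.

The model: comparison *i* has a latent log odds ratio ``omega_i`` drawn i.i.d.
from an unknown prior *G*, assumed symmetric about 0 because the two arms of
an active-comparator trial play symmetric roles. Conditioning the table on its
margins gives Fisher's noncentral hypergeometric likelihood

    L_i(w) = C(nA, xA) C(nB, xB) e^{w xA} / sum_t C(nA, t) C(nB, m - t) e^{w t}

with nA = xA + yA, nB = xB + yB, m = xA + xB and t ranging over the achievable
event splits. *G* is estimated by the Kiefer-Wolfowitz nonparametric maximum
likelihood estimator restricted to symmetric discrete distributions on a fixed
log-odds-ratio grid, fitted by EM. Point estimates are posterior means
E[omega | table, G-hat], which shrink noisy sample odds ratios toward 1 by an
amount adapted to each table's information content.

Numerical conventions
---------------------
All likelihood work is in log space with log-binomials via ``gammaln`` and
log-sum-exp denominators. The public likelihood matrix is shifted per table by
its value at omega = 0; the NPMLE objective and posterior means are invariant
to such per-table constants. Tables are canonicalized internally (the
lexicographically smaller column tuple is evaluated directly, the swapped
orientation at negated omega) so that exchanging the drug columns negates
posterior means *exactly*, not merely to rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .contingency import ComparisonRecord, ContingencyTable, sample_odds_ratio

#: default grid: atoms at 0 and +-k*0.05 on the log-OR scale out to log(1000).
DEFAULT_GRID_STEP = 0.05
DEFAULT_GRID_MAX = math.log(1000.0)

#: fitted mixing weights below this are truncated and the rest renormalized.
WEIGHT_TRUNCATION = 1e-12


# ---------------------------------------------------------------------------
# Grid and prior types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectGrid:
    """A symmetric grid of candidate log odds ratios containing 0."""

    atoms: np.ndarray

    def __post_init__(self) -> None:
        atoms = np.asarray(self.atoms, dtype=float)
        object.__setattr__(self, "atoms", atoms)
        if atoms.ndim != 1 or atoms.size == 0:
            raise ValueError("grid atoms must be a nonempty 1-d array")
        if np.any(np.diff(atoms) <= 0):
            raise ValueError("grid atoms must be strictly increasing")
        if not np.array_equal(atoms, -atoms[::-1]):
            raise ValueError("grid must be exactly symmetric about 0")
        if atoms[self.center] != 0.0:
            raise ValueError("grid must contain 0")

    @property
    def center(self) -> int:
        return (self.atoms.size - 1) // 2

    @property
    def n_half(self) -> int:
        """Number of nonnegative atoms (0 included)."""
        return self.center + 1

    @property
    def half_atoms(self) -> np.ndarray:
        """The nonnegative atoms, ascending from 0."""
        return self.atoms[self.center:]

    @classmethod
    def symmetric(cls, step: float = DEFAULT_GRID_STEP,
                  max_abs: float = DEFAULT_GRID_MAX) -> "EffectGrid":
        """Build 0, +-step, +-2*step, ... out to at least ``max_abs``."""
        if step <= 0 or max_abs <= 0:
            raise ValueError("step and max_abs must be positive")
        k = int(math.ceil(max_abs / step - 1e-9))
        pos = step * np.arange(1, k + 1)
        return cls(np.concatenate([-pos[::-1], [0.0], pos]))


@dataclass(frozen=True)
class PriorEstimate:
    """A discrete symmetric prior over log odds ratios: grid atoms + weights."""

    grid: EffectGrid
    weights: np.ndarray
    n_iter: int = 0
    objective: float = math.nan

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != self.grid.atoms.shape:
            raise ValueError("one weight per grid atom required")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")
        if np.max(np.abs(w - w[::-1])) > 1e-12:
            raise ValueError("weights must be symmetric about 0")

    @classmethod
    def point_mass_at_zero(cls, grid: EffectGrid) -> "PriorEstimate":
        w = np.zeros_like(grid.atoms)
        w[grid.center] = 1.0
        return cls(grid, w)

    @property
    def half_weights(self) -> np.ndarray:
        """Total mass per nonnegative atom: w(0), then w(+g) + w(-g)."""
        c = self.grid.center
        out = self.weights[c:].copy()
        out[1:] += self.weights[:c][::-1]
        return out


@dataclass(frozen=True)
class DenoisedEffect:
    """A comparison with its raw sample OR and empirical-Bayes denoised effect."""

    record: ComparisonRecord
    sample_or: float
    omega_eb: float
    or_eb: float


# ---------------------------------------------------------------------------
# Conditional likelihood
# ---------------------------------------------------------------------------


def _lchoose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _canonical(table: ContingencyTable) -> tuple[ContingencyTable, bool]:
    """Deterministic column orientation; second element: was it swapped."""
    own = (table.x_a, table.y_a, table.x_b, table.y_b)
    other = (table.x_b, table.y_b, table.x_a, table.y_a)
    if own <= other:
        return table, False
    return table.swapped(), True


def _raw_loglik(table: ContingencyTable, omegas: np.ndarray) -> np.ndarray:
    """log L(omega) for each omega, by exact support enumeration in log space."""
    n_a, n_b, m, x_a = table.n_a, table.n_b, table.m, table.x_a
    lo, hi = max(0, m - n_b), min(n_a, m)
    if lo == hi:  # single-point support: probability 1 for every omega
        return np.zeros_like(omegas, dtype=float)
    t = np.arange(lo, hi + 1)
    log_coeffs = _lchoose(n_a, t) + _lchoose(n_b, m - t)
    denom = logsumexp(log_coeffs[:, None] + t[:, None] * omegas[None, :], axis=0)
    return _lchoose(n_a, x_a) + _lchoose(n_b, table.x_b) + omegas * x_a - denom


def log_likelihood(table: ContingencyTable, omega: float) -> float:
    """Log of the Fisher noncentral hypergeometric pmf at the observed x_a."""
    canon, swapped = _canonical(table)
    w = -omega if swapped else omega
    return float(_raw_loglik(canon, np.asarray([w], dtype=float))[0])


def _loglik_on_grid(table: ContingencyTable, atoms: np.ndarray) -> np.ndarray:
    """Log-likelihood across a symmetric grid, swap-exact (see module docs)."""
    canon, swapped = _canonical(table)
    vals = _raw_loglik(canon, -atoms if swapped else atoms)
    return vals


def likelihood_matrix(
    tables: Sequence[ContingencyTable], grid: EffectGrid
) -> np.ndarray:
    """Per-table log-likelihood rows over the grid, shifted to 0 at omega = 0.

    The per-table shift is harmless: the NPMLE objective and posterior means
    are invariant to multiplying each table's likelihood by a constant.
    """
    atoms = grid.atoms
    out = np.empty((len(tables), atoms.size))
    for i, table in enumerate(tables):
        out[i] = _loglik_on_grid(table, atoms)
    out -= out[:, grid.center][:, None]
    return out


# ---------------------------------------------------------------------------
# Symmetric NPMLE via EM
# ---------------------------------------------------------------------------


def _half_kernels(shifted_ll: np.ndarray, grid: EffectGrid) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized likelihood kernels on the nonnegative half-grid.

    Returns (K, row_shift) where K[i, j] = (L_i(+g_j) + L_i(-g_j)) / 2 after
    rescaling row i by exp(-row_shift[i]) to keep everything in float range.
    """
    c = grid.center
    row_shift = shifted_ll.max(axis=1)
    L = np.exp(shifted_ll - row_shift[:, None])
    K = np.empty((shifted_ll.shape[0], grid.n_half))
    K[:, 0] = L[:, c]
    K[:, 1:] = 0.5 * (L[:, c + 1:] + L[:, :c][:, ::-1])
    return K, row_shift


def fit_symmetric_npmle(
    tables: Sequence[ContingencyTable],
    grid: EffectGrid | None = None,
    tol: float = 1e-9,
    max_iter: int = 10000,
) -> PriorEstimate:
    """Kiefer-Wolfowitz NPMLE of the effect prior, constrained symmetric.

    Maximizes the marginal log-likelihood ``sum_i log sum_j w_j L_i(g_j)``
    over symmetric discrete distributions on the grid. Symmetry is imposed
    structurally: the problem is reduced to an unconstrained-simplex NPMLE
    over the nonnegative half-grid with symmetrized kernels
    ``K_i(j) = [L_i(+g_j) + L_i(-g_j)] / 2``, whose solution is reflected back
    to full-grid weights. Fitting uses EM self-consistency iterations from
    uniform weights; each iteration is monotone in the objective. Stops when
    the relative objective improvement drops below ``tol`` or after
    ``max_iter`` iterations. The reported ``objective`` is on the same
    per-table-shifted scale as :func:`marginal_log_likelihood`.
    """
    if len(tables) == 0:
        raise ValueError("at least one table is required")
    grid = grid if grid is not None else EffectGrid.symmetric()
    shifted = likelihood_matrix(tables, grid)
    K, row_shift = _half_kernels(shifted, grid)
    # row_shift converts the EM objective back to the omega=0-shifted scale
    const = row_shift.sum()
    v = np.full(grid.n_half, 1.0 / grid.n_half)
    prev = -math.inf
    obj = -math.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mix = K @ v
        obj = float(np.log(mix).sum() + const)
        if n_iter > 1 and obj - prev < tol * (abs(prev) + 1.0):
            break
        prev = obj
        v *= (K / mix[:, None]).mean(axis=0)
        v /= v.sum()
    v[v < WEIGHT_TRUNCATION] = 0.0
    v /= v.sum()
    weights = np.zeros_like(grid.atoms)
    c = grid.center
    weights[c] = v[0]
    weights[c + 1:] = v[1:] / 2.0
    weights[:c] = weights[c + 1:][::-1]
    weights /= weights.sum()
    return PriorEstimate(grid=grid, weights=weights, n_iter=n_iter, objective=obj)


def marginal_log_likelihood(
    prior: PriorEstimate, tables: Sequence[ContingencyTable]
) -> float:
    """Mixture log-likelihood of the tables under the prior (shifted scale).

    Uses the per-table omega=0-shifted likelihood matrix, so absolute values
    carry per-table constants but *differences* between priors are shift-free.
    """
    shifted = likelihood_matrix(tables, prior.grid)
    with np.errstate(divide="ignore"):
        logw = np.log(prior.weights)
    return float(logsumexp(shifted + logw[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# Posterior-mean denoising
# ---------------------------------------------------------------------------


def posterior_mean(prior: PriorEstimate, table: ContingencyTable) -> float:
    """E[omega | table, prior]: the empirical-Bayes denoised log odds ratio.

    Computed over half-grid atom pairs so that the drug-column-swapped table
    yields the exactly negated value; magnitude is bounded by the largest
    grid atom.
    """
    grid = prior.grid
    c = grid.center
    ll = _loglik_on_grid(table, grid.atoms)
    with np.errstate(divide="ignore"):
        logw = np.log(prior.weights)
    # use the positive-side weights for both signs: the prior is symmetric and
    # this keeps the +/- terms bitwise mirrored
    s_pos = ll[c + 1:] + logw[c + 1:]
    s_neg = ll[:c][::-1] + logw[c + 1:]
    s_zero = ll[c] + logw[c]
    shift = max(float(np.max(s_pos, initial=-math.inf)),
                float(np.max(s_neg, initial=-math.inf)),
                s_zero)
    if shift == -math.inf:  # prior is a point mass at 0
        return 0.0
    pos = np.exp(s_pos - shift)
    neg = np.exp(s_neg - shift)
    g = grid.atoms[c + 1:]
    num = float(np.sum(g * (pos - neg)))
    den = float(math.exp(s_zero - shift) + np.sum(pos + neg))
    return num / den


def denoise_all(
    prior: PriorEstimate, records: Sequence[ComparisonRecord]
) -> list[DenoisedEffect]:
    """Posterior-mean denoising of every comparison, order preserved."""
    out = []
    for rec in records:
        omega_eb = posterior_mean(prior, rec.table)
        out.append(
            DenoisedEffect(
                record=rec,
                sample_or=sample_odds_ratio(rec.table, continuity=0.5),
                omega_eb=omega_eb,
                or_eb=math.exp(omega_eb),
            )
        )
    return out


def prior_cdf(prior: PriorEstimate, omega: float) -> float:
    """Right-continuous CDF of the discrete prior at ``omega``."""
    mass = float(prior.weights[prior.grid.atoms <= omega].sum())
    return min(mass, 1.0)  # weight sums may overshoot 1 by an ulp


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------


def write_prior_tsv(prior: PriorEstimate, path: str | Path) -> None:
    df = pd.DataFrame({"log_or_atom": prior.grid.atoms, "weight": prior.weights})
    df.to_csv(path, sep="\t", index=False, float_format="%.12e", lineterminator="\n")


def read_prior_tsv(path: str | Path) -> PriorEstimate:
    df = pd.read_csv(path, sep="\t")
    atoms = df["log_or_atom"].to_numpy(dtype=float)
    # re-symmetrize exactly: serialization rounds atoms/weights to 12 digits
    c = (atoms.size - 1) // 2
    atoms = np.concatenate([-atoms[c + 1:][::-1], [0.0], atoms[c + 1:]])
    w = df["weight"].to_numpy(dtype=float)
    w = np.clip(w, 0.0, None)
    w_half = w[c:].copy()
    w_half[1:] = 0.5 * (w[c + 1:] + w[:c][::-1])
    full = np.concatenate([w_half[1:][::-1], [w_half[0]], w_half[1:]])
    full /= full.sum()
    return PriorEstimate(grid=EffectGrid(atoms), weights=full)


def denoised_to_frame(effects: Sequence[DenoisedEffect]) -> pd.DataFrame:
    from .contingency import comparisons_to_frame

    df = comparisons_to_frame([e.record for e in effects])
    df["sample_or"] = [e.sample_or for e in effects]
    df["log_or_eb"] = [e.omega_eb for e in effects]
    df["or_eb"] = [e.or_eb for e in effects]
    return df


def write_denoised_tsv(effects: Sequence[DenoisedEffect], path: str | Path) -> None:
    denoised_to_frame(effects).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_denoised_tsv(path: str | Path) -> list[DenoisedEffect]:
    from .contingency import read_comparisons_tsv

    df = pd.read_csv(path, sep="\t")
    records = read_comparisons_tsv(path)
    return [
        DenoisedEffect(
            record=rec,
            sample_or=float(row["sample_or"]),
            omega_eb=float(row["log_or_eb"]),
            or_eb=float(row["or_eb"]),
        )
        for rec, (_, row) in zip(records, df.iterrows())
    ]
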