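"""Mean-field direct coupling analysis (DCA).

The inference pipeline is the classic naive mean-field scheme: reweighted
single-site and pair frequencies are regularised with a heavy uniform
pseudocount admixture (weight 0.8 by default), the connected-correlation
(covariance) matrix is built in the gauge that drops the gap state, couplings
are read off the negative inverse of that matrix, and each pair is ranked by
its direct information (DI) -- the mutual information of the pair's two-site
model against the independent product of its site marginals.  Scores are
finally re-indexed to 1-based positions of the original target sequence.

Memory note: the covariance matrix has side ``C * (q - 1)`` for ``C``
retained columns, i.e. about 12,000 for a 600-residue target; dense inversion
of that size is the intended operating range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .msa import Alignment, GAP_STATE, Q, SequenceWeights, sequence_weights


@dataclass
class FrequencyModel:
    """Reweighted, pseudocount-regularised frequency estimates.

    ``single_site[i, A] = (1 - lambda_pc) * f_emp_i(A) + lambda_pc / q`` and
    pair tables mix the empirical weighted pair counts with a uniform
    ``lambda_pc / q**2`` background (for distinct sites).  With
    ``lambda_pc = 1`` everything is exactly uniform.
    """

    q: int
    lambda_pc: float
    single_site: np.ndarray  # (C, q)
    m_eff: float
    _onehot: np.ndarray  # (M, C, q) float32
    _weights: np.ndarray  # (M,)

    @property
    def n_columns(self) -> int:
        return self.single_site.shape[0]

    def pair(self, i: int, j: int) -> np.ndarray:
        """Pseudocounted pair table ``f_ij(A, B)`` for columns ``i``, ``j`` (0-based)."""
        if i == j:
            return np.diag(self.single_site[i])
        emp = (self._onehot[:, i, :] * self._weights[:, None]).T @ self._onehot[:, j, :]
        emp /= self.m_eff
        return (1.0 - self.lambda_pc) * emp + self.lambda_pc / self.q**2


def compute_frequencies(
    aln: Alignment,
    weights: SequenceWeights | None = None,
    lambda_pc: float = 0.8,
) -> FrequencyModel:
    """Weighted single-site/pair frequencies with uniform pseudocounts."""
    if not 0.0 <= lambda_pc <= 1.0:
        raise ValueError("lambda_pc must lie in [0, 1]")
    if weights is None:
        weights = sequence_weights(aln)
    w = np.asarray(weights.weights, dtype=np.float64)
    M, C = aln.matrix.shape
    onehot = np.zeros((M, C, Q), dtype=np.float32)
    rows = np.repeat(np.arange(M), C)
    cols = np.tile(np.arange(C), M)
    onehot[rows, cols, aln.matrix.ravel()] = 1.0
    f_emp = np.tensordot(w, onehot, axes=(0, 0)) / weights.m_eff  # (C, q)
    single = (1.0 - lambda_pc) * f_emp + lambda_pc / Q
    return FrequencyModel(
        q=Q,
        lambda_pc=lambda_pc,
        single_site=single,
        m_eff=weights.m_eff,
        _onehot=onehot,
        _weights=w,
    )


def covariance_matrix(freqs: FrequencyModel) -> np.ndarray:
    """Connected-correlation matrix ``C_ij(A,B) = f_ij(A,B) - f_i(A) f_j(B)``.

    The gap state is dropped as the gauge choice, giving a square matrix of
    side ``n_columns * (q - 1)``.
    """
    q = freqs.q
    n = freqs.n_columns
    lam = freqs.lambda_pc
    Xr = (freqs._onehot[:, :, : q - 1]).reshape(freqs._onehot.shape[0], n * (q - 1))
    Xr = Xr.astype(np.float64)
    P2 = (Xr * freqs._weights[:, None]).T @ Xr / freqs.m_eff
    F2 = (1.0 - lam) * P2 + lam / q**2
    # the same-site block of the pair table is diagonal: f_ii(A,B) = f_i(A) delta_AB
    for i in range(n):
        s = slice(i * (q - 1), (i + 1) * (q - 1))
        F2[s, s] = np.diag(freqs.single_site[i, : q - 1])
    f1 = freqs.single_site[:, : q - 1].ravel()
    return F2 - np.outer(f1, f1)


def mean_field_couplings(C: np.ndarray, n_columns: int | None = None, q: int = Q) -> np.ndarray:
    """Couplings ``e_ij(A,B) = -(C^{-1})_ij(A,B)`` as ``(C, C, q-1, q-1)`` blocks.

    Diagonal (same-site) blocks are returned but carry no interpretation.
    """
    side = C.shape[0]
    if n_columns is None:
        n_columns = side // (q - 1)
    if n_columns * (q - 1) != side:
        raise ValueError("covariance side is not a multiple of q - 1")
    try:
        inv = scipy.linalg.inv(C)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; increase the pseudocount weight lambda_pc"
        ) from exc
    e = -inv.reshape(n_columns, q - 1, n_columns, q - 1)
    return np.ascontiguousarray(e.transpose(0, 2, 1, 3))


def _fit_two_site_model(W, fi, fj, tol, max_iter):
    """Match the marginals of ``P ~ W * mu_i mu_j`` to ``fi``, ``fj``.

    Alternating fixed-point iteration with deterministic uniform
    initialisation; returns (mu_i, mu_j, converged).
    """
    q = W.shape[0]
    mu1 = np.full(q, 1.0 / q)
    mu2 = np.full(q, 1.0 / q)
    for _ in range(max_iter):
        new1 = fi / (W @ mu2)
        new1 /= new1.sum()
        new2 = fj / (W.T @ new1)
        new2 /= new2.sum()
        delta = max(np.abs(new1 - mu1).max(), np.abs(new2 - mu2).max())
        mu1, mu2 = new1, new2
        if delta < tol:
            return mu1, mu2, True
    return mu1, mu2, False


def direct_information(
    couplings: np.ndarray,
    freqs: FrequencyModel,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Direct information for all column pairs.

    For each pair the two-site distribution ``P_ij(A,B) ~ exp(e_ij(A,B))
    h_i(A) h_j(B)`` is fitted so its marginals reproduce the single-site
    frequencies (the dropped gauge state carries zero coupling), then
    ``DI = sum P log(P / (f_i f_j))``.  Returns a symmetric ``(C, C)`` matrix
    with ``nan`` on the diagonal; values are clipped at zero against
    round-off.  Non-converged pairs are scored from the last iterate and
    reported in a single warning.
    """
    n = freqs.n_columns
    q = freqs.q
    di = np.zeros((n, n))
    n_fail = 0
    for i in range(n - 1):
        fi = freqs.single_site[i]
        for j in range(i + 1, n):
            fj = freqs.single_site[j]
            W = np.ones((q, q))
            W[: q - 1, : q - 1] = np.exp(couplings[i, j])
            mu1, mu2, ok = _fit_two_site_model(W, fi, fj, tol, max_iter)
            if not ok:
                n_fail += 1
            P = W * np.outer(mu1, mu2)
            P /= P.sum()
            ref = np.outer(fi, fj)
            val = float(np.sum(P * np.log(np.clip(P, 1e-30, None) / np.clip(ref, 1e-30, None))))
            di[i, j] = di[j, i] = max(val, 0.0)
    if n_fail:
        warnings.warn(f"direct-information fixed point did not converge for {n_fail} pairs")
    np.fill_diagonal(di, np.nan)
    return di


def map_scores_to_sequence(
    di: np.ndarray, column_map: np.ndarray, original_length: int
) -> np.ndarray:
    """Re-index a column-space DI matrix to original 1-based target positions.

    Positions removed by filtering carry ``nan`` (no score).
    """
    column_map = np.asarray(column_map)
    if di.shape[0] != di.shape[1] or di.shape[0] != column_map.size:
        raise ValueError("DI matrix side must match column_map length")
    out = np.full((original_length, original_length), np.nan)
    idx = column_map - 1
    out[np.ix_(idx, idx)] = di
    np.fill_diagonal(out, np.nan)
    return out


@dataclass
class CouplingResult:
    """Couplings and DI scores of one alignment, in target coordinates."""

    di: np.ndarray  # (L, L), nan where unscored
    couplings: np.ndarray  # (C, C, q-1, q-1)
    column_map: np.ndarray
    m_eff: float
    lambda_pc: float


def run_dca(
    aln: Alignment,
    weights: SequenceWeights | None = None,
    lambda_pc: float = 0.8,
) -> CouplingResult:
    """Full mean-field DCA on a (filtered) alignment."""
    if weights is None:
        weights = sequence_weights(aln)
    freqs = compute_frequencies(aln, weights, lambda_pc)
    C = covariance_matrix(freqs)
    e = mean_field_couplings(C, freqs.n_columns)
    di_cols = direct_information(e, freqs)
    di = map_scores_to_sequence(di_cols, aln.column_map, aln.original_length)
    return CouplingResult(
        di=di,
        couplings=e,
        column_map=aln.column_map.copy(),
        m_eff=weights.m_eff,
        lambda_pc=lambda_pc,
    )


def write_di_tsv(di: np.ndarray, path) -> None:
    """Write scored pairs as ``i<TAB>j<TAB>di`` with 1-based coordinates."""
    L = di.shape[0]
    with open(path, "w") as fh:
        fh.write("i\tj\tdi\n")
        for i in range(L - 1):
            for j in range(i + 1, L):
                if np.isfinite(di[i, j]):
                    fh.write(f"{i + 1}\t{j + 1}\t{di[i, j]:.10g}\n")


def read_di_tsv(path, length: int) -> np.ndarray:
    di = np.full((length, length), np.nan)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("i\tj"):
            raise ValueError("not a DI table: missing 'i\\tj\\tdi' header")
        for line in fh:
            si, sj, sv = line.split()
            i, j = int(si) - 1, int(sj) - 1
            di[i, j] = di[j, i] = float(sv)
    return di
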