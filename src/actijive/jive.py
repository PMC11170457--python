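"""Joint and Individual Variation Explained (JIVE) for multi-block features.

Given K feature blocks sharing subjects (rows), JIVE decomposes each block
as ``X_k = J_k + A_k + E_k`` where the joint parts ``J_k`` share a common
rank-r subject subspace across blocks, the individual parts ``A_k`` are
block-specific low-rank terms whose subject scores are orthogonal to the
joint scores, and ``E_k`` is residual noise.  Estimation alternates

* joint step: best rank-r approximation (SVD) of the column-concatenation
  of ``X_k - A_k``;
* individual step: best rank-r_k approximation of
  ``(I - U U^T)(X_k - J_k)``, which enforces the score orthogonality,

until the Frobenius change in the joint part falls below ``tol``.  Each
step minimises the total residual sum of squares, so the fit is monotone.

Ranks can be supplied or selected by permutation tests: observed singular
values are compared with the null distribution obtained by independently
permuting each block's rows (joint rank) or each column's entries within a
block (individual ranks).

Loadings are reported with unit Euclidean norm per component (squared
loadings sum to 1 across the concatenated features for joint components,
within the block for individual ones), so squared loadings read as the
proportional importance of each feature for the component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import BLOCKS, FeatureBlocks


@dataclass
class ScaledBlocks:
    """Preprocessed blocks: median-imputed, column z-scored, Frobenius-normalised."""

    X: dict[str, np.ndarray]
    columns: dict[str, list[str]]
    subjects: list[str]
    col_mean: dict[str, np.ndarray]
    col_sd: dict[str, np.ndarray]
    block_norm: dict[str, float]

    @property
    def n(self) -> int:
        return len(self.subjects)

    def inverse_transform(self, name: str, Z: np.ndarray) -> pd.DataFrame:
        """Map a matrix on the preprocessed scale back to feature units."""
        raw = Z * self.block_norm[name] * self.col_sd[name] + self.col_mean[name]
        return pd.DataFrame(raw, index=self.subjects, columns=self.columns[name])


def preprocess(blocks: FeatureBlocks | pd.DataFrame,
               block_map: dict[str, list[str]] | None = None) -> ScaledBlocks:
    """Impute (column median), z-score each column, scale each block to
    unit Frobenius norm so the blocks contribute equally to the joint fit."""
    if isinstance(blocks, FeatureBlocks):
        df, block_map = blocks.data, blocks.blocks
    else:
        df = blocks
        block_map = block_map or {
            k: [c for c in cols if c in blocks.columns] for k, cols in BLOCKS.items()
        }
    X, means, sds, norms, columns = {}, {}, {}, {}, {}
    for name, cols in block_map.items():
        M = df[cols].to_numpy(dtype=float).copy()
        med = np.nanmedian(M, axis=0)
        nan_mask = np.isnan(M)
        if nan_mask.any():
            M[nan_mask] = np.take(med, np.nonzero(nan_mask)[1])
        mu = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd <= 1e-10 * np.maximum(1.0, np.abs(mu)))
        if zero.size:
            raise ValueError(f"zero-variance feature '{cols[zero[0]]}' in block {name}")
        Z = (M - mu) / sd
        fro = float(np.linalg.norm(Z))
        X[name] = Z / fro
        means[name], sds[name], norms[name], columns[name] = mu, sd, fro, list(cols)
    return ScaledBlocks(X, columns, list(df.index.astype(str)), means, sds, norms)


@dataclass
class JiveModel:
    """Fitted JIVE decomposition on the preprocessed scale."""

    block_names: list[str]
    subjects: list[str]
    columns: dict[str, list[str]]
    r_joint: int
    r_indiv: dict[str, int]
    joint_scores: np.ndarray  # n x r_joint (U * singular values)
    joint_loadings: np.ndarray  # (sum p_k) x r_joint, unit-norm columns
    joint_parts: dict[str, np.ndarray]  # J_k
    indiv_scores: dict[str, np.ndarray]  # n x r_k
    indiv_loadings: dict[str, np.ndarray]  # p_k x r_k, unit-norm columns
    indiv_parts: dict[str, np.ndarray]  # A_k
    varexp: dict[str, dict[str, float]]
    converged: bool
    n_iter: int
    rss_path: list[float] = field(default_factory=list)

    def residual(self, name: str, X: dict[str, np.ndarray]) -> np.ndarray:
        return X[name] - self.joint_parts[name] - self.indiv_parts[name]


def _rank_approx(M: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best rank-r approximation; returns (approx, scores, unit loadings)."""
    n, p = M.shape
    if r == 0:
        return np.zeros_like(M), np.zeros((n, 0)), np.zeros((p, 0))
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    scores = u[:, :r] * s[:r]
    loadings = vt[:r].T
    return scores @ loadings.T, scores, loadings


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Deterministic sign: largest-|.| element of each loading column positive."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0


def fit_jive(
    scaled: ScaledBlocks,
    r_joint: int,
    r_indiv: dict[str, int] | list[int] | tuple[int, ...],
    *,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> JiveModel:
    """Alternating joint/individual estimation at fixed ranks."""
    names = list(scaled.X)
    if not isinstance(r_indiv, dict):
        r_indiv = dict(zip(names, r_indiv))
    Xs = scaled.X
    n = scaled.n
    p_tot = sum(x.shape[1] for x in Xs.values())
    if r_joint + max(r_indiv.values(), default=0) >= min(n, p_tot):
        raise ValueError("requested ranks are infeasible for the data size")
    splits = np.cumsum([Xs[k].shape[1] for k in names])[:-1]
    A = {k: np.zeros_like(Xs[k]) for k in names}
    J_prev = None
    U = np.zeros((n, 0))
    rss_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = np.hstack([Xs[k] - A[k] for k in names])
        J, joint_scores, joint_loadings = _rank_approx(C, r_joint)
        if r_joint > 0:
            U, _ = np.linalg.qr(joint_scores)
        J_parts = dict(zip(names, np.hsplit(J, splits)))
        rss = 0.0
        for k in names:
            R = Xs[k] - J_parts[k]
            R_proj = R - U @ (U.T @ R) if r_joint > 0 else R
            A[k] = _rank_approx(R_proj, r_indiv[k])[0]
            rss += float(np.linalg.norm(Xs[k] - J_parts[k] - A[k]) ** 2)
        rss_path.append(rss)
        if J_prev is not None and float(np.linalg.norm(J - J_prev)) < tol:
            converged = True
            break
        if r_joint == 0 and it >= 1:
            converged = True
            break
        J_prev = J
    _fix_signs(joint_scores, joint_loadings)
    indiv_scores, indiv_loadings = {}, {}
    for k in names:
        _, sc, ld = _rank_approx(A[k], r_indiv[k])
        _fix_signs(sc, ld)
        indiv_scores[k], indiv_loadings[k] = sc, ld
    varexp = {}
    for k in names:
        tot = float(np.linalg.norm(Xs[k]) ** 2)
        j2 = float(np.linalg.norm(J_parts[k]) ** 2)
        a2 = float(np.linalg.norm(A[k]) ** 2)
        r2 = float(np.linalg.norm(Xs[k] - J_parts[k] - A[k]) ** 2)
        varexp[k] = {"joint": j2 / tot, "individual": a2 / tot, "residual": r2 / tot}
    return JiveModel(
        block_names=names, subjects=scaled.subjects, columns=scaled.columns,
        r_joint=r_joint, r_indiv=dict(r_indiv), joint_scores=joint_scores,
        joint_loadings=joint_loadings, joint_parts=J_parts,
        indiv_scores=indiv_scores, indiv_loadings=indiv_loadings,
        indiv_parts={k: A[k] for k in names}, varexp=varexp,
        converged=converged, n_iter=it, rss_path=rss_path,
    )


def _sv(M: np.ndarray) -> np.ndarray:
    return np.linalg.svd(M, compute_uv=False)


def select_ranks(
    scaled: ScaledBlocks,
    *,
    alpha: float = 0.05,
    n_perm: int = 99,
    seed: int = 0,
    max_cycles: int = 10,
) -> tuple[int, dict[str, int], bool]:
    """Permutation-based selection of the joint and individual ranks.

    Returns ``(r_joint, r_indiv, stable)``; ``stable`` is False when the
    outer loop did not reach a fixed point within ``max_cycles``.
    """
    rng = np.random.default_rng(seed)
    names = list(scaled.X)
    n = scaled.n
    r_joint, r_indiv = 0, {k: 0 for k in names}
    A = {k: np.zeros_like(scaled.X[k]) for k in names}
    stable = False
    for _ in range(max_cycles):
        # joint rank: null from independent row permutation of each block
        resid = {k: scaled.X[k] - A[k] for k in names}
        obs = _sv(np.hstack([resid[k] for k in names]))
        null_max = np.empty(n_perm)
        for b in range(n_perm):
            null_max[b] = _sv(np.hstack(
                [resid[k][rng.permutation(n)] for k in names]))[0]
        thr = float(np.quantile(null_max, 1.0 - alpha))
        new_r_joint = int(np.count_nonzero(obs > thr))
        cap = min(n, sum(x.shape[1] for x in scaled.X.values())) - 1
        new_r_joint = min(new_r_joint, cap)
        model = fit_jive(scaled, new_r_joint, r_indiv)
        # individual ranks: null from within-column entry permutation
        new_r_indiv = {}
        for k in names:
            R = scaled.X[k] - model.joint_parts[k]
            obs_k = _sv(R)
            null_k = np.empty(n_perm)
            Rp = R.copy()
            for b in range(n_perm):
                for j in range(Rp.shape[1]):
                    Rp[:, j] = R[rng.permutation(n), j]
                null_k[b] = _sv(Rp)[0]
            thr_k = float(np.quantile(null_k, 1.0 - alpha))
            new_r_indiv[k] = min(int(np.count_nonzero(obs_k > thr_k)),
                                 min(R.shape) - 1)
        if new_r_joint == r_joint and new_r_indiv == r_indiv:
            stable = True
            break
        r_joint, r_indiv = new_r_joint, new_r_indiv
        model = fit_jive(scaled, r_joint, r_indiv)
        A = model.indiv_parts
    return r_joint, r_indiv, stable


def extract_scores(model: JiveModel) -> pd.DataFrame:
    """Subject score table, standardized to mean 0 / SD 1 per column.

    Columns are named ``Joint-1..``, then ``<block>-1..`` per block.  Joint
    scores are mutually orthogonal and every individual score is orthogonal
    to all joint scores; standardization is a pure rescale (scores are
    exactly mean 0 on column-centered inputs), so orthogonality survives.
    """
    cols, mats = [], []
    if model.r_joint > 0:
        cols += [f"Joint-{i + 1}" for i in range(model.r_joint)]
        mats.append(model.joint_scores)
    for k in model.block_names:
        r = model.r_indiv[k]
        if r > 0:
            cols += [f"{k}-{i + 1}" for i in range(r)]
            mats.append(model.indiv_scores[k])
    S = np.hstack(mats) if mats else np.zeros((len(model.subjects), 0))
    S = S - S.mean(axis=0, keepdims=True)
    sd = S.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return pd.DataFrame(S / sd, index=model.subjects, columns=cols)


def loading_table(model: JiveModel, *, min_share: float = 0.05) -> pd.DataFrame:
    """Long-format loadings: signed loading, squared loading and a flag for
    features carrying more than ``min_share`` of a component's variation."""
    rows = []
    all_cols = [c for k in model.block_names for c in model.columns[k]]
    for j in range(model.r_joint):
        for f, v in zip(all_cols, model.joint_loadings[:, j]):
            rows.append(("Joint", f"Joint-{j + 1}", f, float(v), float(v * v)))
    for k in model.block_names:
        for j in range(model.r_indiv[k]):
            for f, v in zip(model.columns[k], model.indiv_loadings[k][:, j]):
                rows.append((k, f"{k}-{j + 1}", f, float(v), float(v * v)))
    df = pd.DataFrame(rows, columns=["block", "component", "feature",
                                     "loading", "squared_loading"])
    df["important"] = df["squared_loading"] > min_share
    return df


def varexp_table(model: JiveModel) -> pd.DataFrame:
    """Per-block joint/individual/residual variance-explained fractions."""
    return pd.DataFrame(model.varexp).T[["joint", "individual", "residual"]]
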