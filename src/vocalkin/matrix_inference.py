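"""Permutation inference on dyadic score matrices.

Mantel tests correlate two individual-by-individual matrices over their
dyads; significance comes from simultaneously permuting the rows and
columns of the second matrix (the standard object-label null, which
respects the dyadic dependence structure).  Partial Mantel tests hold a
third matrix constant through the first-order partial correlation.  The
contact-restricted Pearson correlation addresses the excess of zeros in
the contact matrix (most dyads never shared a cage) by correlating
acoustic dissimilarity with contact only over dyads that had contact.

Sign convention: contact is a *similarity* (1 = always together) correlated
directly against a *dissimilarity*, so a negative r means vocal convergence
and a positive r divergence, as printed in the source tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dyad_scores import ScoreMatrix


@dataclass
class MantelResult:
    r: float
    p_two_tailed: float
    n_permutations: int
    held_constant: str | None
    n_dyads: int


def _as_labelled(m) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(m, ScoreMatrix):
        return m.values, m.ids
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), [str(i) for i in m.index]
    return np.asarray(m, dtype=float), None


def _align(*matrices) -> list[np.ndarray]:
    """Check shapes and id order of the inputs; return plain arrays."""
    arrays, id_sets = [], []
    for m in matrices:
        a, ids = _as_labelled(m)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("matrices must be square")
        arrays.append(a)
        id_sets.append(ids)
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("matrices differ in size")
    labelled = [ids for ids in id_sets if ids is not None]
    for ids in labelled[1:]:
        if ids != labelled[0]:
            raise ValueError("matrix individual ids do not match")
    return arrays


def symmetrize(values: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Symmetrize a directed matrix: dyad mean or upper triangle mirrored."""
    if mode == "mean":
        return 0.5 * (values + values.T)
    if mode == "upper":
        return np.triu(values, 1) + np.triu(values, 1).T
    raise ValueError(f"unknown symmetrize mode {mode!r}")


def vectorize_dyads(matrix, mode: str = "mean") -> np.ndarray:
    """Flatten a square matrix to a dyad vector.

    ``mean``: one value per unordered pair, (v_ij + v_ji) / 2;
    ``upper``: the upper triangle as stored;
    ``directed``: all n(n-1) off-diagonal cells.
    """
    (a,) = _align(matrix)
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    if mode == "mean":
        return 0.5 * (a + a.T)[iu]
    if mode == "upper":
        return a[iu]
    if mode == "directed":
        return a[~np.eye(n, dtype=bool)]
    raise ValueError(f"unknown vectorize mode {mode!r}")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance dyad vector: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(A, B, n_perm: int = 999, seed: int | None = None, symmetrize_mode: str = "mean") -> MantelResult:
    """Permuted Mantel test between two dyadic matrices.

    r is the Pearson correlation of the unordered-dyad vectors (asymmetric
    matrices are symmetrized by the dyad mean first).  The null permutes
    the object labels of B — its rows and columns simultaneously; the
    two-tailed p counts permutations with |r_perm| >= |r_obs|, with the
    observed configuration included (+1 smoothing, so p is never 0).
    """
    a, b = _align(A, B)
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 individuals")
    a = symmetrize(a, symmetrize_mode)
    b = symmetrize(b, symmetrize_mode)
    iu = np.triu_indices(n, 1)
    va = a[iu]
    r_obs = _pearson(va, b[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(va, b[np.ix_(perm, perm)][iu])
        if abs(r_p) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p_two_tailed=p, n_permutations=n_perm, held_constant=None, n_dyads=len(va))


def partial_correlation(r_ab: float, r_ac: float, r_bc: float) -> float:
    """First-order partial correlation r_AB.C."""
    numer = r_ab - r_ac * r_bc
    denom = math_sqrt((1 - r_ac**2) * (1 - r_bc**2))
    if denom == 0:
        if abs(numer) < 1e-12:
            return 0.0  # e.g. A vs B given B itself: nothing left to correlate
        raise ValueError("partial correlation undefined: |r_AC| or |r_BC| is 1")
    return numer / denom


def math_sqrt(x: float) -> float:
    return float(np.sqrt(x))


def partial_mantel(
    A, B, C, n_perm: int = 999, seed: int | None = None, symmetrize_mode: str = "mean"
) -> MantelResult:
    """Permuted partial Mantel test of A vs B holding C constant.

    The statistic is the first-order partial correlation of the dyad
    vectors, r_AB.C = (r_AB - r_AC r_BC) / sqrt((1-r_AC^2)(1-r_BC^2));
    the null permutes B's labels, recomputing r_AB and r_BC per
    permutation.
    """
    a, b, c = _align(A, B, C)
    n = a.shape[0]
    if n < 4:
        raise ValueError("partial Mantel test needs at least 4 individuals")
    a = symmetrize(a, symmetrize_mode)
    b = symmetrize(b, symmetrize_mode)
    c = symmetrize(c, symmetrize_mode)
    iu = np.triu_indices(n, 1)
    va, vc = a[iu], c[iu]
    r_ac = _pearson(va, vc)
    vb = b[iu]
    r_obs = partial_correlation(_pearson(va, vb), r_ac, _pearson(vb, vc))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)][iu]
        r_p = partial_correlation(_pearson(va, bp), r_ac, _pearson(bp, vc))
        if abs(r_p) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    held = C.name if isinstance(C, ScoreMatrix) else "C"
    return MantelResult(r=r_obs, p_two_tailed=p, n_permutations=n_perm, held_constant=held, n_dyads=len(va))


def contact_pearson(acoustic, contact, symmetrize_mode: str = "mean") -> tuple[float, float, int]:
    """Pearson correlation restricted to dyads that had contact.

    Masks the unordered-dyad vectors to contact score > 0 and returns
    (r, two-tailed parametric p with n-2 d.f., number of dyads used).
    """
    va = vectorize_dyads(acoustic, symmetrize_mode)
    vc = vectorize_dyads(contact, symmetrize_mode)
    if len(va) != len(vc):
        raise ValueError("matrices differ in size")
    mask = vc > 0
    if mask.sum() < 3:
        raise ValueError("fewer than 3 dyads with contact > 0")
    r, p = stats.pearsonr(va[mask], vc[mask])
    return float(r), float(p), int(mask.sum())
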