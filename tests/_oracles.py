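"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: gene-dropping Monte
Carlo for pedigree kinship, residual-based partial correlation, and direct
sums-of-squares ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def gene_drop_kinship(ped_df: pd.DataFrame, n_reps: int, seed: int) -> tuple[pd.DataFrame, float]:
    """Monte-Carlo kinship by dropping alleles down the pedigree.

    Every founder receives two unique alleles; each offspring inherits one
    random allele from each parent, independently per replicate.  The
    kinship estimate for (i, j) is the fraction of replicates x allele
    pairs that are identical by descent.  Returns the matrix and the
    worst-case binomial standard error for phi = 0.5.
    """
    rng = np.random.default_rng(seed)
    rows = {str(r.id): r for r in ped_df.itertuples()}

    def parent(r, attr):
        v = getattr(r, attr)
        return None if pd.isna(v) or v == "" else str(v)

    alleles: dict[str, np.ndarray] = {}
    next_allele = [0]

    def founder_pair() -> np.ndarray:
        a = np.full((n_reps, 1), next_allele[0])
        b = np.full((n_reps, 1), next_allele[0] + 1)
        next_allele[0] += 2
        return np.hstack([a, b])

    remaining = list(rows)
    while remaining:
        progressed = []
        for ind in remaining:
            r = rows[ind]
            s, d = parent(r, "sire_id"), parent(r, "dam_id")
            deps = [p for p in (s, d) if p in rows]
            if any(p not in alleles for p in deps):
                continue
            if not deps:
                alleles[ind] = founder_pair()
            else:
                cols = []
                for p in (s, d):
                    if p in alleles:
                        pick = rng.integers(0, 2, n_reps)
                        cols.append(alleles[p][np.arange(n_reps), pick][:, None])
                    else:  # unknown parent: fresh founder gamete
                        cols.append(founder_pair()[:, :1])
                alleles[ind] = np.hstack(cols)
            progressed.append(ind)
        if not progressed:
            raise ValueError("pedigree cycle or missing records")
        remaining = [i for i in remaining if i not in progressed]

    ids = [str(i) for i in ped_df["id"]]
    n = len(ids)
    phi = np.zeros((n, n))
    for i in range(n):
        ai = alleles[ids[i]]
        for j in range(i, n):
            aj = alleles[ids[j]]
            # mean over the four allele-pair draws
            m = sum(
                (ai[:, a] == aj[:, b]).mean() for a in (0, 1) for b in (0, 1)
            ) / 4.0
            phi[i, j] = phi[j, i] = m
    se = np.sqrt(0.5 * 0.5 / n_reps)
    return pd.DataFrame(phi, index=ids, columns=ids), se


def partial_corr_residuals(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Partial correlation of a and b given c, via regression residuals."""
    X = np.column_stack([np.ones_like(c), c])
    ra = a - X @ np.linalg.lstsq(X, a, rcond=None)[0]
    rb = b - X @ np.linalg.lstsq(X, b, rcond=None)[0]
    return float(np.corrcoef(ra, rb)[0, 1])


def anova_f_bruteforce(samples: list[np.ndarray]) -> float:
    """One-way ANOVA F from explicit sums of squares."""
    allv = np.concatenate(samples)
    grand = allv.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    dfb = len(samples) - 1
    dfw = len(allv) - len(samples)
    return (ssb / dfb) / (ssw / dfw)
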