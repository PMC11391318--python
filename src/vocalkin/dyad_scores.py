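"""Dyadic score matrices over the individuals of a colony.

Four individual-by-individual matrices drive the accommodation analysis:

* **acoustic dissimilarity** — Euclidean distance between z-scored
  per-individual parameter medians, scaled to [0, 1] (0 = identical trills,
  1 = the most different pair observed);
* **genetic relatedness** — the autosomal kinship coefficient φ from the
  breeding-colony pedigree (0 = unrelated, 0.5 = a non-inbred individual
  with itself, above 0.5 under inbreeding);
* **social contact** — days a dyad shared a cage before the *focal*
  individual's recording, scaled to [0, 1]; directional, hence asymmetric,
  because dyad partners were recorded in different years;
* **body-weight dissimilarity** — computed like the acoustic score from
  median weekly body weights (a proxy for morphometry).

Scaling convention: distances and contact times are anchored at their
theoretical minimum 0 and divided by the maximal off-diagonal value, so a
score of 0 means exactly identical (or never co-housed) and 1 marks the
extreme observed dyad.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("vocalkin.dyad_scores")


@dataclass
class ScoreMatrix:
    """A named square matrix over an ordered set of individuals."""

    name: str
    ids: list[str]
    values: np.ndarray
    symmetric: bool = True
    value_range: str = "[0,1]"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("values must be square over ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, name: str, symmetric: bool = True) -> "ScoreMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(name=name, ids=list(df.index), values=df.to_numpy(), symmetric=symmetric)

    def subset(self, ids: list[str]) -> "ScoreMatrix":
        """Submatrix over ``ids`` (e.g. one sex), preserving the given order."""
        pos = {j: i for i, j in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return ScoreMatrix(
            name=self.name,
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            symmetric=self.symmetric,
            value_range=self.value_range,
        )


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _scale_to_unit(values: np.ndarray, what: str) -> np.ndarray:
    """Scale off-diagonal entries by their maximum; 0 stays exactly 0."""
    n = values.shape[0]
    mask = _offdiag_mask(n)
    top = values[mask].max() if n > 1 else 0.0
    if top <= 0:
        warnings.warn(f"{what}: all off-diagonal values are zero; left unscaled")
        return values
    out = values / top
    return out


# ---------------------------------------------------------------------------
# acoustic dissimilarity
# ---------------------------------------------------------------------------

def individual_medians(features: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-individual median of each acoustic parameter.

    ``features`` carries one row per call with an ``individual_id`` column;
    every other numeric column is treated as a parameter unless ``columns``
    restricts the set.
    """
    if "individual_id" not in features.columns:
        raise ValueError("features table needs an individual_id column")
    if columns is None:
        columns = [
            c
            for c in features.columns
            if c not in ("individual_id", "call_id", "sex", "date")
            and pd.api.types.is_numeric_dtype(features[c])
        ]
    return features.groupby("individual_id", sort=True)[columns].median()


def acoustic_dissimilarity(medians: pd.DataFrame, name: str = "acoustic") -> ScoreMatrix:
    """Pairwise acoustic dissimilarity from per-individual parameter medians.

    Parameters are z-scored across individuals (constant parameters are
    dropped with a warning), pairwise Euclidean distances computed and the
    matrix scaled to [0, 1].
    """
    if len(medians) < 3:
        raise ValueError("need at least 3 individuals for a scaled dissimilarity matrix")
    sds = medians.std(axis=0, ddof=1)
    constant = list(sds.index[(sds == 0) | sds.isna()])
    if constant:
        warnings.warn(f"dropping constant parameters (z-score undefined): {constant}")
        medians = medians.drop(columns=constant)
        sds = sds.drop(index=constant)
    z = (medians - medians.mean(axis=0)) / sds
    dist = squareform(pdist(z.to_numpy(), metric="euclidean"))
    scaled = _scale_to_unit(dist, "acoustic dissimilarity")
    return ScoreMatrix(name=name, ids=[str(i) for i in medians.index], values=scaled)


# ---------------------------------------------------------------------------
# pedigree kinship
# ---------------------------------------------------------------------------

def _pedigree_frame(pedigree) -> pd.DataFrame:
    """Accept a Pedigree object or a DataFrame with id/sire_id/dam_id."""
    if hasattr(pedigree, "to_frame"):
        df = pedigree.to_frame()
    else:
        df = pd.DataFrame(pedigree)
    for col in ("id", "sire_id", "dam_id"):
        if col not in df.columns:
            raise ValueError(f"pedigree needs column {col!r}")
    return df


def _topological_order(df: pd.DataFrame) -> list[str]:
    """Order ids so every parent precedes its offspring; error on cycles."""
    parents = {
        str(r.id): [p for p in (r.sire_id, r.dam_id) if pd.notna(p) and p != ""]
        for r in df.itertuples()
    }
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        if state.get(node) == 2:
            return
        if state.get(node) == 1:
            raise ValueError(f"pedigree cycle involving {node!r}")
        state[node] = 1
        for p in parents.get(node, []):
            if str(p) in parents:
                visit(str(p))
        state[node] = 2
        order.append(node)

    for node in parents:
        visit(node)
    return order


def kinship_matrix(pedigree, name: str = "kinship") -> ScoreMatrix:
    """Autosomal kinship coefficients φ by the recursive pedigree algorithm.

    φ(i, j) is the probability that alleles drawn at random from i and j at
    an autosomal locus are identical by descent.  Founders (and unknown
    parents) are treated as unrelated and non-inbred, so φ(i, i) = 0.5 for a
    non-inbred individual, φ = 0.25 for parent–offspring and full siblings,
    and self-kinship exceeds 0.5 under inbreeding.  Processing is in
    topological order:

        φ(i, i) = ½ (1 + φ(sire_i, dam_i))
        φ(i, j) = ½ (φ(sire_i, j) + φ(dam_i, j))   for j processed before i
    """
    df = _pedigree_frame(pedigree)
    df = df.assign(id=df["id"].astype(str))
    order = _topological_order(df)
    pos = {ind: k for k, ind in enumerate(order)}
    sire = {}
    dam = {}
    for r in df.itertuples():
        sire[str(r.id)] = str(r.sire_id) if pd.notna(r.sire_id) and r.sire_id != "" else None
        dam[str(r.id)] = str(r.dam_id) if pd.notna(r.dam_id) and r.dam_id != "" else None
    n = len(order)
    K = np.zeros((n, n))

    def phi(a: str | None, b: str | None) -> float:
        if a is None or b is None or a not in pos or b not in pos:
            return 0.0
        return K[pos[a], pos[b]]

    for k, ind in enumerate(order):
        s, d = sire[ind], dam[ind]
        K[k, k] = 0.5 * (1.0 + phi(s, d))
        for j in range(k):
            other = order[j]
            K[k, j] = K[j, k] = 0.5 * (phi(s, other) + phi(d, other))

    # return in the pedigree's own id order
    ids = list(df["id"])
    idx = np.array([pos[i] for i in ids])
    return ScoreMatrix(
        name=name,
        ids=ids,
        values=K[np.ix_(idx, idx)],
        symmetric=True,
        value_range="[0,0.5+]",
    )


def relationship_matrix(kinship: ScoreMatrix) -> np.ndarray:
    """Numerator relationship matrix A = 2φ (unit diagonal for non-inbred)."""
    return 2.0 * kinship.values


# ---------------------------------------------------------------------------
# social contact
# ---------------------------------------------------------------------------

def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def cohousing_days(
    housing: pd.DataFrame, id_a: str, id_b: str, before: dt.date
) -> int:
    """Whole days ``id_a`` and ``id_b`` shared a cage strictly before ``before``.

    Partial days count as one day; an interval day d contributes when
    start ≤ d ≤ end and d < before.
    """
    total = 0
    ha = housing[housing["individual_id"].astype(str) == str(id_a)]
    hb = housing[housing["individual_id"].astype(str) == str(id_b)]
    for ra in ha.itertuples():
        for rb in hb.itertuples():
            if str(ra.cage_id) != str(rb.cage_id):
                continue
            start = max(_as_date(ra.start_date), _as_date(rb.start_date))
            end = min(_as_date(ra.end_date), _as_date(rb.end_date))
            end = min(end, before - dt.timedelta(days=1))
            days = (end - start).days + 1
            if days > 0:
                total += days
    return total


def social_contact_matrix(
    housing: pd.DataFrame,
    recording_dates: pd.Series | dict,
    normalize: bool = True,
    name: str = "contact",
) -> ScoreMatrix:
    """Directional social contact scores.

    Entry [i, j] is the number of days i and j were co-housed before i's
    recording date, scaled so the maximal dyad scores 1 ("always together")
    and a never-co-housed dyad scores 0.  Because dyad partners were
    recorded on different dates the matrix is generally asymmetric; the
    diagonal is set to 1 by convention and excluded from all analyses.
    """
    rec = {str(k): _as_date(v) for k, v in dict(recording_dates).items()}
    ids = sorted(rec)
    missing = set(housing["individual_id"].astype(str)) - set(ids)
    if missing:
        raise ValueError(f"missing recording date for: {sorted(missing)}")
    n = len(ids)
    raw = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            raw[i, j] = cohousing_days(housing, a, b, before=rec[a])
    values = _scale_to_unit(raw, "social contact") if normalize else raw
    np.fill_diagonal(values, 1.0 if normalize else 0.0)
    return ScoreMatrix(name=name, ids=ids, values=values, symmetric=False)


# ---------------------------------------------------------------------------
# body weight dissimilarity
# ---------------------------------------------------------------------------

def weight_dissimilarity(
    weights: pd.DataFrame,
    recording_dates: pd.Series | dict,
    name: str = "weight",
) -> ScoreMatrix:
    """Body-weight dissimilarity from weekly weighings.

    For each individual the median weight over the calendar year of its
    recording is taken, medians are z-scored and absolute pairwise
    differences scaled to [0, 1] — the same construction as the acoustic
    score, with body weight standing in for morphometry.
    """
    rec = {str(k): _as_date(v) for k, v in dict(recording_dates).items()}
    ids = sorted(rec)
    w = weights.assign(individual_id=weights["individual_id"].astype(str))
    medians = {}
    for ind in ids:
        year = rec[ind].year
        rows = w[
            (w["individual_id"] == ind)
            & (pd.to_datetime(w["date"]).dt.year == year)
        ]
        if rows.empty:
            raise ValueError(f"no weights for {ind!r} in reference year {year}")
        medians[ind] = float(rows["grams"].median())
    vals = np.array([medians[i] for i in ids])
    sd = vals.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(vals)
    else:
        z = (vals - vals.mean()) / sd
    diff = np.abs(z[:, None] - z[None, :])
    return ScoreMatrix(name=name, ids=ids, values=_scale_to_unit(diff, "weight dissimilarity"))
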