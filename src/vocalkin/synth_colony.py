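"""Synthetic breeding-colony generator.

The accommodation analysis needs a colony's worth of linked records:
a pedigree, cage-housing intervals, weekly body weights, recording dates and
a trill feature table.  This module generates all of them with *known*
signature and accommodation structure so the downstream statistics can be
validated against ground truth.

The default configuration emulates the study conditions: 36 focal adults
(22 females, 14 males) contributing 482 trills in total, females housed with
matrilineal kin, males housed mostly with non-kin, recordings spread over a
nine-year window so the contact matrix is asymmetric.

Generative model of a call's 29-parameter feature vector (on a standardised
latent scale, mapped affinely to physical units):

    y_call = mu + beta_sex * male + b_individual + contact_shift + eps

* ``b_individual`` — per-individual baseline offsets, multivariate normal
  across individuals with covariance ``sigma_individual^2 *
  [(1 - beta_kin) I + beta_kin A]`` where A = 2 phi is the (unit-diagonal
  normalised) pedigree relationship matrix — so ``beta_kin`` in [0, 1] sets
  how strongly kin share acoustic baselines;
* ``contact_shift`` — the accommodation term: each individual's calls move
  along the direction away from (``beta_contact`` > 0, divergence) or toward
  (``beta_contact`` < 0, convergence) its cage partners' baselines,
  proportionally to the normalised social-contact score, computed with the
  very same contact definition the estimation side uses;
* ``eps`` — call-level noise, N(0, sigma_call^2) i.i.d. per parameter.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dyad_scores import kinship_matrix, social_contact_matrix
from .trill_signal import FEATURE_COLUMNS

N_PARAMS = len(FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # "F" or "M"
    birth_date: dt.date
    sire_id: str | None = None
    dam_id: str | None = None


class Pedigree:
    """An acyclic set of individuals with parent links."""

    def __init__(self, individuals: list[Individual]):
        self.individuals = list(individuals)
        self._by_id = {i.id: i for i in self.individuals}
        self.validate()

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def validate(self) -> None:
        if len(self._by_id) != len(self.individuals):
            raise ValueError("duplicate individual ids in pedigree")
        for ind in self.individuals:
            for pid, want_sex in ((ind.sire_id, "M"), (ind.dam_id, "F")):
                if pid is None:
                    continue
                if pid not in self._by_id:
                    continue  # unknown parent treated as founder elsewhere
                parent = self._by_id[pid]
                if parent.sex != want_sex:
                    raise ValueError(f"{ind.id}: parent {pid} has wrong sex")
                if ind.birth_date <= parent.birth_date:
                    raise ValueError(f"{ind.id}: born before parent {pid}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "sire_id": [i.sire_id for i in self.individuals],
                "dam_id": [i.dam_id for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "birth_date": [i.birth_date.isoformat() for i in self.individuals],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        inds = []
        for r in df.itertuples():
            inds.append(
                Individual(
                    id=str(r.id),
                    sex=str(r.sex),
                    birth_date=pd.Timestamp(r.birth_date).date(),
                    sire_id=None if pd.isna(r.sire_id) or r.sire_id == "" else str(r.sire_id),
                    dam_id=None if pd.isna(r.dam_id) or r.dam_id == "" else str(r.dam_id),
                )
            )
        return cls(inds)


@dataclass(frozen=True)
class HousingInterval:
    individual_id: str
    cage_id: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self):
        if self.end_date < self.start_date:
            raise ValueError("housing interval ends before it starts")


@dataclass
class EffectConfig:
    """Tunable effect structure of the synthetic feature generator.

    All effect sizes act on the standardised latent scale of the 29 acoustic
    parameters (one latent s.d. corresponds to one physical scale unit of
    the parameter).
    """

    sigma_individual: float = 1.0
    sigma_call: float = 0.6
    beta_sex: np.ndarray | float | None = None  # default: 0.8 on 15 of 29 params
    beta_kin: float = 0.5
    beta_contact: float | dict = 0.0  # scalar, or {"F": ..., "M": ...}
    n_individuals_f: int = 22
    n_individuals_m: int = 14
    calls_per_individual: int | None = None  # None: distribute n_calls_total
    n_calls_total: int = 482
    min_calls_per_individual: int = 6
    syllables_range: tuple[int, int] = (5, 28)
    female_kin_bias: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_individual < 0 or self.sigma_call < 0:
            raise ValueError("sigmas must be non-negative")
        lo, hi = self.syllables_range
        if not (1 <= lo <= hi <= 30):
            raise ValueError("syllables_range must lie within [1, 30]")
        if not (0.0 <= self.beta_kin <= 1.0):
            raise ValueError("beta_kin is a correlation weight in [0, 1]")

    def contact_coefficient(self, sex: str) -> float:
        """Accommodation coefficient for one sex (negative = convergence)."""
        if isinstance(self.beta_contact, dict):
            return float(self.beta_contact.get(sex, 0.0))
        return float(self.beta_contact)

    def sex_offsets(self) -> np.ndarray:
        """Additive latent offset applied to males, per parameter."""
        if self.beta_sex is None:
            # moderate sex effect on roughly half the parameters
            v = np.zeros(N_PARAMS)
            v[::2] = 0.8
            return v
        if np.isscalar(self.beta_sex):
            return np.full(N_PARAMS, float(self.beta_sex))
        v = np.asarray(self.beta_sex, dtype=float)
        if v.shape != (N_PARAMS,):
            raise ValueError(f"beta_sex must be scalar or length {N_PARAMS}")
        return v

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["beta_sex"], np.ndarray):
            d["beta_sex"] = d["beta_sex"].tolist()
        d["syllables_range"] = list(d["syllables_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EffectConfig":
        d = dict(d)
        if d.get("beta_sex") is not None and not np.isscalar(d["beta_sex"]):
            d["beta_sex"] = np.asarray(d["beta_sex"], dtype=float)
        if "syllables_range" in d:
            d["syllables_range"] = tuple(d["syllables_range"])
        return cls(**d)


@dataclass
class ColonyDataset:
    """Everything the pipeline consumes, linked by individual and call ids."""

    individuals: pd.DataFrame  # id, sex, birth_date (focal adults)
    pedigree: Pedigree  # focal adults plus ancestors
    housing: pd.DataFrame  # individual_id, cage_id, start_date, end_date
    weights: pd.DataFrame  # individual_id, date, grams
    recordings: pd.DataFrame  # call_id, individual_id, date
    features: pd.DataFrame  # call_id index; individual_id, sex + 29 params

    def recording_dates(self) -> pd.Series:
        """One recording date per focal individual."""
        return (
            self.recordings.groupby("individual_id")["date"].first().astype(str)
        )

    def validate(self) -> None:
        ids = set(self.individuals["id"].astype(str))
        rec_ids = set(self.recordings["individual_id"].astype(str))
        if not rec_ids <= ids:
            raise ValueError("recording refers to unknown individual")
        if not set(self.features.index) <= set(self.recordings["call_id"]):
            raise ValueError("feature row without a recording")


# ---------------------------------------------------------------------------
# physical scale of the 29 parameters
# ---------------------------------------------------------------------------

def _physical_scale() -> tuple[np.ndarray, np.ndarray]:
    """Affine map (mu, scale) from the latent scale to physical units.

    Magnitudes are chosen to resemble published trill statistics: whole
    calls of roughly a second, syllables of tens of milliseconds, F0 in the
    ultrasonic 15–30 kHz band.
    """
    mu = {}
    scale = {}
    mu["trill_duration_s"], scale["trill_duration_s"] = 1.1, 0.25
    mu["n_syllables"], scale["n_syllables"] = 16.0, 4.0
    f0_mu = {
        "startF0": 24_000.0,
        "endF0": 19_000.0,
        "minF0": 17_000.0,
        "maxF0": 26_000.0,
        "meanF0": 21_500.0,
        "rangeF0": 9_000.0,
    }
    for k in ("F", "M", "E"):
        mu[f"duration_{k}"], scale[f"duration_{k}"] = 0.05, 0.012
        for p, m in f0_mu.items():
            mu[f"{p}_{k}"], scale[f"{p}_{k}"] = m, 1_500.0
        for p in ("timeminF0", "timemaxF0"):
            mu[f"{p}_{k}"], scale[f"{p}_{k}"] = 0.5, 0.15
    return (
        np.array([mu[c] for c in FEATURE_COLUMNS]),
        np.array([scale[c] for c in FEATURE_COLUMNS]),
    )


MU_PHYS, SCALE_PHYS = _physical_scale()


# ---------------------------------------------------------------------------
# pedigree generation
# ---------------------------------------------------------------------------

def generate_pedigree(
    n_founders: int,
    n_generations: int,
    seed: int,
    litter_range: tuple[int, int] = (1, 3),
    base_year: int = 1994,
) -> Pedigree:
    """Random breeding pedigree: founders plus ``n_generations`` of matings.

    Founders alternate sexes so both are always present; each generation,
    every adult female is bred to a random adult male with probability 0.8
    and bears 1–3 offspring of random sex.  Deterministic under ``seed``.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders (one of each sex)")
    rng = np.random.default_rng(seed)
    inds: list[Individual] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:03d}"

    for k in range(n_founders):
        inds.append(
            Individual(
                id=new_id(),
                sex="F" if k % 2 == 0 else "M",
                birth_date=dt.date(base_year, 1 + int(rng.integers(0, 12)), 1 + int(rng.integers(0, 28))),
            )
        )
    for g in range(1, n_generations + 1):
        year = base_year + 2 * g
        dams = [i for i in inds if i.sex == "F" and i.birth_date.year < year]
        sires = [i for i in inds if i.sex == "M" and i.birth_date.year < year]
        if not dams or not sires:
            break
        for dam in dams:
            if rng.random() > 0.8:
                continue
            sire = sires[int(rng.integers(0, len(sires)))]
            for _ in range(int(rng.integers(litter_range[0], litter_range[1] + 1))):
                inds.append(
                    Individual(
                        id=new_id(),
                        sex="F" if rng.random() < 0.5 else "M",
                        birth_date=dt.date(year, 1 + int(rng.integers(0, 12)), 1 + int(rng.integers(0, 28))),
                        sire_id=sire.id,
                        dam_id=dam.id,
                    )
                )
    return Pedigree(inds)


def _grow_to_counts(ped: Pedigree, n_f: int, n_m: int, rng: np.random.Generator) -> Pedigree:
    """Breed extra offspring of forced sex until the colony has enough adults."""
    inds = list(ped.individuals)
    counter = len(inds)
    last_year = max(i.birth_date.year for i in inds)
    for sex, need in (("F", n_f), ("M", n_m)):
        have = sum(1 for i in inds if i.sex == sex)
        while have < need:
            dams = [i for i in inds if i.sex == "F" and i.birth_date.year < last_year + 2]
            sires = [i for i in inds if i.sex == "M" and i.birth_date.year < last_year + 2]
            dam = dams[int(rng.integers(0, len(dams)))]
            sire = sires[int(rng.integers(0, len(sires)))]
            counter += 1
            inds.append(
                Individual(
                    id=f"I{counter:03d}",
                    sex=sex,
                    birth_date=dt.date(last_year + 2, 1 + int(rng.integers(0, 12)), 1),
                    sire_id=sire.id,
                    dam_id=dam.id,
                )
            )
            have += 1
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# housing generation
# ---------------------------------------------------------------------------

def _first_degree(ped: Pedigree, a: str, b: str) -> bool:
    """Parent-offspring or (half/full) sibling link between a and b."""
    ia, ib = ped[a], ped[b]
    if a in (ib.sire_id, ib.dam_id) or b in (ia.sire_id, ia.dam_id):
        return True
    shared = False
    if ia.sire_id is not None and ia.sire_id == ib.sire_id:
        shared = True
    if ia.dam_id is not None and ia.dam_id == ib.dam_id:
        shared = True
    return shared


def generate_housing(
    pedigree: Pedigree,
    female_kin_bias: float,
    seed: int,
    focal_ids: list[str] | None = None,
    epochs: tuple[tuple[str, str], ...] = (
        ("2003-01-01", "2005-12-31"),
        ("2006-01-01", "2009-06-30"),
    ),
) -> list[HousingInterval]:
    """Assign adults to same-sex cages of 2–3 over one or more housing epochs.

    With probability ``female_kin_bias`` a female cage is seeded from a
    first-degree kin pair (matrilineal housing); otherwise cages are filled
    at random.  Male cages are always random draws, which on a typical
    pedigree makes most male cage mates unrelated.  Interval lengths vary
    within each epoch so co-housing times differ across dyads.
    """
    rng = np.random.default_rng(seed)
    ids = focal_ids if focal_ids is not None else [i.id for i in pedigree.individuals]
    females = [i for i in ids if pedigree[i].sex == "F"]
    males = [i for i in ids if pedigree[i].sex == "M"]
    intervals: list[HousingInterval] = []
    cage_counter = 0

    def form_cages(pool: list[str], kin_bias: float) -> list[list[str]]:
        pool = list(pool)
        rng.shuffle(pool)
        cages: list[list[str]] = []
        while len(pool) >= 2:
            cage = []
            if kin_bias > 0 and rng.random() < kin_bias:
                # seed with a first-degree kin pair if one exists in the pool
                found = None
                for a in pool:
                    for b in pool:
                        if a != b and _first_degree(pedigree, a, b):
                            found = (a, b)
                            break
                    if found:
                        break
                if found:
                    cage = [found[0], found[1]]
                    pool.remove(found[0])
                    pool.remove(found[1])
            if not cage:
                cage = [pool.pop(), pool.pop()]
            # sometimes a third cage mate
            if pool and (len(pool) == 1 or rng.random() < 0.35):
                cage.append(pool.pop())
            cages.append(cage)
        return cages

    for e_start, e_end in epochs:
        es, ee = dt.date.fromisoformat(e_start), dt.date.fromisoformat(e_end)
        span = (ee - es).days
        for pool, bias in ((females, female_kin_bias), (males, 0.0)):
            for cage in form_cages(pool, bias):
                cage_counter += 1
                start = es + dt.timedelta(days=int(rng.integers(0, max(span // 4, 1))))
                length = int(rng.integers(max(span // 3, 30), span + 1))
                end = min(start + dt.timedelta(days=length), ee)
                for ind in cage:
                    intervals.append(
                        HousingInterval(
                            individual_id=ind,
                            cage_id=f"C{cage_counter:03d}",
                            start_date=start,
                            end_date=end,
                        )
                    )
    return intervals


def housing_to_frame(intervals: list[HousingInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [h.individual_id for h in intervals],
            "cage_id": [h.cage_id for h in intervals],
            "start_date": [h.start_date.isoformat() for h in intervals],
            "end_date": [h.end_date.isoformat() for h in intervals],
        }
    )


# ---------------------------------------------------------------------------
# feature generation
# ---------------------------------------------------------------------------

def _kin_correlated_baselines(
    ped_frame: pd.DataFrame,
    focal_ids: list[str],
    cfg: EffectConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-individual latent baselines with covariance (1-b) I + b A, A = 2 phi."""
    n = len(focal_ids)
    if cfg.sigma_individual == 0:
        return np.zeros((n, N_PARAMS))
    kin = kinship_matrix(ped_frame).subset(focal_ids)
    A = 2.0 * kin.values
    d = np.sqrt(np.diag(A))
    A_norm = A / np.outer(d, d)  # unit diagonal even under inbreeding
    cov = (1.0 - cfg.beta_kin) * np.eye(n) + cfg.beta_kin * A_norm
    L = np.linalg.cholesky(cov + 1e-9 * np.eye(n))
    z = rng.standard_normal((n, N_PARAMS))
    return cfg.sigma_individual * (L @ z)


def generate_trill_features(
    colony: "ColonyDataset",
    cfg: EffectConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Feature table for every recorded call under the configured effects.

    See the module docstring for the generative model.  The latent vectors
    are mapped to physical units; the syllable count is rounded and clipped
    to ``cfg.syllables_range`` and the relative time positions to [0, 1].
    """
    if colony.recordings.empty:
        raise ValueError("colony has no recordings")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    focal_ids = [str(i) for i in colony.individuals["id"]]
    sex = dict(zip(colony.individuals["id"].astype(str), colony.individuals["sex"]))
    pos = {ind: k for k, ind in enumerate(focal_ids)}

    baselines = _kin_correlated_baselines(colony.pedigree.to_frame(), focal_ids, cfg, rng)

    # accommodation shift shares the estimator's contact definition
    shift = np.zeros_like(baselines)
    betas = {s: cfg.contact_coefficient(s) for s in ("F", "M")}
    if any(b != 0.0 for b in betas.values()):
        contact = social_contact_matrix(colony.housing, colony.recording_dates())
        C = contact.subset(focal_ids).values.copy()
        np.fill_diagonal(C, 0.0)
        for i, ind_id in enumerate(focal_ids):
            beta = betas[sex[ind_id]]
            if beta == 0.0:
                continue
            partners = np.where(C[i] > 0)[0]
            if len(partners) == 0:
                continue
            # per-partner pull; a convergence pull is bounded at -0.5 so the
            # dyad meets in the middle instead of overshooting past it
            w = np.maximum(beta * C[i, partners], -0.5)
            away = (baselines[i] - baselines[partners]) * w[:, None]
            shift[i] = away.sum(axis=0) / len(partners)

    beta_sex = cfg.sex_offsets()
    rows = {}
    meta = {}
    for r in colony.recordings.itertuples():
        ind = str(r.individual_id)
        k = pos[ind]
        latent = baselines[k] + shift[k]
        if sex[ind] == "M":
            latent = latent + beta_sex
        latent = latent + cfg.sigma_call * rng.standard_normal(N_PARAMS)
        phys = MU_PHYS + SCALE_PHYS * latent
        rows[str(r.call_id)] = phys
        meta[str(r.call_id)] = (ind, sex[ind])

    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_COLUMNS))
    df.index.name = "call_id"
    lo, hi = cfg.syllables_range
    df["n_syllables"] = np.clip(np.round(df["n_syllables"]), lo, hi)
    for k in ("F", "M", "E"):
        for p in ("timeminF0", "timemaxF0"):
            df[f"{p}_{k}"] = np.clip(df[f"{p}_{k}"], 0.0, 1.0)
        df[f"rangeF0_{k}"] = np.abs(df[f"rangeF0_{k}"])
    df.insert(0, "individual_id", [meta[c][0] for c in df.index])
    df.insert(1, "sex", [meta[c][1] for c in df.index])
    return df


# ---------------------------------------------------------------------------
# the full colony
# ---------------------------------------------------------------------------

def _select_focals(ped: Pedigree, n_f: int, n_m: int, rng: np.random.Generator) -> list[str]:
    """Pick focal adults: whole matrilines of females, males from many dams."""
    females = [i for i in ped.individuals if i.sex == "F"]
    males = [i for i in ped.individuals if i.sex == "M"]
    # group females by matriline root (follow dam links to a founder)
    def matriline(ind: Individual) -> str:
        cur = ind
        while cur.dam_id is not None and cur.dam_id in ped:
            cur = ped[cur.dam_id]
        return cur.id

    lines: dict[str, list[str]] = {}
    for f in females:
        lines.setdefault(matriline(f), []).append(f.id)
    chosen_f: list[str] = []
    for root in sorted(lines, key=lambda r: -len(lines[r])):
        for fid in lines[root]:
            if len(chosen_f) < n_f:
                chosen_f.append(fid)
    if len(chosen_f) < n_f:
        raise ValueError("pedigree does not contain enough females")
    # males: spread over dams so most cage mates end up unrelated
    by_dam: dict[str, list[str]] = {}
    for m in males:
        by_dam.setdefault(m.dam_id or m.id, []).append(m.id)
    chosen_m: list[str] = []
    dams_order = sorted(by_dam)
    rng.shuffle(dams_order)
    while len(chosen_m) < n_m:
        progressed = False
        for damid in dams_order:
            if by_dam[damid] and len(chosen_m) < n_m:
                chosen_m.append(by_dam[damid].pop(0))
                progressed = True
        if not progressed:
            raise ValueError("pedigree does not contain enough males")
    return chosen_f + chosen_m


def generate_colony(cfg: EffectConfig | None = None) -> ColonyDataset:
    """Generate a complete synthetic colony dataset from an effect config."""
    cfg = cfg or EffectConfig()
    rng = np.random.default_rng(cfg.seed)
    ped = generate_pedigree(n_founders=12, n_generations=3, seed=int(rng.integers(2**31)))
    ped = _grow_to_counts(ped, cfg.n_individuals_f + 2, cfg.n_individuals_m + 2, rng)
    focal_ids = _select_focals(ped, cfg.n_individuals_f, cfg.n_individuals_m, rng)

    individuals = pd.DataFrame(
        {
            "id": focal_ids,
            "sex": [ped[i].sex for i in focal_ids],
            "birth_date": [ped[i].birth_date.isoformat() for i in focal_ids],
        }
    )

    housing = housing_to_frame(
        generate_housing(
            ped, cfg.female_kin_bias, seed=int(rng.integers(2**31)), focal_ids=focal_ids
        )
    )

    # one recording date per individual, spread over a nine-year window so
    # dyad partners can be recorded up to 9 years apart
    rec_dates = {}
    for ind in focal_ids:
        year = 2004 + int(rng.integers(0, 9))
        rec_dates[ind] = dt.date(year, 1 + int(rng.integers(0, 12)), 1 + int(rng.integers(0, 28)))

    # weekly weights covering each individual's recording year
    w_rows = []
    base_w = 85.0 + 12.0 * rng.standard_normal(len(focal_ids))
    for k, ind in enumerate(focal_ids):
        year = rec_dates[ind].year
        d = dt.date(year, 1, 3)
        while d.year == year:
            w_rows.append(
                {
                    "individual_id": ind,
                    "date": d.isoformat(),
                    "grams": round(float(base_w[k] + 4.0 * rng.standard_normal()), 1),
                }
            )
            d += dt.timedelta(days=7)
    weights = pd.DataFrame(w_rows)

    # call counts: fixed per individual, or n_calls_total distributed
    n = len(focal_ids)
    if cfg.calls_per_individual is not None:
        counts = np.full(n, int(cfg.calls_per_individual))
    else:
        base = cfg.min_calls_per_individual
        remainder = cfg.n_calls_total - base * n
        if remainder < 0:
            raise ValueError("n_calls_total too small for min_calls_per_individual")
        extra = rng.multinomial(remainder, np.full(n, 1.0 / n))
        counts = base + extra
    rec_rows = []
    call_no = 0
    for k, ind in enumerate(focal_ids):
        for _ in range(int(counts[k])):
            call_no += 1
            rec_rows.append(
                {
                    "call_id": f"T{call_no:04d}",
                    "individual_id": ind,
                    "date": rec_dates[ind].isoformat(),
                }
            )
    recordings = pd.DataFrame(rec_rows)

    colony = ColonyDataset(
        individuals=individuals,
        pedigree=ped,
        housing=housing,
        weights=weights,
        recordings=recordings,
        features=pd.DataFrame(),
    )
    colony.features = generate_trill_features(colony, cfg, rng)
    colony.validate()
    return colony


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_colony(colony: ColonyDataset, outdir, cfg: EffectConfig | None = None) -> None:
    """Write the colony tables as UTF-8 CSV (ISO-8601 dates) plus config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    colony.pedigree.to_frame().to_csv(out / "pedigree.csv", index=False)
    colony.individuals.to_csv(out / "individuals.csv", index=False)
    colony.housing.to_csv(out / "housing.csv", index=False)
    colony.weights.to_csv(out / "weights.csv", index=False)
    colony.recordings.to_csv(out / "recordings.csv", index=False)
    colony.features.to_csv(out / "features.csv")
    if cfg is not None:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)


def read_colony(indir) -> ColonyDataset:
    """Read a colony previously written with :func:`write_colony`."""
    d = Path(indir)
    colony = ColonyDataset(
        individuals=pd.read_csv(d / "individuals.csv", dtype={"id": str}),
        pedigree=Pedigree.from_frame(pd.read_csv(d / "pedigree.csv", dtype=str)),
        housing=pd.read_csv(d / "housing.csv", dtype={"individual_id": str, "cage_id": str}),
        weights=pd.read_csv(d / "weights.csv", dtype={"individual_id": str}),
        recordings=pd.read_csv(d / "recordings.csv", dtype={"call_id": str, "individual_id": str}),
        features=pd.read_csv(d / "features.csv", index_col="call_id", dtype={"individual_id": str}),
    )
    colony.validate()
    return colony
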