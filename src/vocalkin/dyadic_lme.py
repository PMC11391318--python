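"""Dyadic mixed-effects models and backward elimination.

The dyad is the analysis unit: every ordered within-sex pair of individuals
contributes one row with its acoustic dissimilarity (response), genetic
relatedness, social contact, body-weight dissimilarity and the recording
time difference in years.  The full model is

    acoustic ~ genetic * contact * weight + contact * time_difference
    random intercepts for both dyad members

fitted by maximising the log-likelihood (ML).  Both-member random
intercepts are implemented as crossed variance components (one component
per dyad position), the practical surrogate for a nested
individual1/individual2 specification.

Backward elimination removes, at each step, the highest-level interaction
with the highest non-significant p-value (never a main term, and never an
interaction still contained in a retained higher-order interaction).  After
each removal the reduced model is compared with its predecessor: the trace
records the Wald p of the dropped coefficient and a likelihood-ratio
chi-square between the two ML fits, and the elimination stops when (i) only
main terms remain, (ii) all remaining interactions are significant, or
(iii) the model comparison itself is significant (the dropped term mattered,
so the previous model is kept).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .dyad_scores import ScoreMatrix
from .synth_colony import Pedigree
from .synth_colony import _first_degree as first_degree

logger = logging.getLogger("vocalkin.dyadic_lme")

ALPHA = 0.05

MAIN_TERMS = ["genetic_relatedness", "social_contact", "body_weight", "time_difference"]
FULL_INTERACTIONS = [
    "genetic_relatedness:social_contact",
    "genetic_relatedness:body_weight",
    "social_contact:body_weight",
    "genetic_relatedness:social_contact:body_weight",
    "social_contact:time_difference",
]


# ---------------------------------------------------------------------------
# dyad table
# ---------------------------------------------------------------------------

def build_dyad_table(
    acoustic: ScoreMatrix,
    genetic: ScoreMatrix,
    contact: ScoreMatrix,
    weight: ScoreMatrix,
    recording_years: dict | pd.Series,
    pedigree: Pedigree | None = None,
    sex: str | None = None,
) -> pd.DataFrame:
    """One row per ordered (directed) dyad of the matrices' individuals.

    The directed layout keeps the asymmetric contact score: row (i, j)
    carries contact[i, j], the co-housing time before i's recording.  The
    time difference is recording year of individual 1 minus that of
    individual 2.  Socialized dyads (contact > 0 in either direction) are
    categorised as ``parent_sibling`` when first-degree related, else as
    ``female_dyad``/``male_dyad``; non-socialized dyads carry no category.
    """
    ids = acoustic.ids
    for m in (genetic, contact, weight):
        if m.ids != ids:
            raise ValueError(f"matrix {m.name!r} ids do not match acoustic matrix")
    years = {str(k): int(v) for k, v in dict(recording_years).items()}
    missing = [i for i in ids if i not in years]
    if missing:
        raise ValueError(f"missing recording year for: {missing}")
    nonkin_label = {"F": "female_dyad", "M": "male_dyad"}.get(sex or "", "nonkin_dyad")
    rows = []
    n = len(ids)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = ids[i], ids[j]
            socialized = contact.values[i, j] > 0 or contact.values[j, i] > 0
            if socialized:
                if pedigree is not None and a in pedigree and b in pedigree and first_degree(pedigree, a, b):
                    rel = "parent_sibling"
                else:
                    rel = nonkin_label
            else:
                rel = None
            rows.append(
                {
                    "individual1": a,
                    "individual2": b,
                    "sex": sex,
                    "acoustic_dissimilarity": acoustic.values[i, j],
                    "genetic_relatedness": genetic.values[i, j],
                    "social_contact": contact.values[i, j],
                    "body_weight": weight.values[i, j],
                    "time_difference": years[a] - years[b],
                    "dyad_relationship": rel,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class LMEFit:
    """A fitted dyadic mixed model."""

    terms: pd.DataFrame  # index term; estimate, se, t, df, p
    fixed_terms: list[str]
    log_likelihood: float
    n_obs: int
    n_fixed: int
    random_structure: str
    converged: bool
    formula: str

    @property
    def df_resid(self) -> int:
        # single residual-d.f. convention: dyads minus fixed effects
        return self.n_obs - self.n_fixed


def _fit_mixed(
    data: pd.DataFrame, response: str, fixed_terms: list[str]
) -> LMEFit:
    """Fit response ~ fixed_terms with crossed dyad-member random intercepts."""
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"{response} ~ {rhs}"
    df = data.copy()
    df["_all"] = 1
    vc = {
        "ind1": "0 + C(individual1)",
        "ind2": "0 + C(individual2)",
    }
    random_structure = "crossed intercepts individual1 + individual2"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups="_all", vc_formula=vc, re_formula="0")
            fit = model.fit(reml=False, method=["lbfgs", "cg"])
            converged = bool(fit.converged)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("crossed-components fit failed (%s); simplified structure", exc)
            model = smf.mixedlm(formula, df, groups="individual1")
            fit = model.fit(reml=False)
            random_structure = "random intercept individual1 (fallback)"
            converged = bool(fit.converged)
    fe_names = list(model.exog_names)
    n_obs = len(df)
    n_fixed = len(fe_names)
    df_resid = max(n_obs - n_fixed, 1)
    rows = []
    for name in fe_names:
        est = float(fit.params[name])
        se = float(fit.bse[name])
        t = est / se if se > 0 else np.nan
        p = 2 * float(stats.t.sf(abs(t), df_resid)) if np.isfinite(t) else np.nan
        rows.append({"term": name, "estimate": est, "se": se, "t": t, "df": df_resid, "p": p})
    return LMEFit(
        terms=pd.DataFrame(rows).set_index("term"),
        fixed_terms=list(fixed_terms),
        log_likelihood=float(fit.llf),
        n_obs=n_obs,
        n_fixed=n_fixed,
        random_structure=random_structure,
        converged=converged,
        formula=formula,
    )


def fit_full_model(table: pd.DataFrame, response: str = "acoustic_dissimilarity") -> LMEFit:
    """Fit the full dyadic model (4 mains, 4 interactions, intercept).

    Fixed effects: genetic * contact * weight expanded (3 mains, 3 two-way,
    1 three-way) plus time_difference and contact x time_difference.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 dyads")
    for col in MAIN_TERMS:
        if table[col].nunique() < 2:
            raise ValueError(f"predictor {col} is constant")
    return _fit_mixed(table, response, MAIN_TERMS + FULL_INTERACTIONS)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

@dataclass
class EliminationStep:
    removed_term: str
    term_p: float
    wald_p: float
    lr_stat: float
    lr_df: int
    lr_p: float


@dataclass
class EliminationTrace:
    steps: list[EliminationStep] = field(default_factory=list)
    stopping_rule: str = ""


def _order(term: str) -> int:
    return term.count(":") + 1


def _removable(terms: list[str]) -> list[str]:
    """Interactions not contained in a higher-order interaction still present."""
    inter = [t for t in terms if ":" in t]
    out = []
    for t in inter:
        parts = set(t.split(":"))
        nested = any(
            parts < set(o.split(":")) for o in inter if o != t
        )
        if not nested:
            out.append(t)
    return out


def backward_eliminate(
    table: pd.DataFrame,
    response: str = "acoustic_dissimilarity",
    alpha: float = ALPHA,
    full_fit: LMEFit | None = None,
) -> tuple[LMEFit, EliminationTrace]:
    """Backward elimination to the minimum adequate dyadic model.

    Repeatedly drops the highest-level removable interaction with the
    highest non-significant p-value, validating each reduction by a
    likelihood-ratio test between the nested ML fits (plus the Wald p of
    the dropped coefficient, both recorded in the trace).  Main terms are
    never removed.  Stops under the three rules documented in the module
    docstring.
    """
    current = full_fit if full_fit is not None else fit_full_model(table, response)
    trace = EliminationTrace()
    while True:
        candidates = _removable(current.fixed_terms)
        if not candidates:
            trace.stopping_rule = "main-terms-only"
            return current, trace
        pvals = {}
        for t in candidates:
            if t in current.terms.index:
                pvals[t] = float(current.terms.loc[t, "p"])
            else:  # patsy may reorder factors inside the term name
                match = [
                    ix for ix in current.terms.index
                    if ":" in ix and set(ix.split(":")) == set(t.split(":"))
                ]
                pvals[t] = float(current.terms.loc[match[0], "p"])
        nonsig = {t: p for t, p in pvals.items() if not (p < alpha)}
        if not nonsig:
            trace.stopping_rule = "significant-interactions"
            return current, trace
        top_order = max(_order(t) for t in nonsig)
        victim = max((t for t in nonsig if _order(t) == top_order), key=lambda t: nonsig[t])
        reduced_terms = [t for t in current.fixed_terms if t != victim]
        try:
            reduced = _fit_mixed(table, response, reduced_terms)
        except Exception as exc:  # halted elimination, annotated
            logger.warning("reduced model failed to fit: %s", exc)
            trace.stopping_rule = f"halted: reduced model failed ({exc})"
            return current, trace
        lr = max(2.0 * (current.log_likelihood - reduced.log_likelihood), 0.0)
        lr_df = max(current.n_fixed - reduced.n_fixed, 1)
        lr_p = float(stats.chi2.sf(lr, lr_df))
        step = EliminationStep(
            removed_term=victim,
            term_p=nonsig[victim],
            wald_p=nonsig[victim],
            lr_stat=lr,
            lr_df=lr_df,
            lr_p=lr_p,
        )
        if lr_p < alpha:
            trace.steps.append(step)
            trace.stopping_rule = "comparison-significant"
            return current, trace
        trace.steps.append(step)
        current = reduced


# ---------------------------------------------------------------------------
# dyad-relationship models
# ---------------------------------------------------------------------------

def dyad_relationship_lme(table: pd.DataFrame, score: str) -> LMEFit:
    """Mixed model of one dyad score on the dyad-relationship category.

    Restricted to socialized dyads; the categorical predictor contrasts
    first-degree (parent/sibling) dyads with unrelated same-sex dyads,
    controlling for both individuals of the dyad as random effects.
    ``score`` is one of acoustic_dissimilarity, genetic_relatedness,
    social_contact.
    """
    if score not in ("acoustic_dissimilarity", "genetic_relatedness", "social_contact"):
        raise ValueError(f"unknown score {score!r}")
    soc = table[table["dyad_relationship"].notna()].copy()
    cats = sorted(soc["dyad_relationship"].unique())
    if len(cats) < 2:
        raise ValueError(f"need >= 2 dyad-relationship categories, got {cats}")
    counts = soc["dyad_relationship"].value_counts()
    if (counts < 2).any():
        raise ValueError(f"every category needs >= 2 dyads: {counts.to_dict()}")
    return _fit_mixed(soc, score, ["C(dyad_relationship)"])
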