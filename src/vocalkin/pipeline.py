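"""End-to-end orchestration: data -> signatures -> scores -> inference -> models.

One call runs the whole analysis on a synthetic colony (simulate mode) or on
user-supplied CSV tables (real mode), per sex, and writes every intermediate
artifact plus report tables shaped like the study's result tables: the
final-LME coefficient table, the Mantel/partial-Mantel overview and the
contact-restricted correlations.  A provenance manifest (config, seeds,
package versions) makes a run reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .synth_colony import (
    ColonyDataset,
    EffectConfig,
    Pedigree,
    generate_colony,
    read_colony,
    write_colony,
)
from .trill_signal import FEATURE_COLUMNS
from .signature_stats import (
    beecher_hs,
    binomial_individual_tests,
    cohens_kappa,
    lda_loo,
    nested_pdfa,
    pca_kaiser,
    per_individual_anova,
    sex_difference_lmes,
)
from .dyad_scores import (
    ScoreMatrix,
    acoustic_dissimilarity,
    individual_medians,
    kinship_matrix,
    social_contact_matrix,
    weight_dissimilarity,
)
from .matrix_inference import contact_pearson, mantel, partial_mantel
from .dyadic_lme import backward_eliminate, build_dyad_table, dyad_relationship_lme

logger = logging.getLogger("vocalkin.pipeline")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"  # or "real"
    out_dir: str = "vocalkin_run"
    seed: int = 0
    effect: EffectConfig = field(default_factory=EffectConfig)
    input_dir: str | None = None  # real mode: colony CSV directory
    n_perm_mantel: int = 999
    n_perm_pdfa: int = 200
    n_selections_pdfa: int = 20
    per_sex: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect"] = self.effect.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "effect" in d and d["effect"] is not None:
            d["effect"] = EffectConfig.from_dict(d["effect"])
        return cls(**d)


@dataclass
class RunReport:
    """All headline outputs of a run, traceable to files in ``out_dir``."""

    signature_summary: pd.DataFrame  # per sex: DFA %, LOO %, kappa, H_s
    pdfa_sex: dict
    mantel_table: pd.DataFrame  # Table-2 shape: comparison x (r, p) per sex
    lme_tables: dict[str, pd.DataFrame]  # Table-1 shape per sex
    contact_correlations: pd.DataFrame
    manifest: dict
    warnings: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("data")
def _load_data(cfg: RunConfig, out: Path) -> ColonyDataset:
    if cfg.mode == "simulate":
        effect = dataclasses.replace(cfg.effect, seed=cfg.seed)
        colony = generate_colony(effect)
        write_colony(colony, out / "data", effect)
        return colony
    if cfg.mode == "real":
        if cfg.input_dir is None:
            raise ValueError("real mode needs input_dir")
        d = Path(cfg.input_dir)
        for fname in ("pedigree.csv", "housing.csv", "weights.csv", "recordings.csv", "features.csv", "individuals.csv"):
            if not (d / fname).exists():
                raise FileNotFoundError(f"missing input file: {d / fname}")
        return read_colony(d)
    raise ValueError(f"unknown mode {cfg.mode!r}")


def _signatures_for_sex(feats: pd.DataFrame, warns: list[str]) -> dict:
    pca, scores = pca_kaiser(feats[list(FEATURE_COLUMNS)])
    original, loo = lda_loo(scores, feats["individual_id"])
    binom = binomial_individual_tests(original)
    return {
        "n_calls": len(feats),
        "n_individuals": feats["individual_id"].nunique(),
        "n_pcs": pca.retained_count,
        "dfa_pct": original.accuracy_pct,
        "dfa_loo_pct": loo.accuracy_pct,
        "kappa": cohens_kappa(original),
        "hs_bits": beecher_hs(scores, feats["individual_id"]),
        "n_individuals_above_chance": int((binom < 0.05).sum()),
        "_confusion": original,
        "_binomial": binom,
    }


@_stage("scores")
def _matrices_for_sex(colony: ColonyDataset, ids: list[str]) -> dict[str, ScoreMatrix]:
    feats = colony.features[colony.features["individual_id"].isin(ids)]
    med = individual_medians(feats, columns=list(FEATURE_COLUMNS))
    acoustic = acoustic_dissimilarity(med)
    rec = colony.recording_dates()
    rec_sex = rec[rec.index.isin(ids)]
    housing = colony.housing[colony.housing["individual_id"].astype(str).isin(ids)]
    contact = social_contact_matrix(housing, rec_sex)
    weights = colony.weights[colony.weights["individual_id"].astype(str).isin(ids)]
    weight = weight_dissimilarity(weights, rec_sex)
    kin = kinship_matrix(colony.pedigree.to_frame()).subset(acoustic.ids)
    # align everything to the acoustic id order
    return {
        "acoustic": acoustic,
        "genetic": kin,
        "contact": contact.subset(acoustic.ids),
        "weight": weight.subset(acoustic.ids),
    }


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage and persist artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warns: list[str] = []
    colony = _load_data(cfg, out)
    feats = colony.features
    rng = np.random.default_rng(cfg.seed)

    # pooled sex classification (pDFA) and per-parameter sex LMEs
    try:
        pca_all, scores_all = pca_kaiser(feats[list(FEATURE_COLUMNS)])
        pdfa = nested_pdfa(
            scores_all,
            feats["sex"],
            feats["individual_id"],
            n_perm=cfg.n_perm_pdfa,
            n_selections=cfg.n_selections_pdfa,
            seed=int(rng.integers(2**31)),
        )
        sex_lmes = sex_difference_lmes(
            feats, feats["sex"], feats["individual_id"], columns=list(FEATURE_COLUMNS)
        )
    except Exception as exc:
        raise StageError("signatures-pooled", exc) from exc
    sex_lmes.to_csv(out / "sex_difference_lmes.csv")

    sexes = sorted(feats["sex"].unique()) if cfg.per_sex else [None]
    sig_rows = {}
    mantel_rows = []
    lme_tables: dict[str, pd.DataFrame] = {}
    contact_rows = []
    for sex in sexes:
        sub = feats if sex is None else feats[feats["sex"] == sex]
        label = sex or "all"
        try:
            sig = _signatures_for_sex(sub, warns)
        except Exception as exc:
            raise StageError(f"signatures-{label}", exc) from exc
        sig["_confusion"].to_frame().to_csv(out / f"confusion_{label}.csv")
        sig["_binomial"].to_csv(out / f"binomial_{label}.csv")
        sig_rows[label] = {k: v for k, v in sig.items() if not k.startswith("_")}

        ids = sorted(sub["individual_id"].unique())
        mats = _matrices_for_sex(colony, ids)
        for name, m in mats.items():
            m.to_csv(out / f"score_{name}_{label}.csv")

        try:
            seed_m = int(rng.integers(2**31))
            for other in ("genetic", "contact", "weight"):
                res = mantel(mats["acoustic"], mats[other], n_perm=cfg.n_perm_mantel, seed=seed_m)
                mantel_rows.append(
                    {"sex": label, "comparison": other, "partial": "", "r": res.r, "p": res.p_two_tailed}
                )
            for held, other in (
                ("genetic", "contact"),
                ("genetic", "weight"),
                ("contact", "genetic"),
                ("contact", "weight"),
            ):
                res = partial_mantel(
                    mats["acoustic"], mats[other], mats[held], n_perm=cfg.n_perm_mantel, seed=seed_m
                )
                mantel_rows.append(
                    {"sex": label, "comparison": other, "partial": f"{held} constant", "r": res.r, "p": res.p_two_tailed}
                )
            r, p, n_d = contact_pearson(mats["acoustic"], mats["contact"])
            contact_rows.append({"sex": label, "r": r, "p": p, "n_dyads": n_d})
        except Exception as exc:
            raise StageError(f"inference-{label}", exc) from exc

        try:
            rec_years = {
                i: pd.Timestamp(d).year for i, d in colony.recording_dates().items() if i in ids
            }
            table = build_dyad_table(
                mats["acoustic"], mats["genetic"], mats["contact"], mats["weight"],
                rec_years, pedigree=colony.pedigree, sex=sex,
            )
            table.to_csv(out / f"dyads_{label}.csv", index=False)
            final, trace = backward_eliminate(table)
            lme_tables[label] = final.terms
            final.terms.to_csv(out / f"lme_final_{label}.csv")
            with open(out / f"elimination_{label}.json", "w") as fh:
                json.dump(
                    {
                        "stopping_rule": trace.stopping_rule,
                        "steps": [dataclasses.asdict(s) for s in trace.steps],
                    },
                    fh,
                    indent=1,
                )
            try:
                rel = dyad_relationship_lme(table, "acoustic_dissimilarity")
                rel.terms.to_csv(out / f"relationship_lme_{label}.csv")
            except ValueError as exc:
                warns.append(f"dyad-relationship model skipped for {label}: {exc}")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"models-{label}", exc) from exc

    signature_summary = pd.DataFrame(sig_rows).T
    mantel_table = pd.DataFrame(mantel_rows)
    contact_correlations = pd.DataFrame(contact_rows)
    signature_summary.to_csv(out / "signature_summary.csv")
    mantel_table.to_csv(out / "mantel_table.csv", index=False)
    contact_correlations.to_csv(out / "contact_correlations.csv", index=False)

    cfg_dict = cfg.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": cfg.seed,
        "package_version": _pkg_version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "warnings": warns,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    report = RunReport(
        signature_summary=signature_summary,
        pdfa_sex=dataclasses.asdict(pdfa),
        mantel_table=mantel_table,
        lme_tables=lme_tables,
        contact_correlations=contact_correlations,
        manifest=manifest,
        warnings=warns,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(
            {
                "pdfa_sex": report.pdfa_sex,
                "signature_summary": signature_summary.to_dict(orient="index"),
                "mantel_table": mantel_table.to_dict(orient="records"),
                "lme_tables": {k: v.reset_index().to_dict(orient="records") for k, v in lme_tables.items()},
                "contact_correlations": contact_correlations.to_dict(orient="records"),
                "warnings": warns,
            },
            fh,
            indent=1,
            default=float,
        )
    return report
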