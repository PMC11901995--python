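"""End-to-end orchestration: simulate, score, adjust, phenotype, compose,
evaluate, calibrate — from one YAML config, with a reproducibility manifest.

Every stage's numeric output is a deterministic function of the config
(including its seed); the manifest records the config, seed, package
version and a checksum per output file, so a rerun can be verified
bit-for-bit (only the manifest timestamp differs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import metaprs_kit

from .adjust import adjust_by_ancestry
from .calibration import calibration_curve, calibration_report, predict_probabilities
from .evaluate import evaluate_by_ancestry
from .metaprs import STANDARD_DEFINITIONS, fit_metaprs_by_ancestry
from .phenotype import EhrStream, phenotype_cohort
from .scoring import score_panel, write_scoring_file
from .simcohort import (
    DEFAULT_CODE_SETS,
    AncestryModel,
    EhrNoise,
    TraitArchitecture,
    compute_pcs,
    simulate_ehr,
    simulate_frequencies,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_weight_panels,
)

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ["age", "sex", "PC1", "PC2", "PC3", "PC4"]


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    n_variants: int = 5000
    ancestry: AncestryModel = field(default_factory=AncestryModel)
    architecture: TraitArchitecture = field(default_factory=TraitArchitecture)
    ehr_noise: EhrNoise = field(default_factory=EhrNoise)
    adjust_mode: str = "per-ancestry"
    n_pcs: int = 4
    k_folds: int = 5
    n_bins: int = 5
    risk_ratio: float = 2.0
    n_boot: int = 200
    definitions: tuple[str, ...] = ("risk_factors", "risk_factors_plus_cad")
    write_genotypes: bool = False
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        if self.adjust_mode not in ("per-ancestry", "pooled"):
            raise ValueError("adjust_mode must be 'per-ancestry' or 'pooled'")
        unknown = [d for d in self.definitions if d not in STANDARD_DEFINITIONS]
        if unknown:
            raise ValueError(f"unknown metaPRS definitions {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        for key, typ in (
            ("ancestry", AncestryModel),
            ("architecture", TraitArchitecture),
            ("ehr_noise", EhrNoise),
        ):
            if key in raw and isinstance(raw[key], dict):
                sub = raw[key]
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                raw[key] = typ(**sub)
        if "definitions" in raw:
            raw["definitions"] = tuple(raw["definitions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Run every stage, writing TSV tables, figures and a manifest.

    Returns the run directory.  Stage failures abort with the stage name.
    """
    run_dir = Path(out_dir if out_dir is not None else config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "setup"
    try:
        # ------------------------------------------------ simulation
        stage = "simulate"
        seed = int(config.seed)
        freqs = simulate_frequencies(config.ancestry, config.n_variants, seed)
        genotypes, labels = simulate_genotypes(freqs, config.ancestry, seed + 1)
        panels = simulate_weight_panels(config.architecture, genotypes, seed + 2)
        truth = simulate_phenotypes(
            genotypes, panels, labels, config.architecture, seed + 3
        )
        ehr = simulate_ehr(truth, seed + 4, noise=config.ehr_noise)
        pcs = compute_pcs(genotypes, n_components=config.n_pcs)

        sim_dir = run_dir / "simulated"
        sim_dir.mkdir(exist_ok=True)
        truth.to_csv(sim_dir / "truth.tsv", sep="\t")
        pcs.to_csv(sim_dir / "pcs.tsv", sep="\t")
        ehr.write_tsvs(sim_dir / "ehr")
        panel_dir = sim_dir / "panels"
        panel_dir.mkdir(exist_ok=True)
        for name, panel in panels.items():
            write_scoring_file(panel, panel_dir / f"{name}.txt")
            outputs.append(panel_dir / f"{name}.txt")
        outputs += [sim_dir / "truth.tsv", sim_dir / "pcs.tsv"]
        outputs += sorted((sim_dir / "ehr").glob("*.tsv"))
        if config.write_genotypes:
            genotypes.to_vcf(sim_dir / "genotypes.vcf")
            genotypes.to_dosage_tsv(sim_dir / "genotypes.dosage.tsv")
            outputs += [sim_dir / "genotypes.vcf", sim_dir / "genotypes.dosage.tsv"]

        # ------------------------------------------------ scoring + adjustment
        stage = "score"
        raw_scores = {
            name: score_panel(genotypes, panel) for name, panel in panels.items()
        }
        raw_df = pd.DataFrame({n: rv.scores for n, rv in raw_scores.items()})
        raw_df.to_csv(run_dir / "raw_scores.tsv", sep="\t")
        outputs.append(run_dir / "raw_scores.tsv")

        stage = "adjust"
        adjusted = {
            name: adjust_by_ancestry(
                rv.scores, pcs, labels, mode=config.adjust_mode, panel_name=name
            )
            for name, rv in raw_scores.items()
        }
        adj_df = pd.DataFrame({n: a.scores for n, a in adjusted.items()})
        adj_df.to_csv(run_dir / "adjusted_scores.tsv", sep="\t")
        outputs.append(run_dir / "adjusted_scores.tsv")

        # ------------------------------------------------ phenotyping
        stage = "phenotype"
        phenos = phenotype_cohort(ehr, DEFAULT_CODE_SETS)
        phenos.to_csv(run_dir / "phenotypes.tsv", sep="\t")
        outputs.append(run_dir / "phenotypes.tsv")
        outcome = phenos["cad"]

        covariates = pd.concat([truth[["age", "sex"]], pcs], axis=1)
        covariates = covariates[COVARIATE_COLUMNS[: 2 + config.n_pcs]]

        # ------------------------------------------------ metaPRS + evaluation
        stage = "metaprs"
        eval_tables = []
        meta_scores = {}
        for definition in config.definitions:
            meta, beta_sets = fit_metaprs_by_ancestry(
                adj_df,
                outcome,
                covariates,
                labels,
                definition=definition,
                k=config.k_folds,
                seed=seed + 5,
            )
            meta_scores[definition] = meta
            beta_df = pd.DataFrame(
                {anc: bs.betas for anc, bs in beta_sets.items()}
            )
            beta_df.to_csv(run_dir / f"betas_{definition}.tsv", sep="\t")
            outputs.append(run_dir / f"betas_{definition}.tsv")
        pd.DataFrame(meta_scores).to_csv(run_dir / "metaprs_scores.tsv", sep="\t")
        outputs.append(run_dir / "metaprs_scores.tsv")

        stage = "evaluate"
        for definition, meta in meta_scores.items():
            table = evaluate_by_ancestry(
                meta,
                outcome,
                covariates,
                labels,
                name=definition,
                n_boot=config.n_boot,
                seed=seed + 6,
                r=config.risk_ratio,
            )
            eval_tables.append(table)
        evaluation = pd.concat(eval_tables, ignore_index=True)
        evaluation.to_csv(run_dir / "evaluation.tsv", sep="\t", index=False)
        outputs.append(run_dir / "evaluation.tsv")

        # ------------------------------------------------ calibration
        stage = "calibrate"
        definition = config.definitions[-1]
        meta = meta_scores[definition]
        curves = []
        for group in pd.unique(labels):
            idx = labels.index[labels == group]
            probs = predict_probabilities(
                meta.loc[idx],
                outcome.loc[idx],
                covariates.loc[idx],
                mode="cv",
                k=config.k_folds,
                seed=seed + 7,
            )
            curves.append(
                calibration_curve(
                    probs,
                    outcome.loc[idx],
                    n_bins=config.n_bins,
                    ancestry=str(group),
                    model=definition,
                )
            )
        summary = calibration_report(
            curves, out_path=run_dir / "calibration.png", title=definition
        )
        summary.to_csv(run_dir / "calibration_summary.tsv", sep="\t", index=False)
        bin_tables = pd.concat(
            [c.bins.assign(ancestry=c.ancestry) for c in curves]
        )
        bin_tables.to_csv(run_dir / "calibration_bins.tsv", sep="\t")
        outputs += [
            run_dir / "calibration_summary.tsv",
            run_dir / "calibration_bins.tsv",
        ]
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed (partial outputs in {run_dir}): {exc}"
        ) from exc

    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package_version": metaprs_kit.__version__,
        "seed": int(config.seed),
        "config": config.to_dict(),
        "checksums": {
            str(p.relative_to(run_dir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return run_dir


def compare_metaprs(run_dir) -> pd.DataFrame:
    """Per-ancestry comparison of the two metaPRS evaluations.

    The improvement column is the OR-ratio convention,
    ``100 * (OR_with_cad / OR_without - 1)`` percent; the log-odds-ratio
    alternative ``100 * (log OR_with / log OR_without - 1)`` is reported
    alongside.
    """
    run_dir = Path(run_dir)
    path = run_dir / "evaluation.tsv"
    if not path.exists():
        raise FileNotFoundError(f"no evaluation table in {run_dir}")
    ev = pd.read_csv(path, sep="\t")
    names = ev["PRS"].unique()
    if len(names) < 2:
        raise ValueError("need two evaluated metaPRS definitions to compare")
    base, full = names[0], names[1]
    a = ev[ev["PRS"] == base].set_index("Ancestry")
    b = ev[ev["PRS"] == full].set_index("Ancestry")
    out = pd.DataFrame(
        {
            f"OR_{base}": a["OR_per_SD"],
            f"OR_{full}": b["OR_per_SD"],
            f"AUC_{base}": a["AUC"],
            f"AUC_{full}": b["AUC"],
            "improvement_pct": 100.0 * (b["OR_per_SD"] / a["OR_per_SD"] - 1.0),
            "log_or_improvement_pct": 100.0
            * (np.log(b["OR_per_SD"]) / np.log(a["OR_per_SD"]) - 1.0),
            f"high_risk_pct_{base}": a["high_risk_percent"],
            f"high_risk_pct_{full}": b["high_risk_percent"],
        }
    )
    out.to_csv(run_dir / "metaprs_comparison.tsv", sep="\t")
    return out
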