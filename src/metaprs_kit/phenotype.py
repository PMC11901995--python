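"""EHR-rule phenotyping: diagnosis outcomes, lab phenotypes, lipid states.

Rules mirror common biobank phenotyping practice for prevalent disease:

* a binary outcome requires at least two instances of a qualifying
  diagnosis code (ICD9 and ICD10 members of the code set pool) dated on
  or before the per-person analysis date (enrollment by default);
* lab phenotypes keep measurements dated strictly before the earliest of
  enrollment, the first start of an excluded medication class and the
  first excluded-outcome diagnosis, drop implausible outliers outside an
  open (lower, upper) interval, and average the survivors;
* binary lipid risk states require a minimum number (default 2) of
  surviving measurements beyond the guideline threshold; persons with too
  few surviving measurements are missing, not controls.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ICD9 codes are numeric (possibly with a dot), ICD10 start with a letter.
_CODE_RE = re.compile(r"^(?:[A-Z][0-9]|[0-9])")


@dataclass
class EhrStream:
    """Event tables: diagnoses, labs, medication starts and enrollment.

    All date columns are pandas datetimes.  ``enrollment`` has one row per
    person and defines the cohort; persons absent from an event table
    simply have no events.
    """

    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame
    enrollment: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df, cols in (
            ("diagnoses", self.diagnoses, ["person_id", "code", "date"]),
            ("labs", self.labs, ["person_id", "analyte", "value", "date"]),
            ("medications", self.medications, ["person_id", "drug_class", "date"]),
            ("enrollment", self.enrollment, ["person_id", "date"]),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table lacks columns {missing}")
        if self.enrollment["person_id"].duplicated().any():
            raise ValueError("duplicate person in enrollment table")
        vals = self.labs["value"].to_numpy(dtype=np.float64)
        if len(vals) and (~np.isfinite(vals) | (vals <= 0)).any():
            raise ValueError("lab values must be finite positive numbers")

    @property
    def persons(self) -> pd.Index:
        return pd.Index(self.enrollment["person_id"], name="person_id")

    def enrollment_dates(self) -> pd.Series:
        return self.enrollment.set_index("person_id")["date"]

    # ------------------------------------------------------------- I/O

    def write_tsvs(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("diagnoses", "labs", "medications", "enrollment"):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)

    @classmethod
    def read_tsvs(cls, in_dir) -> "EhrStream":
        from pathlib import Path

        p = Path(in_dir)
        frames = {}
        for name in ("diagnoses", "labs", "medications", "enrollment"):
            df = pd.read_csv(p / f"{name}.tsv", sep="\t", dtype={"code": str})
            df["date"] = pd.to_datetime(df["date"])
            frames[name] = df
        return cls(**frames)


@dataclass
class OutcomeDefinition:
    """Diagnosis-count rule for a binary outcome."""

    name: str
    code_set: frozenset
    min_instances: int = 2

    def __post_init__(self) -> None:
        self.code_set = frozenset(self.code_set)
        if not self.code_set:
            raise ValueError(f"outcome {self.name}: empty code set")
        if self.min_instances < 1:
            raise ValueError(f"outcome {self.name}: min_instances must be >= 1")


@dataclass
class LabRule:
    """Windowing, outlier and averaging rule for a lab analyte.

    ``lower``/``upper`` bound an open interval of plausible values in
    mg/dL; ``excluded_medications`` and ``excluded_outcomes`` truncate the
    usable window at the earliest such event.
    """

    analyte: str
    lower: float
    upper: float
    excluded_medications: tuple = ()
    excluded_outcomes: tuple = ()  # OutcomeDefinitions whose first dx censors

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.analyte}: lower bound must be < upper bound")


@dataclass
class BinaryLipidRule:
    """Persistent-threshold rule for a binary lipid risk state."""

    analyte: str
    threshold: float
    direction: str = ">="  # ">=" or "<"
    min_measures: int = 2

    def __post_init__(self) -> None:
        if self.direction not in (">=", "<"):
            raise ValueError("direction must be '>=' or '<'")
        if self.min_measures < 1:
            raise ValueError("min_measures must be >= 1")


#: Default rules matching guideline thresholds and plausibility bounds:
#: LDL/TG values outside (20, 500) mg/dL and HDL outside (10, 100) mg/dL
#: are treated as implausible outliers.
DEFAULT_LAB_RULES = {
    "LDL": LabRule("LDL", 20.0, 500.0, ("statin",), ("CAD",)),
    "TG": LabRule("TG", 20.0, 500.0, ("statin",), ("CAD",)),
    "HDL": LabRule("HDL", 10.0, 100.0, ("statin",), ("CAD",)),
}

DEFAULT_LIPID_RULES = {
    "ldl_160": BinaryLipidRule("LDL", 160.0, ">="),
    "ldl_190": BinaryLipidRule("LDL", 190.0, ">="),
    "tg_175": BinaryLipidRule("TG", 175.0, ">="),
    "hdl_40": BinaryLipidRule("HDL", 40.0, "<"),
}


def _valid_code_mask(codes: pd.Series) -> pd.Series:
    ok = codes.astype(str).str.match(_CODE_RE)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(
            f"ignoring {n_bad} diagnosis event(s) with unrecognized code system",
            stacklevel=3,
        )
    return ok


def define_diagnosis_outcome(
    stream: EhrStream,
    definition: OutcomeDefinition,
    analysis_date: pd.Series | None = None,
) -> pd.Series:
    """Case flag per person: >= ``min_instances`` qualifying codes.

    ICD9 and ICD10 members of the code set pool into a single count.
    Only events dated on or before the person's analysis date (their
    enrollment date by default) count, so cases are prevalent cases.
    Returns an int Series (1 case / 0 control) over enrolled persons.
    """
    persons = stream.persons
    if analysis_date is None:
        analysis_date = stream.enrollment_dates()
    dx = stream.diagnoses
    dx = dx[_valid_code_mask(dx["code"])]
    dx = dx[dx["code"].isin(definition.code_set)]
    cutoff = dx["person_id"].map(analysis_date)
    dx = dx[dx["date"] <= cutoff]
    counts = dx.groupby("person_id").size().reindex(persons, fill_value=0)
    return (counts >= definition.min_instances).astype(int).rename(definition.name)


def _censor_dates(
    stream: EhrStream, rule: LabRule, code_sets: dict | None = None
) -> pd.Series:
    """Earliest of enrollment, first excluded-med start, first excluded dx."""
    censor = stream.enrollment_dates().copy()
    meds = stream.medications
    if rule.excluded_medications and len(meds):
        m = meds[meds["drug_class"].isin(rule.excluded_medications)]
        first = m.groupby("person_id")["date"].min()
        censor = pd.concat([censor, first], axis=1).min(axis=1)
    if rule.excluded_outcomes:
        dx = stream.diagnoses
        for outcome in rule.excluded_outcomes:
            codes = (
                outcome.code_set
                if isinstance(outcome, OutcomeDefinition)
                else (code_sets or {}).get(outcome, ())
            )
            d = dx[dx["code"].isin(codes)]
            if len(d):
                first = d.groupby("person_id")["date"].min()
                censor = pd.concat([censor, first], axis=1).min(axis=1)
    return censor.reindex(stream.persons)


def surviving_lab_values(
    stream: EhrStream, rule: LabRule, code_sets: dict | None = None
) -> pd.DataFrame:
    """Lab rows passing the window and outlier filters for one analyte."""
    labs = stream.labs
    labs = labs[labs["analyte"] == rule.analyte]
    censor = _censor_dates(stream, rule, code_sets)
    cutoff = labs["person_id"].map(censor)
    labs = labs[labs["date"] < cutoff]
    v = labs["value"]
    return labs[(v > rule.lower) & (v < rule.upper)]


def derive_lab_phenotype(
    stream: EhrStream, rule: LabRule, code_sets: dict | None = None
) -> pd.Series:
    """Mean surviving value per person (mg/dL), NaN if none survive."""
    kept = surviving_lab_values(stream, rule, code_sets)
    means = kept.groupby("person_id")["value"].mean()
    return means.reindex(stream.persons).rename(rule.analyte)


def define_binary_lipid_outcome(
    stream: EhrStream,
    rule: BinaryLipidRule,
    lab_rule: LabRule,
    code_sets: dict | None = None,
) -> pd.Series:
    """Persistent-threshold flag: 1 / 0 / NaN per person.

    After the lab rule's window and outlier filters, the flag is 1 when at
    least ``min_measures`` surviving values satisfy the threshold, 0 when
    the person has at least ``min_measures`` surviving values but fewer
    than that satisfy it, and missing otherwise (too few usable measures
    to call either way).
    """
    if rule.analyte != lab_rule.analyte:
        raise ValueError("binary rule and lab rule must share an analyte")
    kept = surviving_lab_values(stream, lab_rule, code_sets)
    if rule.direction == ">=":
        meets = kept["value"] >= rule.threshold
    else:
        meets = kept["value"] < rule.threshold
    g = kept.assign(meets=meets).groupby("person_id")["meets"]
    n_total = g.size().reindex(stream.persons, fill_value=0)
    n_meet = g.sum().reindex(stream.persons, fill_value=0)
    flag = pd.Series(np.nan, index=stream.persons, name=rule.analyte)
    flag[n_meet >= rule.min_measures] = 1.0
    flag[(n_total >= rule.min_measures) & (n_meet < rule.min_measures)] = 0.0
    return flag


def phenotype_cohort(
    stream: EhrStream,
    code_sets: dict[str, list[str]],
    lab_rules: dict[str, LabRule] | None = None,
    lipid_rules: dict[str, BinaryLipidRule] | None = None,
) -> pd.DataFrame:
    """Apply all rules, returning one phenotype table over enrolled persons.

    Columns: one 0/1 column per diagnosis outcome (lower-cased name), one
    mean-value column per lab analyte (``<analyte>_mean``), and one
    1/0/NaN column per binary lipid rule.
    """
    lab_rules = lab_rules if lab_rules is not None else DEFAULT_LAB_RULES
    lipid_rules = lipid_rules if lipid_rules is not None else DEFAULT_LIPID_RULES
    out = {}
    for name, codes in code_sets.items():
        d = OutcomeDefinition(name=name, code_set=frozenset(codes))
        out[name.lower()] = define_diagnosis_outcome(stream, d)
    for analyte, rule in lab_rules.items():
        out[f"{analyte.lower()}_mean"] = derive_lab_phenotype(
            stream, rule, code_sets
        )
    for name, rule in lipid_rules.items():
        out[name] = define_binary_lipid_outcome(
            stream, rule, lab_rules[rule.analyte], code_sets
        )
    return pd.DataFrame(out, index=stream.persons)
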