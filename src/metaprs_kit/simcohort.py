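"""Synthetic multi-ancestry cohort simulator.

Generates everything the downstream validation pipeline consumes: group
allele frequencies under the Balding–Nichols model, genotype dosages,
per-panel variant weight sets, liability-threshold binary outcomes with a
partially mediated CAD component, quantitative lipids, EHR-like event
streams (diagnoses, repeated labs with outliers, medication starts), and
genotype principal components.

The divergence model draws each group's allele frequency for a variant
from a Beta distribution with mean equal to the ancestral frequency ``p``
and variance ``fst * p * (1 - p)``, the standard single-parameter device
for emulating allele-frequency differentiation between populations.

CAD is built as a liability with three additive variance components:
a share mediated through the risk-factor liabilities (lipids, blood
pressure, diabetes, atrial fibrillation), a direct polygenic CAD share not
explained by those risk factors, and residual environmental noise.  The
direct share is the quantity the metaPRS comparison is designed to detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GenotypeMatrix, WeightPanel

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("AFR", "AMR", "EAS", "EUR", "SAS", "ADM")

#: Panels mirroring the validated cardiovascular panel set: three lipid
#: traits, Lp(a), three cardiometabolic outcomes and a direct CAD score.
DEFAULT_PANELS = ("LDL", "HDL", "TG", "LPA", "HT", "T2DM", "AF", "CAD")

RISK_FACTOR_PANELS = ("LDL", "HDL", "TG", "LPA", "HT", "T2DM", "AF")

#: Epoch for the integer-day EHR time axis.
EHR_EPOCH = pd.Timestamp("2010-01-01")

# Quantitative lipid scales (mg/dL): population mean and SD used for the
# affine mapping of the standardized lipid liabilities.
LIPID_SCALES = {
    "LDL": (120.0, 30.0),
    "HDL": (55.0, 14.0),
    "TG": (140.0, 60.0),
    "LPA": (30.0, 25.0),
}

ALLELES = np.array(["A", "C", "G", "T"])

# Plausible measurement ranges per analyte (mg/dL): non-outlier lab draws
# are kept inside these, so implausible values appear only via explicit
# outlier injection.
LAB_PLAUSIBLE = {
    "LDL": (20.5, 499.5),
    "TG": (20.5, 499.5),
    "HDL": (10.5, 99.5),
    "LPA": (1.0, 499.5),
}


@dataclass
class AncestryModel:
    """Population-structure parameters for K ancestry groups."""

    group_names: tuple[str, ...] = DEFAULT_GROUPS
    fst: tuple[float, ...] = (0.15, 0.08, 0.12, 0.02, 0.10, 0.06)
    group_sizes: tuple[int, ...] = (3000, 3000, 3000, 6000, 2000, 3000)

    def __post_init__(self) -> None:
        k = len(self.group_names)
        if k < 1:
            raise ValueError("need at least one ancestry group")
        if len(self.fst) != k or len(self.group_sizes) != k:
            raise ValueError("fst and group_sizes must match group_names")
        if any(not (0.0 < f < 1.0) for f in self.fst):
            raise ValueError("fst values must lie strictly in (0, 1)")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("all group sizes must be >= 1")

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))


@dataclass
class TraitArchitecture:
    """Genetic architecture shared by the simulated panels and outcomes.

    ``heritability`` is the variance share of the panel genetic score in
    each trait's liability (or quantitative value).  ``cad_mediation``
    weights the risk-factor liabilities inside the mediated CAD component;
    ``cad_mediated_share`` / ``cad_direct_share`` are the CAD liability
    variance shares of the mediated and direct genetic components, with
    the remainder being environmental noise.
    """

    panel_names: tuple[str, ...] = DEFAULT_PANELS
    causal_fraction: float = 0.2
    effect_scale: float = 1.0
    heritability: float = 0.3
    prevalence: dict = field(
        default_factory=lambda: {"HT": 0.25, "T2DM": 0.12, "AF": 0.04, "CAD": 0.08}
    )
    cad_mediation: dict = field(
        default_factory=lambda: {
            "LDL": 0.35,
            "HDL": -0.20,
            "TG": 0.15,
            "LPA": 0.15,
            "HT": 0.30,
            "T2DM": 0.25,
            "AF": 0.10,
        }
    )
    cad_mediated_share: float = 0.25
    cad_direct_share: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must lie in (0, 1]")
        for name, p in self.prevalence.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence for {name} must lie in (0, 1)")
        for share in (self.cad_mediated_share, self.cad_direct_share):
            if not (0.0 <= share <= 1.0):
                raise ValueError("CAD variance shares must lie in [0, 1]")
        if self.cad_mediated_share + self.cad_direct_share > 1.0:
            raise ValueError("CAD variance shares exceed 1")
        if not (0.0 < self.heritability <= 1.0):
            raise ValueError("heritability must lie in (0, 1]")

    @property
    def cad_noise_share(self) -> float:
        return 1.0 - self.cad_mediated_share - self.cad_direct_share


@dataclass
class EhrNoise:
    """Noise knobs for the EHR event-stream generator.

    Defaults describe a lightly noisy record: a few percent of true cases
    fail to accumulate two diagnosis codes, a few percent of controls pick
    up a single stray code, labs repeat 1–5 times with measurement jitter,
    and a small fraction of draws are implausible outliers.
    """

    false_negative_rate: float = 0.05
    control_code_rate: float = 0.05
    min_lab_repeats: int = 1
    max_lab_repeats: int = 5
    lab_jitter_frac: float = 0.04
    outlier_rate: float = 0.01
    medicated_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (1 <= self.min_lab_repeats <= self.max_lab_repeats):
            raise ValueError("lab repeat bounds invalid")
        for r in (
            self.false_negative_rate,
            self.control_code_rate,
            self.lab_jitter_frac,
            self.outlier_rate,
            self.medicated_fraction,
        ):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


#: Default diagnosis code sets: a mix of ICD9 (numeric) and ICD10
#: (letter-prefixed) codes per outcome, mirroring pooled-code phenotyping.
DEFAULT_CODE_SETS = {
    "CAD": ["I25.1", "I25.9", "414.0", "414.9"],
    "HT": ["I10", "401.9", "401.1"],
    "T2DM": ["E11.9", "E11.8", "250.00", "250.02"],
    "AF": ["I48.0", "I48.91", "427.31"],
}

DEFAULT_MED_CLASSES = {"LDL": "statin", "T2DM": "metformin"}


def simulate_frequencies(
    model: AncestryModel,
    n_variants: int,
    seed: int,
    base_freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw group-specific allele frequencies under the Balding–Nichols model.

    Each group g draws its frequency for variant v from
    ``Beta(p (1 - F) / F, (1 - p)(1 - F) / F)`` with ``p`` the ancestral
    frequency and ``F`` the group's divergence parameter, giving mean p and
    variance ``F p (1 - p)``.  Frequencies are truncated to (0.001, 0.999).

    Returns a DataFrame with one row per variant (``base`` column) and one
    column per group.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    if base_freqs is None:
        base_freqs = rng.uniform(0.05, 0.95, size=n_variants)
    base_freqs = np.asarray(base_freqs, dtype=np.float64)
    if base_freqs.shape != (n_variants,):
        raise ValueError("base_freqs length must equal n_variants")
    if ((base_freqs <= 0.01) | (base_freqs >= 0.99)).any():
        raise ValueError("base frequencies must lie in (0.01, 0.99)")

    out = {"base": base_freqs}
    for name, fst in zip(model.group_names, model.fst):
        a = base_freqs * (1.0 - fst) / fst
        b = (1.0 - base_freqs) * (1.0 - fst) / fst
        p = rng.beta(a, b)
        out[name] = np.clip(p, 0.001, 0.999)
    return pd.DataFrame(out)


def simulate_genotypes(
    freqs: pd.DataFrame, model: AncestryModel, seed: int
) -> tuple[GenotypeMatrix, pd.Series]:
    """Draw binomial(2, p) dosages per individual and variant.

    Returns the genotype matrix and a Series of ancestry labels indexed by
    sample id.  Sample ids are ``S000001, ...`` in group order.
    """
    missing = [g for g in model.group_names if g not in freqs.columns]
    if missing:
        raise ValueError(f"frequency table lacks groups {missing}")
    rng = np.random.default_rng(seed)
    n_variants = len(freqs)
    blocks, labels = [], []
    for name, size in zip(model.group_names, model.group_sizes):
        p = freqs[name].to_numpy()
        blocks.append(rng.binomial(2, p, size=(size, n_variants)))
        labels.extend([name] * size)
    dosages = np.vstack(blocks).astype(np.float64)
    n = dosages.shape[0]
    samples = np.array([f"S{i:06d}" for i in range(1, n + 1)], dtype=object)

    ref_alt = _variant_alleles(rng, n_variants)
    variants = pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(n_variants)],
            "chrom": ["1"] * n_variants,
            "pos": np.arange(1, n_variants + 1) * 100,
            "ref": ref_alt[:, 0],
            "alt": ref_alt[:, 1],
        }
    )
    gm = GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)
    return gm, pd.Series(labels, index=samples, name="ancestry")


def _variant_alleles(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random unambiguous ref/alt pairs (no A/T or C/G strand ambiguity)."""
    pairs = np.array(
        [
            ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
            ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
        ]
    )
    return pairs[rng.integers(0, len(pairs), size=n)]


def simulate_weight_panels(
    arch: TraitArchitecture,
    genotypes: GenotypeMatrix,
    seed: int,
) -> dict[str, WeightPanel]:
    """Draw one weight panel per trait on the cohort's variants.

    Each panel selects ``round(causal_fraction * n_variants)`` variants and
    assigns them independent centered Gaussian weights with standard
    deviation ``effect_scale``; effect allele is the genotype alt allele.
    """
    n_variants = genotypes.n_variants
    if n_variants < 1:
        raise ValueError("need at least one variant")
    n_causal = int(round(arch.causal_fraction * n_variants))
    if n_causal < 1:
        raise ValueError("causal_fraction too small for this variant count")
    rng = np.random.default_rng(seed)
    panels: dict[str, WeightPanel] = {}
    v = genotypes.variants
    for name in arch.panel_names:
        idx = np.sort(rng.choice(n_variants, size=n_causal, replace=False))
        weights = rng.normal(0.0, arch.effect_scale, size=n_causal)
        entries = pd.DataFrame(
            {
                "rsID": v["id"].to_numpy()[idx],
                "chr_name": v["chrom"].to_numpy()[idx],
                "chr_position": v["pos"].to_numpy()[idx],
                "effect_allele": v["alt"].to_numpy()[idx],
                "other_allele": v["ref"].to_numpy()[idx],
                "effect_weight": weights,
            }
        )
        panels[name] = WeightPanel(name=name, entries=entries, source="simulated")
    return panels


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    panels: dict[str, WeightPanel],
    labels: pd.Series,
    arch: TraitArchitecture,
    seed: int,
) -> pd.DataFrame:
    """Build the cohort truth table from genotypes and panel weights.

    Quantitative lipids are affine maps of standardized liabilities
    (``sqrt(h2) * z_genetic + sqrt(1 - h2) * noise``) onto mg/dL scales;
    binary lipid risk states follow guideline thresholds on those values
    (LDL >= 160 and >= 190, TG >= 175, HDL < 40).  Disease outcomes (HT,
    T2DM, AF) are liability-threshold indicators with per-ancestry
    thresholds set at the empirical group quantile of the liability so the
    target prevalence is hit.  The CAD liability mixes the mediated
    risk-factor component, the direct CAD genetic score and noise with the
    architecture's variance shares.

    Returns a truth DataFrame indexed by sample id with covariates (age,
    sex), ancestry, true lab values, binary outcomes, and the latent
    liabilities / standardized genetic scores (``z_*``, ``liab_*``).
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    var_ids = pd.Index(genotypes.variants["id"])
    h2 = arch.heritability

    truth = pd.DataFrame(index=pd.Index(genotypes.samples, name="person_id"))
    truth["ancestry"] = labels.reindex(truth.index).to_numpy()
    truth["age"] = rng.uniform(35.0, 75.0, size=n)
    truth["sex"] = rng.binomial(1, 0.6, size=n)  # 1 = female

    # standardized genetic score per panel
    z = {}
    for name, panel in panels.items():
        pos = var_ids.get_indexer(panel.entries["rsID"])
        if (pos < 0).any():
            raise ValueError(f"panel {name} contains variants absent from genotypes")
        g = genotypes.dosages[:, pos] @ panel.entries["effect_weight"].to_numpy()
        z[name] = _standardize(g)
        truth[f"z_{name}"] = z[name]

    # quantitative lipids and guideline binary states
    liab = {}
    for name, (mu, sd) in LIPID_SCALES.items():
        liab[name] = np.sqrt(h2) * z[name] + np.sqrt(1 - h2) * rng.normal(size=n)
        value = mu + sd * liab[name]
        value = np.clip(value, 1.0, None)
        truth[f"{name.lower()}_true"] = value
    truth["ldl_160"] = (truth["ldl_true"] >= 160).astype(int)
    truth["ldl_190"] = (truth["ldl_true"] >= 190).astype(int)
    truth["tg_175"] = (truth["tg_true"] >= 175).astype(int)
    truth["hdl_40"] = (truth["hdl_true"] < 40).astype(int)

    # liability-threshold disease outcomes
    for name in ("HT", "T2DM", "AF"):
        liab[name] = np.sqrt(h2) * z[name] + np.sqrt(1 - h2) * rng.normal(size=n)
        truth[f"liab_{name}"] = liab[name]
        truth[name.lower()] = _threshold_by_group(
            liab[name], truth["ancestry"].to_numpy(), arch.prevalence[name]
        )

    # CAD: mediated + direct + noise, with stated variance shares
    med = np.zeros(n)
    for name, w in arch.cad_mediation.items():
        comp = liab[name] if name in liab else z[name]
        med += w * comp
    med = _standardize(med)
    cad_liab = (
        np.sqrt(arch.cad_mediated_share) * med
        + np.sqrt(arch.cad_direct_share) * z["CAD"]
        + np.sqrt(arch.cad_noise_share) * rng.normal(size=n)
    )
    truth["liab_CAD"] = cad_liab
    truth["cad"] = _threshold_by_group(
        cad_liab, truth["ancestry"].to_numpy(), arch.prevalence["CAD"]
    )
    return truth


def _threshold_by_group(
    liability: np.ndarray, groups: np.ndarray, prevalence: float
) -> np.ndarray:
    """Case indicator from per-group empirical liability quantiles."""
    out = np.zeros(len(liability), dtype=int)
    for g in pd.unique(groups):
        mask = groups == g
        thr = np.quantile(liability[mask], 1.0 - prevalence)
        out[mask] = (liability[mask] > thr).astype(int)
    return out


def simulate_ehr(
    truth: pd.DataFrame,
    seed: int,
    noise: EhrNoise | None = None,
    code_sets: dict[str, list[str]] | None = None,
):
    """Emit diagnosis, lab, medication and enrollment streams from truths.

    True cases of each outcome accumulate >= 2 pre-enrollment diagnosis
    codes (unless hit by the false-negative rate, in which case they get
    exactly one); controls pick up a single stray code at the control
    noise rate.  Each person receives 1–5 repeated lab draws jittered
    around the true value, with optional implausible-outlier injection,
    and a configurable fraction of high-LDL / T2DM individuals starts the
    matching medication class partway through their draw sequence.

    Returns an :class:`~metaprs_kit.phenotype.EhrStream`.
    """
    from .phenotype import EhrStream

    if noise is None:
        noise = EhrNoise()
    if code_sets is None:
        code_sets = DEFAULT_CODE_SETS
    rng = np.random.default_rng(seed)
    persons = truth.index.to_numpy()
    n = len(persons)

    enroll_day = rng.integers(2000, 3000, size=n)
    enrollment = pd.DataFrame(
        {"person_id": persons, "date": EHR_EPOCH + pd.to_timedelta(enroll_day, "D")}
    )

    dx_rows = []
    for outcome, codes in code_sets.items():
        col = outcome.lower()
        if col not in truth.columns:
            continue
        flags = truth[col].to_numpy()
        fn = rng.random(n) < noise.false_negative_rate
        stray = rng.random(n) < noise.control_code_rate
        extra = rng.poisson(1.0, size=n)
        for i in range(n):
            if flags[i] == 1:
                k = 1 if fn[i] else 2 + extra[i]
            else:
                k = 1 if stray[i] else 0
            if k == 0:
                continue
            days = rng.integers(100, enroll_day[i], size=k)
            picks = rng.integers(0, len(codes), size=k)
            for d, c in zip(days, picks):
                dx_rows.append((persons[i], codes[c], int(d)))
    diagnoses = pd.DataFrame(dx_rows, columns=["person_id", "code", "day"])

    # medication starts: a fraction of flagged individuals begin the class
    med_rows = []
    med_start_day = {}
    for flag_col, drug in (("ldl_160", "statin"), ("t2dm", "metformin")):
        if flag_col not in truth.columns:
            continue
        flags = truth[flag_col].to_numpy()
        use = rng.random(n) < noise.medicated_fraction
        for i in range(n):
            if flags[i] == 1 and use[i]:
                day = int(rng.integers(1000, enroll_day[i]))
                med_rows.append((persons[i], drug, day))
                med_start_day[(persons[i], drug)] = min(
                    day, med_start_day.get((persons[i], drug), day)
                )
    medications = pd.DataFrame(med_rows, columns=["person_id", "drug_class", "day"])

    lab_rows = []
    analytes = [(c, c[: -len("_true")].upper()) for c in truth.columns if c.endswith("_true")]
    for col, analyte in analytes:
        values = truth[col].to_numpy()
        _, scale_sd = LIPID_SCALES.get(analyte, (0.0, 25.0))
        lo, hi = LAB_PLAUSIBLE.get(analyte, (1.0, 499.5))
        reps = rng.integers(noise.min_lab_repeats, noise.max_lab_repeats + 1, size=n)
        for i in range(n):
            k = int(reps[i])
            days = np.sort(rng.integers(100, enroll_day[i], size=k))
            jitter = rng.normal(0.0, noise.lab_jitter_frac * scale_sd, size=k)
            vals = np.clip(values[i] + jitter, lo, hi)
            outl = rng.random(k) < noise.outlier_rate
            vals = np.where(outl, np.where(rng.random(k) < 0.5, 600.0, 5.0), vals)
            for d, v in zip(days, vals):
                lab_rows.append((persons[i], analyte, float(v), int(d)))
    labs = pd.DataFrame(lab_rows, columns=["person_id", "analyte", "value", "day"])

    for df in (diagnoses, medications, labs):
        df["date"] = EHR_EPOCH + pd.to_timedelta(df.pop("day"), "D")
    return EhrStream(
        diagnoses=diagnoses,
        labs=labs,
        medications=medications,
        enrollment=enrollment,
    )


def compute_pcs(genotypes: GenotypeMatrix, n_components: int = 4) -> pd.DataFrame:
    """Principal components of the column-standardized dosage matrix.

    Constant dosage columns are dropped (logged) before the decomposition.
    Each returned component is scaled to unit (sample) variance, with sign
    fixed so the largest-magnitude variant loading is positive.  Returns a
    DataFrame indexed by sample id with columns ``PC1..PCk``.
    """
    from sklearn.decomposition import PCA

    x = genotypes.dosages
    n, m = x.shape
    if n_components > min(n, m):
        raise ValueError("n_components exceeds matrix rank bound")
    sd = x.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d constant dosage columns before PCA", n_dropped)
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(xs)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    scores = scores / scores.std(axis=0, ddof=1)
    return pd.DataFrame(
        scores,
        index=pd.Index(genotypes.samples, name="person_id"),
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
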