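"""Raw PRS computation: scoring-file I/O, variant/allele matching, scoring.

The raw score of an individual is the sum over matched variants of the
panel effect weight times the individual's effect-allele dosage.  Variants
are matched to genotypes on (chromosome, position); when the panel's
effect allele equals the genotype reference allele the dosage is counted
as ``2 - d`` (an allele flip) under the ``allow_flip`` policy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, WeightPanel

logger = logging.getLogger(__name__)

VALID_POLICIES = ("strict", "allow_flip", "drop_ambiguous")
_SNV_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class ScoringFileError(ValueError):
    """Raised for unusable scoring files (no parsable rows, duplicates)."""


@dataclass
class RawScoreVector:
    """Per-sample raw scores for one panel, plus match bookkeeping."""

    panel_name: str
    scores: pd.Series
    n_variants_used: int
    n_variants_dropped: int

    def __post_init__(self) -> None:
        self.scores = self.scores.rename(self.panel_name)


@dataclass
class MatchedPanel:
    """Panel aligned to a genotype matrix.

    ``genotype_index`` gives, per retained panel entry, the column in the
    dosage matrix; ``flipped`` marks entries scored on ``2 - dosage``;
    ``drop_report`` lists discarded entries with a reason.
    """

    panel_name: str
    weights: np.ndarray
    genotype_index: np.ndarray
    flipped: np.ndarray
    drop_report: pd.DataFrame

    @property
    def n_matched(self) -> int:
        return len(self.weights)


def read_scoring_file(path, name: str | None = None) -> WeightPanel:
    """Parse a PGS-Catalog-dialect scoring file into a WeightPanel.

    Lines starting with ``#`` are header/metadata and ignored.  Rows with a
    non-numeric weight or non-ACGT alleles are dropped and counted in the
    panel's ``n_dropped_rows``.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"chr_name": str, "rsID": str},
    )
    required = list(WeightPanel.ENTRY_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScoringFileError(f"{path}: missing columns {missing}")
    n_raw = len(df)
    df["effect_weight"] = pd.to_numeric(df["effect_weight"], errors="coerce")
    ok = df["effect_weight"].notna()
    for col in ("effect_allele", "other_allele"):
        ok &= df[col].astype(str).str.upper().isin(_SNV_ALLELES)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise ScoringFileError(f"{path}: no parsable rows")
    dup = df["rsID"][df["rsID"].duplicated()]
    if len(dup):
        raise ScoringFileError(f"{path}: duplicate variant id {dup.iloc[0]!r}")
    df["chr_position"] = df["chr_position"].astype(int)
    return WeightPanel(
        name=name or str(path),
        entries=df[required],
        n_dropped_rows=n_raw - len(df),
        source=str(path),
    )


def write_scoring_file(panel: WeightPanel, path) -> None:
    """Write a panel in the PGS Catalog scoring-file dialect."""
    with open(path, "w") as fh:
        fh.write("### PGS CATALOG SCORING FILE\n")
        fh.write(f"#pgs_name={panel.name}\n")
        fh.write(f"#variants_number={panel.n_variants}\n")
        entries = panel.entries.copy()
        entries["effect_weight"] = entries["effect_weight"].map(
            lambda w: format(float(w), ".17g")
        )
        entries.to_csv(fh, sep="\t", index=False)


def match_variants(
    panel: WeightPanel,
    genotypes: GenotypeMatrix,
    policy: str = "allow_flip",
) -> MatchedPanel:
    """Align panel entries to genotype columns by (chromosome, position).

    Under ``allow_flip`` an entry whose effect allele equals the genotype
    ref (with other allele equal to alt) is retained and marked flipped;
    under ``strict`` such entries are dropped.  ``drop_ambiguous`` behaves
    like ``allow_flip`` but additionally discards strand-ambiguous A/T and
    C/G entries.  Unmatched or allele-inconsistent entries are dropped and
    listed in the drop report.  Zero matches is a hard error, since it
    almost always signals a coordinate-convention mismatch.
    """
    if policy not in VALID_POLICIES:
        raise ValueError(f"policy must be one of {VALID_POLICIES}")
    geno = genotypes.variants
    lookup = {
        (str(c), int(p)): j
        for j, (c, p) in enumerate(zip(geno["chrom"], geno["pos"]))
    }
    weights, gidx, flipped = [], [], []
    drops = []
    for row in panel.entries.itertuples(index=False):
        ea = str(row.effect_allele).upper()
        oa = str(row.other_allele).upper()
        key = (str(row.chr_name), int(row.chr_position))
        if ea not in _SNV_ALLELES or oa not in _SNV_ALLELES:
            drops.append((row.rsID, "non_snv_allele"))
            continue
        if policy == "drop_ambiguous" and (ea, oa) in _AMBIGUOUS_PAIRS:
            drops.append((row.rsID, "ambiguous"))
            continue
        j = lookup.get(key)
        if j is None:
            drops.append((row.rsID, "unmatched_position"))
            continue
        ref = str(geno["ref"].iloc[j]).upper()
        alt = str(geno["alt"].iloc[j]).upper()
        if ea == alt and oa == ref:
            flip = False
        elif ea == ref and oa == alt:
            if policy == "strict":
                drops.append((row.rsID, "flip_needed_under_strict"))
                continue
            flip = True
        else:
            drops.append((row.rsID, "allele_mismatch"))
            continue
        weights.append(float(row.effect_weight))
        gidx.append(j)
        flipped.append(flip)
    if not weights:
        raise ValueError(
            f"panel {panel.name}: zero variants matched the genotype matrix "
            "(coordinate-convention mismatch?)"
        )
    return MatchedPanel(
        panel_name=panel.name,
        weights=np.asarray(weights, dtype=np.float64),
        genotype_index=np.asarray(gidx, dtype=np.intp),
        flipped=np.asarray(flipped, dtype=bool),
        drop_report=pd.DataFrame(drops, columns=["rsID", "reason"]),
    )


def compute_raw_prs(
    genotypes: GenotypeMatrix, matched: MatchedPanel
) -> RawScoreVector:
    """Score each sample: sum of weight times (flip-adjusted) dosage.

    Missing dosages are mean-imputed at ``2 * AF`` where AF is the cohort
    alt-allele frequency of the variant; a variant with no observed
    dosages at all is dropped with a warning.
    """
    if matched.n_matched == 0:
        raise ValueError("matched panel is empty")
    d = genotypes.dosages[:, matched.genotype_index].copy()
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"panel {matched.panel_name}: dropping "
            f"{int(all_missing.sum())} all-missing variant(s)",
            stacklevel=2,
        )
    keep = ~all_missing
    d = d[:, keep]
    weights = matched.weights[keep]
    flipped = matched.flipped[keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        af = np.nanmean(d, axis=0) / 2.0
    fill = np.broadcast_to(2.0 * af, d.shape)
    d = np.where(np.isnan(d), fill, d)
    d = np.where(flipped, 2.0 - d, d)
    scores = d @ weights
    n_used = int(keep.sum())
    return RawScoreVector(
        panel_name=matched.panel_name,
        scores=pd.Series(scores, index=pd.Index(genotypes.samples, name="person_id")),
        n_variants_used=n_used,
        n_variants_dropped=len(matched.drop_report) + int(all_missing.sum()),
    )


def score_panel(
    genotypes: GenotypeMatrix, panel: WeightPanel, policy: str = "allow_flip"
) -> RawScoreVector:
    """Convenience: match then score in one call."""
    return compute_raw_prs(genotypes, match_variants(panel, genotypes, policy))
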