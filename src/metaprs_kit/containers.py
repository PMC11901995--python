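"""Core in-memory containers: genotype dosage matrices and weight panels.

Genotypes travel as an individuals-by-variants dosage matrix (alt-allele
counts in [0, 2], possibly fractional for imputed data) with variant and
sample metadata.  Weight panels carry per-variant effect alleles and effect
weights in the PGS Catalog scoring-file convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with sample ids and variant records.

    Parameters
    ----------
    samples
        Sample identifiers, one per matrix row.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt``; ``pos`` is
        1-based.  Variant ids must be unique.
    dosages
        Array of shape ``(n_samples, n_variants)`` holding alt-allele
        dosages in [0, 2]; NaN marks a missing call.
    """

    samples: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns {missing}")
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # ---------------------------------------------------------------- I/O

    def to_dosage_tsv(self, path) -> None:
        """Write a plain dosage TSV: variant metadata columns then one
        column per sample."""
        out = self.variants.copy()
        dos = pd.DataFrame(
            self.dosages.T, columns=list(self.samples), index=out.index
        )
        pd.concat([out, dos], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta = df[VARIANT_COLUMNS]
        sample_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]
        dosages = df[sample_cols].to_numpy(dtype=np.float64).T
        return cls(
            samples=np.array(sample_cols, dtype=object),
            variants=meta.reset_index(drop=True),
            dosages=dosages,
        )

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with GT and DS per sample.

        GT is derived by rounding the dosage; DS carries the exact value,
        so fractional dosages round-trip through the DS field.
        """
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,'
                'Description="Alt allele dosage">\n'
            )
            for chrom in pd.unique(self.variants["chrom"].astype(str)):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, self.samples))
                + "\n"
            )
            gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
            order = np.lexsort(
                (self.variants["pos"].to_numpy(), self.variants["chrom"].astype(str))
            )
            for j in order:
                v = self.variants.iloc[j]
                fields = [
                    str(v["chrom"]),
                    str(int(v["pos"])),
                    str(v["id"]),
                    str(v["ref"]),
                    str(v["alt"]),
                    ".",
                    "PASS",
                    ".",
                    "GT:DS",
                ]
                col = self.dosages[:, j]
                cells = []
                for d in col:
                    if np.isnan(d):
                        cells.append("./.:.")
                    else:
                        gt = gt_codes[int(round(d))]
                        cells.append(f"{gt}:{d:.6g}")
                fh.write("\t".join(fields + cells) + "\n")

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read genotypes from VCF; the DS field is preferred when present,
        otherwise dosage is the alt-allele count of the GT call."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = np.array(vcf.samples, dtype=object)
        rows, cols = [], []
        for var in vcf:
            alt = var.ALT[0] if var.ALT else "."
            rows.append(
                {
                    "id": var.ID if var.ID not in (None, ".") else
                    f"{var.CHROM}:{var.POS}",
                    "chrom": str(var.CHROM),
                    "pos": int(var.POS),
                    "ref": var.REF,
                    "alt": alt,
                }
            )
            ds = None
            try:
                ds = var.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                col = np.asarray(ds, dtype=np.float64).reshape(-1)
            else:
                gts = var.genotype.array()
                alleles = gts[:, :-1].astype(np.float64)
                alleles[alleles < 0] = np.nan
                col = alleles.sum(axis=1)
            rows[-1]["_col"] = col
            cols.append(col)
        vcf.close()
        if not rows:
            raise ValueError(f"no variants in {path}")
        for r in rows:
            r.pop("_col")
        variants = pd.DataFrame(rows)
        dosages = np.column_stack(cols)
        return cls(samples=samples, variants=variants, dosages=dosages)


@dataclass
class WeightPanel:
    """Named set of per-variant effect weights (one PRS panel).

    ``entries`` uses PGS Catalog scoring-file column names: ``rsID``,
    ``chr_name``, ``chr_position`` (1-based), ``effect_allele``,
    ``other_allele``, ``effect_weight``.
    """

    name: str
    entries: pd.DataFrame
    n_dropped_rows: int = 0
    source: str | None = None

    ENTRY_COLUMNS = (
        "rsID",
        "chr_name",
        "chr_position",
        "effect_allele",
        "other_allele",
        "effect_weight",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.ENTRY_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"weight panel lacks columns {missing}")
        ids = self.entries["rsID"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r} in panel {self.name}")
        w = self.entries["effect_weight"].to_numpy(dtype=np.float64)
        if not np.isfinite(w).all():
            raise ValueError(f"non-finite weight in panel {self.name}")

    @property
    def n_variants(self) -> int:
        return len(self.entries)
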