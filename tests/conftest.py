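import numpy as np
import pandas as pd
import pytest

from metaprs_kit import (
    AncestryModel,
    GenotypeMatrix,
    TraitArchitecture,
    compute_pcs,
    simulate_frequencies,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_weight_panels,
)


def make_genotypes(dosages, chrom="1", ref="A", alt="G", start_pos=100):
    """Toy genotype matrix from an (n_samples, n_variants) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m)],
            "chrom": [chrom] * m,
            "pos": [start_pos + 100 * j for j in range(m)],
            "ref": [ref] * m,
            "alt": [alt] * m,
        }
    )
    samples = np.array([f"S{i + 1:03d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


@pytest.fixture(scope="session")
def two_group_model():
    return AncestryModel(
        group_names=("GRP1", "GRP2"), fst=(0.1, 0.1), group_sizes=(400, 400)
    )


@pytest.fixture(scope="session")
def small_cohort(two_group_model):
    """A reusable two-ancestry cohort: genotypes, labels, panels, truth, PCs."""
    freqs = simulate_frequencies(two_group_model, 300, seed=11)
    genotypes, labels = simulate_genotypes(freqs, two_group_model, seed=12)
    arch = TraitArchitecture()
    panels = simulate_weight_panels(arch, genotypes, seed=13)
    truth = simulate_phenotypes(genotypes, panels, labels, arch, seed=14)
    pcs = compute_pcs(genotypes, n_components=4)
    return {
        "model": two_group_model,
        "arch": arch,
        "genotypes": genotypes,
        "labels": labels,
        "panels": panels,
        "truth": truth,
        "pcs": pcs,
    }
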