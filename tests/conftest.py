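import numpy as np
import pandas as pd
import pytest

from qpcrkit import (
    CtSimSpec,
    DilutionSeries,
    FamilySimSpec,
    GeneSpec,
    rank_homologs,
    simulate_ct,
    simulate_gene_family,
)


@pytest.fixture(scope="session")
def default_series() -> DilutionSeries:
    """Stock 50 ng/ul, factors 10..160, 1 ul per reaction."""
    return DilutionSeries()


@pytest.fixture(scope="session")
def perfect_points(default_series):
    """Noise-free doubling series: one extra cycle per twofold dilution."""
    return [(x, 27.0 + i) for i, x in enumerate(default_series.log_inputs)]


@pytest.fixture(scope="session")
def family():
    """A 600-nt gene family with 6 planted SNPs plus its homolog ranking."""
    records, truth = simulate_gene_family(FamilySimSpec(seed=11))
    homolog_set = rank_homologs(records[0], records[1:])
    return records, truth, homolog_set


def make_stability_table(seed: int, effect: float = 2.0, noise: float = 0.2):
    """Six stable genes plus one gene with a group effect, 2 groups x 6."""
    genes = tuple(GeneSpec(f"stable{i}", noise_sd=noise) for i in range(6))
    genes += (GeneSpec("planted", noise_sd=noise, group_effects={"B": effect}),)
    spec = CtSimSpec(genes=genes, groups={"A": 6, "B": 6}, seed=seed)
    return simulate_ct(spec)[0]


@pytest.fixture()
def stability_table():
    return make_stability_table(seed=42)


@pytest.fixture()
def copies_table():
    """Three genes that are exact copies of each other across 5 samples."""
    rng = np.random.default_rng(5)
    cts = 24.0 + rng.normal(0, 0.5, size=5)
    rows = []
    for gene in ("a", "b", "c"):
        for i, ct in enumerate(cts, start=1):
            rows.append(
                {
                    "sample_id": f"s{i}",
                    "group": "g",
                    "gene": gene,
                    "pair": "F1/R1",
                    "anneal_temp_C": 60.6,
                    "primer_conc": "350",
                    "dilution": "",
                    "bio_rep": 1,
                    "tech_rep": 1,
                    "ct": ct,
                }
            )
    return pd.DataFrame(rows)
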