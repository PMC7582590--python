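import numpy as np
import pandas as pd
import pytest

from ribopulse import simulate
from ribopulse.diffexpr import CountMatrix


@pytest.fixture(scope="session")
def small_transcriptome():
    return simulate.make_transcriptome(40, utr5_length=(60, 120),
                                       cds_codons=(40, 120),
                                       utr3_length=(100, 300), seed=7)


@pytest.fixture()
def toy_transcript():
    # 20 nt 5'UTR, 30 nt CDS, 25 nt 3'UTR
    return simulate.Transcript(
        "toy",
        "TTTTTTTTTTGGGGGGGGGG",
        "ATG" + "GCTGCAGCCGCG" * 2 + "TAA",
        "A" * 25,
    )


@pytest.fixture(scope="session")
def trna_catalog():
    refs, landmarks = simulate.make_trna_references(8, seed=21)
    return refs, landmarks


def make_stable_counts(n_genes=300, dispersion=0.04, depth=1e6, seed=0,
                       conditions=("0h",)):
    """Null (stable-only) mRNA counts over control + the given conditions."""
    genes = [f"G{i}" for i in range(n_genes)]
    modes = {c: simulate.plant_modes(genes, {"stable": 1.0}, seed=seed + i)
             for i, c in enumerate(conditions)}
    truth = simulate.SimTruth(
        genes=genes,
        baseline=simulate.random_baseline(genes, seed=seed + 50),
        modes=modes, dispersion=dispersion)
    return truth, simulate.simulate_counts(truth, depth=depth, seed=seed)


@pytest.fixture()
def toy_count_matrix():
    counts = pd.DataFrame(
        {"mRNA_control_1": [100, 10, 0, 50],
         "mRNA_control_2": [110, 12, 0, 55],
         "mRNA_0h_1": [220, 9, 0, 40],
         "mRNA_0h_2": [190, 11, 0, 60]},
        index=["A", "B", "C", "D"])
    return CountMatrix.from_frame(counts)
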