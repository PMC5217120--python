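import numpy as np
import pandas as pd
import pytest

from exorna import (
    SimulationConfig,
    infer_transmissions,
    mendelian_filter,
    phase_parents,
    segment_blocks,
    simulate_study,
)
from exorna._data import CountMatrix


@pytest.fixture(scope="session")
def study():
    """One full synthetic study shared across tests (fixed seed)."""
    cfg = SimulationConfig(seed=11)
    pedigree, genotypes, annotation, counts, truth = simulate_study(cfg)
    return {
        "config": cfg,
        "pedigree": pedigree,
        "genotypes": genotypes,
        "annotation": annotation,
        "counts": counts,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def haplotype_run(study):
    """Mendelian filter -> phasing -> transmissions -> blocks on the study."""
    filtered, report = mendelian_filter(study["genotypes"], study["pedigree"])
    phased = phase_parents(filtered, study["pedigree"])
    transmissions = infer_transmissions(filtered, phased, study["pedigree"])
    blocks = segment_blocks(transmissions)
    return {
        "filtered": filtered,
        "report": report,
        "phased": phased,
        "transmissions": transmissions,
        "blocks": blocks,
    }


def small_count_matrix(counts: np.ndarray, n_individuals: int | None = None) -> CountMatrix:
    """Counts with paired cell/exosome metadata, first half cells."""
    n = counts.shape[1] // 2
    sample_ids = [f"i{j}_cell" for j in range(n)] + [f"i{j}_exosome" for j in range(n)]
    samples = pd.DataFrame(
        {
            "individual": [f"i{j}" for j in range(n)] * 2,
            "compartment": ["cell"] * n + ["exosome"] * n,
        },
        index=sample_ids,
    )
    df = pd.DataFrame(counts, index=[f"t{i}" for i in range(counts.shape[0])], columns=sample_ids)
    return CountMatrix(df, samples)
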