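import numpy as np
import pandas as pd
import pytest

from chronotx.simulate import SimConfig, cohort_to_frame, simulate_tissue


@pytest.fixture(scope="session")
def small_sim():
    """One synthetic tissue with planted effects: 1000 genes, 300 donors."""
    config = SimConfig(n_donors=300, n_genes=1000, seed=1)
    cohort, truth, matrix = simulate_tissue(config)
    return {
        "config": config,
        "cohort": cohort,
        "truth": {t.gene_id: t for t in truth},
        "matrix": matrix,
        "metadata": cohort_to_frame(cohort),
    }


@pytest.fixture(scope="session")
def null_sim():
    """A tissue with no planted effects at all."""
    config = SimConfig(
        n_donors=200, n_genes=600, frac_daynight=0.0, frac_seasonal=0.0, frac_covariate=0.0, seed=7
    )
    cohort, truth, matrix = simulate_tissue(config)
    return {
        "config": config,
        "matrix": matrix,
        "metadata": cohort_to_frame(cohort),
        "truth": {t.gene_id: t for t in truth},
    }


def make_de_result(calls: dict[str, float], tissue: str = "tissue"):
    """Build a minimal DEResult from gene -> log2fc for sensitive calls.

    Genes mapped to 0 are present but uncalled.
    """
    from chronotx.diffexp import DEResult

    genes = pd.Index(sorted(calls), name="gene")
    lfc = pd.Series({g: v for g, v in calls.items()})
    called = lfc != 0
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": np.where(called, 0.01, 0.5),
            "fdr": np.where(called, 0.05, 0.9),
            "mean_expr": 5.0,
            "call_sensitive": called,
            "call_strict": called,
        },
        index=genes,
    )
    return DEResult(table=table, tissue=tissue)
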