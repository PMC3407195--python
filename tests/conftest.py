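import numpy as np
import pandas as pd
import pytest

import acetylchip as ac


@pytest.fixture(scope="session")
def study():
    """Mid-size synthetic study at generator defaults (2,000 genes)."""
    return ac.simulate_study(ac.SimParams(n_genes=2000), seed=11)


@pytest.fixture(scope="session")
def result(study):
    return ac.analyze(study.probes, study.expression, study.annotation)


def make_toy_probes():
    """4 genes x 5 probes with hand-set p-values and signals.

    Gene layout (WT p-values): gA has two bound probes (0.004, 0.005 —
    boundary), gB one (0.0005), gC none, gD one Unknown-type probe bound.
    TG: only gA keeps one bound probe.
    """
    rows = []
    types = ["Promoter", "Promoter", "Inside", "Inside", "Downstream"]
    pv_wt = {
        "gA": [0.9, 0.004, 0.005, 0.8, 0.7],
        "gB": [0.0005, 0.6, 0.9, 0.99, 0.5],
        "gC": [0.7, 0.8, 0.9, 0.95, 0.99],
        "gD": [0.5, 0.6, 0.7, 0.8, 0.001],
    }
    pv_tg = {
        "gA": [0.9, 0.002, 0.8, 0.8, 0.7],
        "gB": [0.6, 0.6, 0.9, 0.99, 0.5],
        "gC": [0.7, 0.8, 0.9, 0.95, 0.99],
        "gD": [0.5, 0.6, 0.7, 0.8, 0.9],
    }
    for gi, gene in enumerate(["gA", "gB", "gC", "gD"]):
        for j in range(5):
            start = 1000 * (gi + 1) + 200 * j
            ptype = "Unknown" if gene == "gD" and j == 4 else types[j]
            rows.append({
                "probe_id": f"{gene}_p{j}",
                "gene_id": gene,
                "chromosome": "chr1",
                "start": start,
                "end": start + 60,
                "probe_type": ptype,
                "signal_wt_1": 1.0 + 0.1 * j,
                "signal_wt_2": 1.2 + 0.1 * j,
                "signal_tg_1": 0.5 + 0.1 * j,
                "signal_tg_2": 0.7 + 0.1 * j,
                "pvalue_wt": pv_wt[gene][j],
                "pvalue_tg": pv_tg[gene][j],
            })
    return pd.DataFrame(rows)


@pytest.fixture
def toy_probes():
    return make_toy_probes()
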