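import numpy as np
import pandas as pd
import pytest

from murideconv import (
    ExpressionMatrix,
    SCSimParams,
    SignatureMatrix,
    build_signature_from_sc,
    simulate_dataset,
)


def make_expr(values, genes=None, samples=None, unit="TPM"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), unit=unit
    )


def random_signature(rng, n_genes=20, n_types=3, equal_colsums=True):
    """A dense random signature; columns normalized to equal totals so an
    exact mixture b = S f is recovered as f itself."""
    S = rng.uniform(1.0, 100.0, size=(n_genes, n_types))
    if equal_colsums:
        S = S / S.sum(axis=0) * 1e6
    return SignatureMatrix(
        pd.DataFrame(
            S,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"ct{j}" for j in range(n_types)],
        )
    )


@pytest.fixture(scope="session")
def pipeline_run():
    """The reference benchmark pipeline: simulated single-cell reference
    (5 types, 2000 genes, 40 planted markers/type at fold 6, NB dispersion
    2, log-normal library sizes sigma 0.3, seed 1), 20 pseudo-bulk samples
    of 500 cells, and the signature/markers built back from the same
    reference."""
    params = SCSimParams(seed=1)
    ds, sc, labels = simulate_dataset(params, n_samples=20, n_cells_per_sample=500)
    sig, markers = build_signature_from_sc(
        sc, labels, n_markers_per_type=40, min_fold=2.0
    )
    return {"dataset": ds, "sc": sc, "labels": labels,
            "signature": sig, "markers": markers}
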