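import numpy as np
import pandas as pd
import pytest

from tcauc import TimeCourseExperiment


@pytest.fixture
def tiny_experiment() -> TimeCourseExperiment:
    """3 genes x 2 conditions x 2 time points x 2 replicates."""
    samples = pd.DataFrame(
        [
            (f"{cond}_t{t}_r{r}", cond, float(t), r)
            for cond in ("Norm", "CHyp")
            for t in (0, 24)
            for r in (1, 2)
        ],
        columns=["sample_id", "condition", "time_h", "replicate"],
    )
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.uniform(0.5, 50.0, size=(3, len(samples))).round(4),
        index=pd.Index(["Arg1", "Il6", "Tnf"], name="gene_id"),
        columns=samples["sample_id"],
    )
    return TimeCourseExperiment(values=values, samples=samples)


def make_contrast(ratios: dict[str, float], name: str = "c"):
    """AUCContrast with prescribed log2 ratios (pseudocount-free algebra)."""
    from tcauc import AUCContrast

    genes = list(ratios)
    auc_r = np.full(len(genes), 100.0)
    auc_t = auc_r * 2.0 ** np.array([ratios[g] for g in genes])
    table = pd.DataFrame(
        {
            "auc_treatment": auc_t - 1e-9,  # keep log2 ratio ~exact despite c
            "auc_reference": auc_r,
            "log2_ratio": [ratios[g] for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return AUCContrast(
        table=table, name=name, treatment="T", reference="R",
        pseudocount=1e-12, time_grid=(0.0, 24.0),
    )
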