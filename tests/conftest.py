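import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import memoryscreen as ms

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_expression() -> ms.ExpressionMatrix:
    """3 genes x 4 samples with distinct, easy-to-track values."""
    return ms.ExpressionMatrix(
        gene_ids=["TP53", "EGFR", "KRAS"],
        sample_ids=["S1", "S2", "S3", "S4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [10.0, 20.0, 30.0, 40.0],
                [5.0, 5.0, 5.0, 5.0],
            ]
        ),
    )


@pytest.fixture
def tiny_survival() -> ms.SurvivalTable:
    return ms.SurvivalTable(
        sample_ids=["S1", "S2", "S3", "S4"],
        time=[10.0, 20.0, 30.0, 40.0],
        event=[1, 0, 1, 0],
    )


@pytest.fixture
def toy_maf() -> ms.MutationTable:
    """20 records over 4 samples for hand-tallied TMB checks."""
    rows = []
    plan = {
        "S1": [("TP53", "Missense_Mutation")] * 3 + [("TP53", "Silent")],
        "S2": [("EGFR", "Nonsense_Mutation"), ("KRAS", "Frame_Shift_Del")],
        "S3": [("TP53", "Silent")] * 2
        + [("EGFR", "Splice_Site"), ("BRAF", "In_Frame_Ins"), ("KRAS", "Missense_Mutation")],
        "S4": [("ALK", "Missense_Mutation")] * 9,
    }
    for sample, muts in plan.items():
        for gene, vc in muts:
            rows.append({"gene": gene, "sample": sample, "variant_class": vc})
    return ms.MutationTable(records=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-program cohort small enough for repeated screening in tests."""
    spec = ms.CohortSpec(n_samples=120, n_genes=60, n_prognostic=6, seed=42)
    expr, surv, truth = ms.generate_cohort(spec)
    return expr, surv, truth


@pytest.fixture(scope="session")
def small_tensor(small_cohort):
    expr, surv, _ = small_cohort
    plan = ms.build_gradient_plan(len(surv))
    return ms.run_permutation_screen(expr, surv, plan, n_perm=40, seed=42)
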