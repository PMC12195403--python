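import numpy as np
import pandas as pd
import pytest

from pm3.expression_io import ExpressionStudy
from pm3.gene_model import bundled_panel
from pm3.synthetic_data import SimGene, SimSpec, simulate


@pytest.fixture(scope="session")
def panel():
    return bundled_panel()


@pytest.fixture(scope="session")
def panel_spec(panel):
    """Small deterministic cohort over the 26 bundled panel genes."""
    from pm3.synthetic_data import REFERENCE_SHIFTS

    rng = np.random.default_rng(42)
    genes = tuple(
        SimGene(
            symbol=a.symbol,
            baseline=float(rng.uniform(20.0, 200.0)),
            shift=REFERENCE_SHIFTS[a.symbol],
            domain=a.domain,
            cofactors=tuple(sorted(a.cofactors)),
            compartment=a.compartment,
        )
        for a in panel
    )
    return SimSpec(genes=genes, seed=42)


@pytest.fixture(scope="session")
def panel_study(panel_spec):
    study, _ = simulate(panel_spec)
    return study


def make_study(values, case_ids, control_ids, genes=None):
    """Build a validated study from a plain array (helper for tests)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    cols = list(case_ids) + list(control_ids)
    labels = {s: "case" for s in case_ids}
    labels.update({s: "control" for s in control_ids})
    df = pd.DataFrame(values, index=genes, columns=cols)
    df.index.name = "symbol"
    return ExpressionStudy(df, labels)
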