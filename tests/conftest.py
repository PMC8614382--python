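import numpy as np
import pytest

from flockbench import DEAProblem, FarmRecord, FarmType, solve_all
from flockbench.synthetic import default_spec, generate_population


def make_record(farm_id="f1", farm_type=FarmType.FRENCH_EXTENSIVE, ewes=400,
                labor=1800.0, variable_cost=28000.0, fixed_cost=31000.0,
                gross_revenue=62000.0, **optional) -> FarmRecord:
    return FarmRecord(
        farm_id=farm_id, farm_type=farm_type, ewes=ewes, labor=labor,
        variable_cost=variable_cost, fixed_cost=fixed_cost,
        gross_revenue=gross_revenue, **optional,
    )


@pytest.fixture(scope="session")
def french_extensive_population():
    """One calibrated synthetic population with its ground truth."""
    spec = default_spec(FarmType.FRENCH_EXTENSIVE, seed=20240915)
    records, te_true = generate_population(spec)
    return spec, records, te_true


@pytest.fixture(scope="session")
def solved_population(french_extensive_population):
    """The same population with its DEA results (both phases)."""
    spec, records, te_true = french_extensive_population
    results = solve_all(DEAProblem.from_records(records))
    return spec, records, te_true, results
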