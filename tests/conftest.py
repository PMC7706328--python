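import numpy as np
import pandas as pd
import pytest

from sdssm.datamodel import SCHEMA_COLUMNS, SequenceTable
from sdssm.synthetic import GreenhouseSimConfig, simulate_greenhouse


def make_table(rows):
    """Build a SequenceTable from a list of row dicts (schema defaults)."""
    defaults = {
        "bed_id": 1, "step_id": 1, "date": "2017-08-28", "day_index": 0,
        "temperature": 25.0, "solar_radiation": 15.0, "vpd": 0.8,
        "co2": 400.0, "elapsed_days": 0.0, "accum_temp": 25.0,
        "stem_diameter": 8.0, "sugar_brix": 6.0,
    }
    frame = pd.DataFrame([{**defaults, **row} for row in rows])
    return SequenceTable(frame[SCHEMA_COLUMNS])


@pytest.fixture(scope="session")
def greenhouse_default():
    """One default simulated season (16 beds x 3 steps x 83 days)."""
    return simulate_greenhouse(GreenhouseSimConfig(), seed=20_17)


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast season for training smoke tests."""
    cfg = GreenhouseSimConfig(n_beds=4, n_steps=1, n_days=24)
    return simulate_greenhouse(cfg, seed=3)


def central_diff(fn, params: dict, eps: float = 1e-6, per_param: int = 3,
                 rng=None, atol: float = 1e-8, rtol: float = 1e-4) -> float:
    """Worst normalized gradient error against central finite differences.

    Uses the standard mixed criterion |num - ana| <= rtol*max(|num|,|ana|)
    + atol, reported as |num - ana| / (max(|num|,|ana|) + atol/rtol) so a
    return value below ``rtol`` means the check passes; the absolute floor
    keeps finite-difference truncation noise on near-zero gradients from
    dominating.  ``fn`` returns the scalar loss; ``params`` maps names to
    Tensors whose ``grad`` fields hold analytic gradients of that loss.
    """
    rng = rng or np.random.default_rng(0)
    worst = 0.0
    for name in sorted(params):
        p = params[name]
        ana_full = p.grad if p.grad is not None else np.zeros_like(p.value)
        flat = p.value.ravel()
        idxs = rng.choice(flat.size, size=min(per_param, flat.size),
                          replace=False)
        for idx in idxs:
            orig = flat[idx]
            flat[idx] = orig + eps
            fp = float(fn())
            flat[idx] = orig - eps
            fm = float(fn())
            flat[idx] = orig
            num = (fp - fm) / (2.0 * eps)
            ana = ana_full.ravel()[idx]
            err = abs(num - ana) / (max(abs(num), abs(ana)) + atol / rtol)
            worst = max(worst, err)
    return worst
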