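import numpy as np
import pytest

from oxiswitch.peaktable import Feature, FeatureTable, Injection
from oxiswitch.simulate import SimulationParams, simulate_study


def build_table(
    intensities,
    roles,
    mz=None,
    rt=None,
    mode="positive",
    patients=None,
    timepoints=None,
):
    """Construct a small FeatureTable from an intensity matrix and role list.

    Study injections get synthetic patient/timepoint labels unless given.
    """
    intensities = np.asarray(intensities, dtype=float)
    nf, ni = intensities.shape
    assert len(roles) == ni
    mz = mz if mz is not None else [100.0 + i for i in range(nf)]
    rt = rt if rt is not None else [60.0 + i for i in range(nf)]
    features = [Feature(f"F{i:03d}", float(mz[i]), float(rt[i]), mode) for i in range(nf)]
    tp_cycle = ["pre", "5min", "6h", "24h", "48h", "72h", "96h"]
    injections = []
    n_study = 0
    for j, role in enumerate(roles):
        if role == "study":
            pid = patients[n_study] if patients else f"P{n_study // 7 + 1:02d}"
            tp = timepoints[n_study] if timepoints else tp_cycle[n_study % 7]
            injections.append(Injection(f"I{j:03d}", j + 1, role, pid, tp))
            n_study += 1
        else:
            injections.append(Injection(f"I{j:03d}", j + 1, role))
    return FeatureTable(features, injections, intensities)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    return simulate_study(SimulationParams(rng_seed=7, n_features_per_mode=120))


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(rng_seed=7, n_features_per_mode=120)
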