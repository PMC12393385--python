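import numpy as np
import pytest

import permkit as pk


@pytest.fixture(scope="session")
def small_run():
    """A short synthetic run with default entry statistics and few bulk ions."""
    spec = pk.SyntheticSpec(duration=40.0, seed=11, n_bulk=6)
    bundle, truth = pk.generate_run(spec)
    return spec, bundle, truth


@pytest.fixture(scope="session")
def table1_summaries():
    return [pk.summary_from_counts(c) for c in pk.table1_fixture()]


def make_trace(zs, ion_id="i0", species="K+", dt=0.1, xy=(0.0, 0.0)):
    """Straight-line helper: one ion at fixed x, y with the given z samples."""
    zs = np.asarray(zs, dtype=float)
    times = dt * np.arange(len(zs))
    pos = np.column_stack([np.full_like(zs, xy[0]), np.full_like(zs, xy[1]), zs])
    return pk.IonTrace(ion_id=ion_id, species=species, times=times, positions=pos)
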