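import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from paleodiv import AgeDepthModel, SampleSeries

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: cm of sediment per year used by the linear test model (sed rate 0.1 cm/yr)
LINEAR_RATE = 0.1


def make_record(age_bounds, counts, volumes=None, taxa=None, groups=None,
                rate=LINEAR_RATE):
    """Build a contiguous SampleSeries plus an exactly linear age-depth model.

    ``age_bounds`` are the n+1 increasing sample boundary ages (cal BP);
    depth = age * rate, so sample ages derived through the model reproduce
    the boundaries exactly.
    """
    age_bounds = np.asarray(age_bounds, dtype=float)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n = len(age_bounds) - 1
    assert counts.shape[0] == n
    if volumes is None:
        volumes = np.full(n, 10.0)
    if taxa is None:
        taxa = [f"t{i}" for i in range(counts.shape[1])]
    depths = age_bounds * rate
    model = AgeDepthModel(
        depths=np.array([depths[0], depths[-1]]),
        ages=np.array([age_bounds[0], age_bounds[-1]]),
    )
    samples = SampleSeries(
        counts=pd.DataFrame(
            counts,
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            columns=taxa,
        ),
        depth_top=depths[:-1],
        depth_bottom=depths[1:],
        volume=np.asarray(volumes, dtype=float),
        groups=groups,
    )
    return samples, model


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def toy_triplet(tmp_path):
    """A 3-sample, 2-taxon CSV triplet on disk."""
    (tmp_path / "counts.csv").write_text(
        "sample_id,Larix,Poaceae\na,4,1\nb,0,2\nc,3,3\n"
    )
    (tmp_path / "meta.csv").write_text(
        "sample_id,depth_top_cm,depth_bottom_cm,volume_cm3\n"
        "a,0,1,10\nb,1,2,10\nc,2,3,12\n"
    )
    (tmp_path / "agedepth.csv").write_text("depth_cm,age_calBP\n0,0\n3,300\n")
    (tmp_path / "groups.csv").write_text("taxon,group\nLarix,tree\nPoaceae,herb\n")
    return tmp_path
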