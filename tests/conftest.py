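import numpy as np
import pytest

from padcyto import NucleusImage, NucleusRecord, PADRecord


def make_image(blue=None, red=None, green=None, px_per_um=1.0, field_id="f"):
    return NucleusImage(blue=blue, red=red, green=green, px_per_um=px_per_um,
                        field_id=field_id)


def make_nucleus(mask, blue=None, nucleus_id=0):
    ifi = float(np.asarray(blue, dtype=float)[mask].sum()) if blue is not None else 0.0
    return NucleusRecord(
        nucleus_id=nucleus_id,
        mask=np.asarray(mask, bool),
        area_px=int(np.asarray(mask).sum()),
        area_um2=float(np.asarray(mask).sum()),
        dapi_ifi=ifi,
    )


def make_pad(area_um2, centromere_count=0, nucleus_id=0, pad_id=0):
    """PADRecord carrier for fit functions (mask geometry irrelevant)."""
    return PADRecord(
        pad_id=pad_id,
        nucleus_id=nucleus_id,
        mask=np.ones((1, 1), bool),
        area_px=max(int(round(area_um2)), 1),
        area_um2=float(area_um2),
        centromere_count=int(centromere_count),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, well-separated population: the exact-recovery regime."""
    import padcyto as pc

    params = pc.PopulationParams(
        n_cells=40,
        noise_sd=0.0,
        count_law=(4, 10),
        dirichlet_alpha=5.0,
        seed=101,
    )
    images, truth = pc.simulate_population(params)
    return params, images, truth
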