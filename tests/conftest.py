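import numpy as np
import pytest

from choreo.dataset import CellRecord, StrainDataset
from choreo.genome import default_locus_panel
from choreo.orient import orient_dataset
from choreo.simulate import preset_scenario, sample_population


@pytest.fixture(scope="session")
def wt_scenario():
    return preset_scenario("WT")


@pytest.fixture(scope="session")
def wt_full(wt_scenario):
    """Full 19-channel WT snapshot population with ground truth."""
    return sample_population(wt_scenario, n=800, seed=5)


@pytest.fixture(scope="session")
def wt_pair(wt_scenario):
    """ori/ter dual-label WT strain (the classic orientation pair)."""
    return sample_population(wt_scenario, n=800, seed=3, channels=("ori_I", "ter_I"))


@pytest.fixture(scope="session")
def wt_pair_oriented(wt_pair):
    ds, _ = wt_pair
    return orient_dataset(ds)


def flip_all(ds: StrainDataset) -> StrainDataset:
    """Reverse the stored axis of every cell (tests axis-direction invariance)."""
    out = ds.copy()
    out.cells = [c.flipped() for c in out.cells]
    return out


def make_cell(cell_id, length, foci, orientation="unoriented"):
    return CellRecord(
        cell_id=cell_id,
        length_um=length,
        foci={ch: tuple(xs) for ch, xs in foci.items()},
        orientation=orientation,
    )


def make_dataset(cells, channels=("ori_I", "ter_I"), strain_id="toy"):
    panel = default_locus_panel()
    return StrainDataset(
        strain_id=strain_id,
        channel_locus_map={ch: panel[ch] for ch in channels},
        cells=list(cells),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
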