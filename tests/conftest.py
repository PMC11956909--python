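import numpy as np
import pandas as pd
import pytest

import densityatlas as da


@pytest.fixture(scope="session")
def small_atlas() -> da.LabelVolume:
    """A 1x1x1 mm two-region atlas at 50 μm voxels."""
    spec = da.AtlasSpec(
        extent_um=(1000.0, 1000.0, 1000.0),
        spacing_um=(50.0, 50.0, 50.0),
        regions=[
            da.RegionSpec(1, "cube", da.Box((100, 100, 100), (500, 500, 500))),
            da.RegionSpec(2, "ball", da.Sphere((750, 750, 750), 200.0)),
        ],
    )
    return da.build_toy_atlas(spec)


@pytest.fixture(scope="session")
def demo_atlas() -> da.LabelVolume:
    return da.build_toy_atlas(da.demo_atlas_spec())


def points_frame(coords: np.ndarray, cell_type: str = "t",
                 subject_id: str = "s1", group: str = "NA") -> pd.DataFrame:
    coords = np.atleast_2d(coords)
    return pd.DataFrame({
        "x_um": coords[:, 0], "y_um": coords[:, 1], "z_um": coords[:, 2],
        "cell_type": cell_type, "subject_id": subject_id, "group": group,
    })
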