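import numpy as np
import pytest
import tifffile

from quadframe import PopulationGrid


def make_geotiff(
    path,
    values,
    cell_size=100.0,
    origin=(0.0, None),
    epsg=32638,
    nodata=None,
    geographic=False,
):
    """Write a GeoTIFF directly with tifffile (independent of the package
    writer) so reader tests check against externally-produced files."""
    values = np.asarray(values, dtype=np.float64)
    origin_x, origin_y = origin
    if origin_y is None:
        origin_y = values.shape[0] * cell_size
    model_type = 2 if geographic else 1
    geokeys = [1024, 0, 1, model_type, 1025, 0, 1, 1]
    if geographic:
        geokeys += [2048, 0, 1, 4326]
    else:
        geokeys += [3072, 0, 1, epsg]
    header = [1, 1, 0, len(geokeys) // 4]
    extratags = [
        (33550, "d", 3, (cell_size, cell_size, 0.0), True),
        (33922, "d", 6, (0.0, 0.0, 0.0, origin_x, origin_y, 0.0), True),
        (34735, "H", len(header) + len(geokeys), tuple(header + geokeys), True),
    ]
    if nodata is not None:
        extratags.append((42113, "s", 0, str(nodata), True))
    tifffile.imwrite(path, values, extratags=extratags)
    return path


@pytest.fixture
def geotiff_factory(tmp_path):
    def factory(values, name="test.tif", **kwargs):
        return make_geotiff(tmp_path / name, values, **kwargs)

    return factory


def grid_from(values, cell_size=100.0, mask=None, origin_x=0.0):
    values = np.asarray(values, dtype=np.float64)
    return PopulationGrid(
        values,
        cell_size,
        origin_x=origin_x,
        origin_y=values.shape[0] * cell_size,
        mask=mask,
    )


@pytest.fixture
def ones_grid():
    def factory(n_rows, n_cols=None, cell_size=100.0):
        n_cols = n_cols or n_rows
        return grid_from(np.ones((n_rows, n_cols)), cell_size)

    return factory
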