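import logging

import numpy as np
import pytest

from nbudget import (
    GridMap,
    GridTransform,
    RunConfig,
    SynthSpec,
    default_library,
    generate,
    run_pipeline,
)

logging.getLogger("nbudget").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic country (200x200 grid, 100 counties), seed 1."""
    return generate(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """Same country written to disk, for file-based stages."""
    outdir = tmp_path_factory.mktemp("bundle")
    bundle = generate(SynthSpec(seed=1), outdir=outdir)
    return bundle


@pytest.fixture(scope="session")
def coeffs():
    return default_library()


def make_run_config(bundle, out_dir) -> RunConfig:
    p = bundle.paths
    return RunConfig(
        admin_csv=p["admin_csv"],
        landuse_tif=p["landuse_tif"],
        region_tif=p["region_tif"],
        proxy_tifs={k.removeprefix("proxy_"): v
                    for k, v in p.items() if k.startswith("proxy_")},
        column_ncs={"NO2": p["columns_no2"], "NH3": p["columns_nh3"]},
        watersheds_geojson=p["watersheds_geojson"],
        coefficients_yaml=p["coefficients_yaml"],
        deposition_totals=bundle.deposition_totals,
        out_dir=out_dir,
        log_level="ERROR",
    )


@pytest.fixture(scope="session")
def run_result(bundle_dir, tmp_path_factory):
    """One full pipeline execution on the synthetic bundle."""
    out = tmp_path_factory.mktemp("pipeline-out")
    return run_pipeline(make_run_config(bundle_dir, out))


@pytest.fixture
def small_grid():
    """A tiny 2x3 grid: one region, unit transform."""
    transform = GridTransform(x0=0.0, y0=2000.0, dx=1000.0, dy=1000.0)

    def _make(values, nodata=None, dtype=None):
        arr = np.asarray(values, dtype=dtype)
        return GridMap(arr, transform, nodata=nodata)

    return _make
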