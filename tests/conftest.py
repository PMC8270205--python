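import numpy as np
import pandas as pd
import pytest

from domwheel import fixtures, ingest


@pytest.fixture(scope="session")
def bundle():
    """Two-cluster synthetic study bundle (50 samples per cluster, seed 1)."""
    return fixtures.synth_bundle(seed=1, n_per_cluster=50)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    fixtures.write_bundle(bundle, out)
    return out


@pytest.fixture(scope="session")
def dataset(bundle_dir):
    return ingest.read_dataset(
        bundle_dir / "spectra.csv",
        bundle_dir / "chem.csv",
        bundle_dir / "lcocd.csv",
        bundle_dir / "meta.csv",
    )


@pytest.fixture(scope="session")
def metrics(dataset):
    return ingest.compute_metrics(dataset)


@pytest.fixture(scope="session")
def labels(bundle):
    return dict(zip(bundle["labels"]["sample_id"], bundle["labels"]["cluster"]))


def exp_spectrum(a0=30.0, s=0.0185, lam_ref=275.0, grid=None, path_length=0.01,
                 sample_id="exp"):
    """Noise-free single-exponential spectrum (decadal absorbance)."""
    from domwheel.datatypes import Spectrum
    from domwheel.optics import LN10

    if grid is None:
        grid = np.arange(200.0, 800.0 + 1e-9, 5.0)
    a = a0 * np.exp(-s * (grid - lam_ref))
    return Spectrum(
        sample_id=sample_id,
        wavelengths=grid,
        absorbance=a * path_length / LN10,
        path_length=path_length,
    )


@pytest.fixture
def tiny_csvs(tmp_path):
    """Minimal hand-written 3-sample CSV bundle for ingest tests."""
    grid = np.arange(250.0, 500.0 + 1e-9, 5.0)
    rows = []
    for sid, a0, s in [("s1", 30.0, 0.015), ("s2", 10.0, 0.020), ("s3", 50.0, 0.010)]:
        a = a0 * np.exp(-s * (grid - 275.0)) * 0.01 / np.log(10)
        rows.extend(
            {"sample_id": sid, "wavelength_nm": wl, "absorbance": ab,
             "path_length_m": 0.01}
            for wl, ab in zip(grid, a)
        )
    pd.DataFrame(rows).to_csv(tmp_path / "spectra.csv", index=False)
    pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "doc_mgC_L": [5.0, 10.0, 2.0],
            "tdn_mgN_L": [1.0, 0.8, 0.5],
            "no3_mgN_L": [0.30, 0.1, 0.05],
            "no2_mgN_L": [0.02, 0.01, 0.01],
            "nh4_mgN_L": [0.18, 0.05, 0.04],
        }
    ).to_csv(tmp_path / "chem.csv", index=False)
    pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "bp_pct": [5.0, 8.0, 3.0],
            "hsf_pct": [60.0, 40.0, 70.0],
            "bb_pct": [15.0, 20.0, 10.0],
            "lmwn_pct": [10.0, 20.0, 8.0],
            "lmwa_pct": [2.0, 5.0, 1.0],
            "hs_mw_g_mol": [800.0, 500.0, 900.0],
        }
    ).to_csv(tmp_path / "lcocd.csv", index=False)
    pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "site": ["YK", "YK", "ELA"],
            "hydro_setting": ["groundwater", "lake", "creek"],
            "date": ["2019-07-01", "2019-07-02", "2019-07-03"],
        }
    ).to_csv(tmp_path / "meta.csv", index=False)
    return tmp_path
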