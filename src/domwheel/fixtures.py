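"""Synthetic datasets: single-exponential spectra and two-cluster bundles.

Real CDOM absorption spectra decay approximately exponentially with
wavelength; the generator produces

    a(lambda) = a0 * exp(-s * (lambda - 275))     [m^-1]

converted to decadal absorbance over the cuvette path length, with optional
multiplicative lognormal noise (relative instrument error; keeps A > 0).

``synth_dataset`` emulates the two compositional end members seen in
surface- and groundwater surveys: an organic-rich groundwater-like cluster
(high SUVA, HSF and DOC:DON, low spectral slope) and a photolyzed-like
cluster (the converse).  Cluster targets are drawn first and the spectra and
chemistry are then *back-solved* so each sample's true SUVA, S275-295 and
DOC:DON equal its target exactly (before noise) — the generating labels and
values are exact ground truth for round-trip tests.

Default cluster centers sit well inside the observed field ranges
(SUVA 1.1-21 L mg^-1 m^-1, S 0.005-0.032 nm^-1, DOC:DON 9-124, HSF 14-85%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import Spectrum
from .optics import LN10

logger = logging.getLogger(__name__)

#: Default 5 nm instrument grid, 200-800 nm.
DEFAULT_GRID = np.arange(200.0, 800.0 + 1e-9, 5.0)
DEFAULT_PATH_LENGTH = 0.01  # 1 cm cuvette, in m

#: Observed field ranges used to truncate cluster draws.
FIELD_RANGES = {
    "suva": (1.1, 21.0),
    "s275_295": (0.005, 0.032),
    "doc_don": (9.0, 124.0),
    "hsf": (14.0, 85.0),
}


@dataclass(frozen=True)
class ClusterSpec:
    """Mean and standard deviation of each target metric for one cluster."""

    suva: tuple[float, float]
    s275_295: tuple[float, float]
    hsf: tuple[float, float]
    doc_don: tuple[float, float]
    doc_log_mean: float  # mean of ln(DOC mg C/L)
    doc_log_sd: float
    hs_mw: tuple[float, float]
    sites: tuple[str, ...]
    hydro_settings: tuple[str, ...]


@dataclass(frozen=True)
class ClusterParams:
    """Generator configuration; the seed is mandatory."""

    seed: int
    n_per_cluster: int = 50
    noise_sigma: float = 0.01  # multiplicative (lognormal) absorbance noise
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    path_length: float = DEFAULT_PATH_LENGTH
    groundwater_like: ClusterSpec = ClusterSpec(
        suva=(9.0, 1.5),
        s275_295=(0.011, 0.0015),
        hsf=(72.0, 6.0),
        doc_don=(90.0, 15.0),
        doc_log_mean=np.log(30.0),
        doc_log_sd=0.5,
        hs_mw=(900.0, 100.0),
        sites=("YK", "ELA", "DL"),
        hydro_settings=("groundwater",),
    )
    photolyzed_like: ClusterSpec = ClusterSpec(
        suva=(2.8, 0.6),
        s275_295=(0.026, 0.003),
        hsf=(28.0, 6.0),
        doc_don=(18.0, 4.0),
        doc_log_mean=np.log(5.0),
        doc_log_sd=0.5,
        hs_mw=(500.0, 80.0),
        sites=("YK", "ELA", "DL"),
        hydro_settings=("pond", "lake"),
    )

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory (no silent nondeterminism)")
        for spec in (self.groundwater_like, self.photolyzed_like):
            for name in ("suva", "s275_295", "hsf", "doc_don", "hs_mw"):
                if getattr(spec, name)[1] <= 0:
                    raise ValueError(f"cluster spread for {name!r} must be > 0")


def synth_spectrum(
    a0: float,
    s: float,
    grid: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    path_length: float = DEFAULT_PATH_LENGTH,
    sample_id: str = "synth",
) -> Spectrum:
    """Single-exponential decadal spectrum with optional lognormal noise.

    ``a0`` is the Naperian amplitude (m^-1) at the 275 nm reference;
    A(lambda) = a0 * exp(-s (lambda - 275)) * L / ln(10), each point
    multiplied by exp(N(0, sigma)) noise.  Exact exponential when
    ``noise_sigma`` is 0.
    """
    if not (a0 > 0):
        raise ValueError(f"a0 must be > 0, got {a0}")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    a = a0 * np.exp(-s * (grid - 275.0))
    A = a * path_length / LN10
    if noise_sigma > 0:
        if seed is None:
            raise ValueError("seed is mandatory when noise_sigma > 0")
        rng = np.random.default_rng(seed)
        A = A * np.exp(rng.normal(0.0, noise_sigma, size=A.shape))
    return Spectrum(
        sample_id=sample_id, wavelengths=grid, absorbance=A, path_length=path_length
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal draws redrawn into [lo, hi] (rejection; bounds are loose)."""
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def synth_dataset(params: ClusterParams) -> dict[str, pd.DataFrame]:
    """Generate the four-file CSV bundle plus ground-truth cluster labels.

    Returns dict with keys ``spectra``, ``chem``, ``lcocd``, ``meta``,
    ``labels``, ``targets`` (DataFrames ready for :func:`write_bundle`).
    """
    rng = np.random.default_rng(params.seed)
    spectra_rows, chem_rows, lcocd_rows, meta_rows, label_rows, target_rows = (
        [], [], [], [], [], []
    )
    base_date = pd.Timestamp("2019-07-01")

    for cluster, spec, prefix in (
        ("groundwater_like", params.groundwater_like, "gw"),
        ("photolyzed_like", params.photolyzed_like, "ph"),
    ):
        n = params.n_per_cluster
        suva = _truncated_normal(rng, *spec.suva, *FIELD_RANGES["suva"], n)
        s = _truncated_normal(rng, *spec.s275_295, *FIELD_RANGES["s275_295"], n)
        hsf = _truncated_normal(rng, *spec.hsf, *FIELD_RANGES["hsf"], n)
        ratio = _truncated_normal(rng, *spec.doc_don, *FIELD_RANGES["doc_don"], n)
        doc = np.exp(rng.normal(spec.doc_log_mean, spec.doc_log_sd, n))
        hs_mw = np.clip(rng.normal(*spec.hs_mw, n), 200.0, 2000.0)

        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            # spectrum back-solved so a(255)/DOC = target SUVA exactly
            a255 = suva[i] * doc[i]
            a275 = a255 * np.exp(-s[i] * (275.0 - 255.0))
            spec_i = synth_spectrum(
                a0=a275,
                s=s[i],
                grid=params.grid,
                noise_sigma=params.noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
                path_length=params.path_length,
                sample_id=sid,
            )
            spectra_rows.extend(
                {
                    "sample_id": sid,
                    "wavelength_nm": wl,
                    "absorbance": ab,
                    "path_length_m": params.path_length,
                }
                for wl, ab in zip(spec_i.wavelengths, spec_i.absorbance)
            )

            # chemistry back-solved so the molar DOC:DON hits the target
            don = (doc[i] / 12.011) * 14.007 / ratio[i]
            no3 = rng.uniform(0.01, 0.2)
            no2 = rng.uniform(0.001, 0.02)
            nh4 = rng.uniform(0.005, 0.1)
            chem_rows.append(
                {
                    "sample_id": sid,
                    "doc_mgC_L": doc[i],
                    "tdn_mgN_L": don + no3 + no2 + nh4,
                    "no3_mgN_L": no3,
                    "no2_mgN_L": no2,
                    "nh4_mgN_L": nh4,
                }
            )

            # remaining LC-OCD fractions share ~92% of the non-HSF balance
            rest = 100.0 - hsf[i]
            w = rng.dirichlet([2.0, 3.0, 3.0, 1.0])
            bp, bb, lmwn, lmwa = rest * 0.92 * w
            lcocd_rows.append(
                {
                    "sample_id": sid,
                    "bp_pct": bp,
                    "hsf_pct": hsf[i],
                    "bb_pct": bb,
                    "lmwn_pct": lmwn,
                    "lmwa_pct": lmwa,
                    "hs_mw_g_mol": hs_mw[i],
                }
            )

            meta_rows.append(
                {
                    "sample_id": sid,
                    "site": spec.sites[i % len(spec.sites)],
                    "hydro_setting": spec.hydro_settings[i % len(spec.hydro_settings)],
                    "date": (base_date + pd.Timedelta(days=i)).date().isoformat(),
                }
            )
            label_rows.append({"sample_id": sid, "cluster": cluster})
            target_rows.append(
                {
                    "sample_id": sid,
                    "suva": suva[i],
                    "s275_295": s[i],
                    "hsf": hsf[i],
                    "doc_don": ratio[i],
                    "doc": doc[i],
                }
            )

    return {
        "spectra": pd.DataFrame(spectra_rows),
        "chem": pd.DataFrame(chem_rows),
        "lcocd": pd.DataFrame(lcocd_rows),
        "meta": pd.DataFrame(meta_rows),
        "labels": pd.DataFrame(label_rows),
        "targets": pd.DataFrame(target_rows),
    }


def write_bundle(bundle: dict[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write the bundle CSVs (deterministic bytes for a given seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in bundle.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.12g", lineterminator="\n")
        paths[name] = p
    return paths


def synth_bundle(seed: int, n_per_cluster: int = 50, **kwargs) -> dict[str, pd.DataFrame]:
    """Convenience wrapper: default two-cluster bundle for a seed."""
    params = ClusterParams(seed=seed, n_per_cluster=n_per_cluster, **kwargs)
    return synth_dataset(params)
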