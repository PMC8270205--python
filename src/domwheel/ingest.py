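"""Read, validate, and join the four CSV inputs; build the metric table.

Input schemas (comma-separated, UTF-8, header row required, "." decimal):

* ``spectra.csv``  — long format: ``sample_id,wavelength_nm,absorbance,path_length_m``
* ``chem.csv``     — ``sample_id,doc_mgC_L,tdn_mgN_L,no3_mgN_L,no2_mgN_L,nh4_mgN_L``
* ``lcocd.csv``    — ``sample_id,bp_pct,hsf_pct,bb_pct,lmwn_pct,lmwa_pct,hs_mw_g_mol``
* ``meta.csv``     — ``sample_id,site,hydro_setting,date`` (ISO-8601 date)

The metric table (``metrics.csv``) holds one row per sample with every
composition measure; missing values are empty cells (NaN in memory), never
zero-filled.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemistry, optics
from .datatypes import (
    HYDRO_SETTINGS,
    ChemRecord,
    LCOCDRecord,
    SampleMeta,
    SampleSet,
    Spectrum,
)

logger = logging.getLogger(__name__)

SPECTRA_COLUMNS = ["sample_id", "wavelength_nm", "absorbance", "path_length_m"]
CHEM_COLUMNS = ["sample_id", "doc_mgC_L", "tdn_mgN_L", "no3_mgN_L", "no2_mgN_L", "nh4_mgN_L"]
LCOCD_COLUMNS = ["sample_id", "bp_pct", "hsf_pct", "bb_pct", "lmwn_pct", "lmwa_pct", "hs_mw_g_mol"]
META_COLUMNS = ["sample_id", "site", "hydro_setting", "date"]

#: Columns of the metric table, in output order.
METRIC_COLUMNS = [
    "doc", "don", "doc_don",
    "e2e3", "e4e6", "sac350", "sac420", "suva",
    "s275_295", "s350_400", "sr",
    "bp", "hsf", "bb", "lmwn", "lmwa", "hs_mw",
]


def _read_csv(path, required_columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, column: str, path, required: bool = False) -> pd.Series:
    """Parse one column as float; blank -> NaN; junk -> error naming row/column."""
    raw = df[column].str.strip()
    out = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    bad = out.isna() & (raw != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column "
            f"{column!r}, data row {row + 1}"
        )
    if required and out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ValueError(f"{path}: empty required column {column!r}, data row {row + 1}")
    return out.astype(float)


def _check_unique(ids: pd.Series, path) -> None:
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")


def read_dataset(spectra_path, chem_path, lcocd_path, meta_path) -> SampleSet:
    """Read and join the four CSV inputs into a :class:`SampleSet`.

    Samples present in some files but not others are retained with the
    missing blocks absent.  Duplicate sample ids within one file are a hard
    error, as is any non-numeric cell in a numeric column.
    """
    ds = SampleSet()

    # spectra: long format, grouped per sample
    sp = _read_csv(spectra_path, SPECTRA_COLUMNS)
    sp = sp.assign(
        wavelength_nm=_numeric(sp, "wavelength_nm", spectra_path, required=True),
        absorbance=_numeric(sp, "absorbance", spectra_path, required=True),
        path_length_m=_numeric(sp, "path_length_m", spectra_path, required=True),
    )
    dup = sp.duplicated(subset=["sample_id", "wavelength_nm"])
    if dup.any():
        sid = sp.loc[dup, "sample_id"].iloc[0]
        raise ValueError(
            f"{spectra_path}: duplicate (sample_id, wavelength) for sample {sid!r}"
        )
    for sid, grp in sp.groupby("sample_id", sort=True):
        grp = grp.sort_values("wavelength_nm")
        pl = grp["path_length_m"].unique()
        if len(pl) != 1:
            raise ValueError(
                f"{spectra_path}: sample {sid!r} has multiple path lengths {pl}"
            )
        ds.spectra[sid] = Spectrum(
            sample_id=sid,
            wavelengths=grp["wavelength_nm"].to_numpy(),
            absorbance=grp["absorbance"].to_numpy(),
            path_length=float(pl[0]),
        )

    ch = _read_csv(chem_path, CHEM_COLUMNS)
    _check_unique(ch["sample_id"], chem_path)
    cols = {c: _numeric(ch, c, chem_path, required=(c == "doc_mgC_L"))
            for c in CHEM_COLUMNS[1:]}
    for i, sid in enumerate(ch["sample_id"]):
        ds.chem[sid] = ChemRecord(
            sample_id=sid,
            doc=cols["doc_mgC_L"].iloc[i],
            tdn=cols["tdn_mgN_L"].iloc[i],
            no3=cols["no3_mgN_L"].iloc[i],
            no2=cols["no2_mgN_L"].iloc[i],
            nh4=cols["nh4_mgN_L"].iloc[i],
        )

    lc = _read_csv(lcocd_path, LCOCD_COLUMNS)
    _check_unique(lc["sample_id"], lcocd_path)
    cols = {c: _numeric(lc, c, lcocd_path) for c in LCOCD_COLUMNS[1:]}
    for i, sid in enumerate(lc["sample_id"]):
        ds.lcocd[sid] = LCOCDRecord(
            sample_id=sid,
            bp=cols["bp_pct"].iloc[i],
            hsf=cols["hsf_pct"].iloc[i],
            bb=cols["bb_pct"].iloc[i],
            lmwn=cols["lmwn_pct"].iloc[i],
            lmwa=cols["lmwa_pct"].iloc[i],
            hs_mw=cols["hs_mw_g_mol"].iloc[i],
        )

    mt = _read_csv(meta_path, META_COLUMNS)
    _check_unique(mt["sample_id"], meta_path)
    for _, row in mt.iterrows():
        setting = row["hydro_setting"].strip().lower()
        if setting not in HYDRO_SETTINGS:
            logger.warning(
                "sample %r: unknown hydro_setting %r flagged as 'other'",
                row["sample_id"], row["hydro_setting"],
            )
            setting = "other"
        date = None
        if row["date"].strip():
            date = _dt.date.fromisoformat(row["date"].strip())
        ds.meta[row["sample_id"]] = SampleMeta(
            sample_id=row["sample_id"],
            site=row["site"].strip(),
            hydro_setting=setting,
            date=date,
        )

    n = len(ds.sample_ids)
    incomplete = [sid for sid in ds.sample_ids if ds.missing_blocks(sid)]
    logger.info(
        "joined %d samples (%d spectra, %d chem, %d lcocd, %d meta); "
        "%d with missing blocks",
        n, len(ds.spectra), len(ds.chem), len(ds.lcocd), len(ds.meta),
        len(incomplete),
    )
    return ds


def compute_metrics(dataset: SampleSet) -> pd.DataFrame:
    """Compute every composition measure per sample.

    Returns a DataFrame indexed by ``sample_id`` with :data:`METRIC_COLUMNS`;
    measures whose inputs are absent stay NaN.
    """
    rows = {}
    for sid in dataset.sample_ids:
        row = dict.fromkeys(METRIC_COLUMNS, np.nan)
        chem = dataset.chem.get(sid)
        if chem is not None:
            row["doc"] = chem.doc
            row["don"] = chemistry.don(chem.tdn, chem.no3, chem.no2, chem.nh4)
            row["doc_don"] = chemistry.doc_don_ratio(chem.doc, row["don"])
        spec = dataset.spectra.get(sid)
        if spec is not None:
            if not spec.covers(250.0, 420.0):
                logger.warning(
                    "sample %r: spectrum does not cover [250, 420] nm; "
                    "absorbance indices left missing", sid,
                )
            else:
                row["e2e3"] = optics.e2_e3(spec)
                if spec.covers(465.0, 665.0):
                    row["e4e6"] = optics.e4_e6(spec)
                doc = chem.doc if chem is not None else np.nan
                row["suva"] = optics.suva(spec, doc)
                row["sac350"] = optics.sac350(spec, doc)
                row["sac420"] = optics.sac420(spec, doc)
                f1 = optics.spectral_slope(spec, optics.WINDOW_275_295)
                f2 = optics.spectral_slope(spec, optics.WINDOW_350_400)
                row["s275_295"] = f1.s if f1 is not None else np.nan
                row["s350_400"] = f2.s if f2 is not None else np.nan
                row["sr"] = optics.slope_ratio(f1, f2)
        lcocd = dataset.lcocd.get(sid)
        if lcocd is not None:
            row["bp"] = lcocd.bp
            row["hsf"] = lcocd.hsf
            row["bb"] = lcocd.bb
            row["lmwn"] = lcocd.lmwn
            row["lmwa"] = lcocd.lmwa
            row["hs_mw"] = lcocd.hs_mw if lcocd.hs_mw is not None else np.nan
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_COLUMNS)
    out.index.name = "sample_id"
    return out.sort_index()


def average_by_site(metrics: pd.DataFrame, dataset_or_meta) -> pd.DataFrame:
    """Average repeated sampling events to one row per (site, hydro_setting).

    The mean is the arithmetic mean of the derived metrics over non-missing
    values (not a recomputation from averaged spectra); a group where a
    metric is missing everywhere stays missing.
    """
    if isinstance(dataset_or_meta, SampleSet):
        meta = {sid: m for sid, m in dataset_or_meta.meta.items()}
    else:
        meta = {m.sample_id: m for m in dataset_or_meta}
    keys = pd.DataFrame(
        {
            "site": [meta[sid].site for sid in metrics.index if sid in meta],
            "hydro_setting": [
                meta[sid].hydro_setting for sid in metrics.index if sid in meta
            ],
        },
        index=[sid for sid in metrics.index if sid in meta],
    )
    dropped = metrics.index.difference(keys.index)
    if len(dropped):
        logger.warning(
            "average_by_site: %d samples without metadata dropped: %s",
            len(dropped), list(dropped[:5]),
        )
    joined = metrics.loc[keys.index].join(keys)
    out = joined.groupby(["site", "hydro_setting"], sort=True).mean()
    return out


def write_metrics(metrics: pd.DataFrame, path) -> None:
    """Write the metric table to CSV (values round-trip to full precision)."""
    metrics.to_csv(path, float_format="%.17g")


def read_metrics(path) -> pd.DataFrame:
    """Read a metric table written by :func:`write_metrics`."""
    df = pd.read_csv(path)
    index_cols = [c for c in ("sample_id", "site", "hydro_setting") if c in df.columns]
    return df.set_index(index_cols[0] if len(index_cols) == 1 else index_cols)
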