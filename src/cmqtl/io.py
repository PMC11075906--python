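"""Readers and writers for the pipeline's file formats.

Conventions: UTF-8 comma-separated CSV with a mandatory header row and '.'
decimals; genomic positions in integer bp; founder dosages in HDF5 (dataset
"dosage", individuals x 8 founders x markers, with a founder_order
attribute) or as an equivalent CSV bundle. Output CSVs carry '#' comment
header lines recording the config hash and seed so every derived number is
traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import GenoProbs, MarkerMap, N_FOUNDERS

WELL_TABLE_COLUMNS = (
    "individual_id",
    "sex",
    "generation",
    "plate",
    "run",
    "replicate_column",
    "dose_um",
    "feature",
    "value",
)


def write_csv(df: pd.DataFrame, path, header_info: dict = None) -> None:
    """Write a CSV with optional '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_info:
            for key, val in header_info.items():
                fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_well_table(path, expected_doses=None) -> pd.DataFrame:
    """Load and validate a well-level morphology table.

    Checks required columns, numeric doses, duplicate rows, and (optionally)
    that the doses match a configured grid.
    """
    df = read_csv(path)
    missing = [c for c in WELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table missing column(s): {', '.join(missing)}")
    doses = pd.to_numeric(df["dose_um"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(doses.to_numpy()))
    if bad.size:
        raise ValueError(f"non-numeric dose at row {int(bad[0])}")
    df["dose_um"] = doses
    key_cols = ["individual_id", "replicate_column", "dose_um", "feature"]
    if df.duplicated(subset=key_cols).any():
        raise ValueError("duplicate individual x replicate x dose x feature rows")
    if expected_doses is not None:
        got = set(np.round(df["dose_um"].unique(), 10))
        want = set(np.round(np.asarray(expected_doses, dtype=float), 10))
        if got - want:
            raise ValueError(f"doses outside configured grid: {sorted(got - want)}")
    return df


def save_genoprobs_hdf5(genoprobs: GenoProbs, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("dosage", data=genoprobs.dosage)
        ds.attrs["founder_order"] = [s.encode() for s in genoprobs.founder_order]
        f.create_dataset(
            "individual_ids", data=[s.encode() for s in genoprobs.individual_ids]
        )
        mm = genoprobs.marker_map.df
        f.create_dataset("marker_id", data=[s.encode() for s in mm["marker_id"]])
        f.create_dataset("chromosome", data=[str(c).encode() for c in mm["chromosome"]])
        f.create_dataset("position_bp", data=mm["position_bp"].to_numpy())
        f.create_dataset("position_cm", data=mm["position_cm"].to_numpy())


def load_genoprobs(path) -> GenoProbs:
    """Load founder dosages from HDF5; the sum-to-2 invariant is enforced."""
    def _str(v):
        return v.decode() if isinstance(v, bytes) else str(v)

    with h5py.File(path, "r") as f:
        dosage = f["dosage"][...]
        founders = tuple(_str(s) for s in f["dosage"].attrs["founder_order"])
        ids = [_str(s) for s in f["individual_ids"][...]]
        mm = pd.DataFrame(
            {
                "marker_id": [_str(s) for s in f["marker_id"][...]],
                "chromosome": [_str(s) for s in f["chromosome"][...]],
                "position_bp": f["position_bp"][...],
                "position_cm": f["position_cm"][...],
            }
        )
    sums = dosage.sum(axis=1)
    bad = np.argwhere(np.abs(sums - 2.0) > 1e-6)
    if bad.size:
        i, m = bad[0]
        raise ValueError(
            f"dosages do not sum to 2 at individual {ids[i]}, marker index {m}"
        )
    return GenoProbs(dosage, ids, MarkerMap(mm), founders)


def save_genoprobs_csv(genoprobs: GenoProbs, prefix) -> None:
    """CSV bundle equivalent of the HDF5 layout: <prefix>_dosage.csv (long
    format) and <prefix>_markers.csv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, _, M = genoprobs.dosage.shape
    long = pd.DataFrame(
        genoprobs.dosage.reshape(n * N_FOUNDERS, M),
        columns=genoprobs.marker_map.df["marker_id"],
    )
    long.insert(0, "individual_id", np.repeat(genoprobs.individual_ids, N_FOUNDERS))
    long.insert(1, "founder", list(genoprobs.founder_order) * n)
    long.to_csv(f"{prefix}_dosage.csv", index=False)
    genoprobs.marker_map.to_csv(f"{prefix}_markers.csv")


def load_genoprobs_csv(prefix) -> GenoProbs:
    mm = MarkerMap.from_csv(f"{prefix}_markers.csv")
    long = pd.read_csv(f"{prefix}_dosage.csv")
    ids = list(dict.fromkeys(long["individual_id"]))
    founders = tuple(dict.fromkeys(long["founder"]))
    n = len(ids)
    dosage = (
        long[mm.df["marker_id"]].to_numpy().reshape(n, N_FOUNDERS, mm.n_markers)
    )
    return GenoProbs(dosage, ids, mm, founders)


def load_variants(path) -> pd.DataFrame:
    """Variant table: variant_id, chromosome, position_bp, sdp (8-char
    founder bitstring, ABCDEFGH order)."""
    df = read_csv(path)
    required = {"variant_id", "chromosome", "position_bp", "sdp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing column(s): {sorted(missing)}")
    df["chromosome"] = df["chromosome"].astype(str)
    df["sdp"] = df["sdp"].astype(str).str.zfill(N_FOUNDERS)
    return df


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
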