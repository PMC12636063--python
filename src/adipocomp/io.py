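"""File formats: GWAS summary-statistics TSV and NIfTI volumes."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .gwas import VariantAssociation

SUMSTATS_COLUMNS = ["rsID", "CHR", "BP", "EA", "OA", "BETA", "SE", "P", "EAF", "N"]

# printed tables use typographic minus/hyphen variants; normalize on read
_CHAR_FIXES = str.maketrans({"−": "-", "‐": "-", "‑": "-", ",": ""})


def _parse_number(text: str, line_no: int, col: str) -> float:
    cleaned = str(text).translate(_CHAR_FIXES).strip()
    # tolerate truncated scientific notation like "4.E-293"
    cleaned = cleaned.replace(".E", ".0E").replace(".e", ".0e")
    try:
        return float(cleaned)
    except ValueError as exc:
        raise ValueError(
            f"line {line_no}: cannot parse {col}={text!r} as a number"
        ) from exc


def read_sumstats(path) -> pd.DataFrame:
    """Read a tab-separated GWAS summary-statistics table.

    Requires the rsID/CHR/BP/EA/OA/BETA/SE/P/EAF/N column set, tolerates
    typographic minus signs, digit-grouping commas and truncated scientific
    notation (``4.E-293``) as printed in journal tables, and reports
    malformed rows with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s): {missing}")
    out = pd.DataFrame()
    out["rsID"] = df["rsID"].astype(str)
    out["EA"] = df["EA"].astype(str)
    out["OA"] = df["OA"].astype(str)
    for col, cast in [
        ("CHR", int),
        ("BP", int),
        ("BETA", float),
        ("SE", float),
        ("P", float),
        ("EAF", float),
        ("N", int),
    ]:
        vals = []
        for i, raw in enumerate(df[col]):
            vals.append(cast(_parse_number(raw, i + 2, col)))
        out[col] = vals
    return out


def write_sumstats(records, path) -> None:
    """Write associations (DataFrame or VariantAssociation iterable) as TSV."""
    if isinstance(records, pd.DataFrame):
        df = records[SUMSTATS_COLUMNS]
    else:
        df = pd.DataFrame(
            [
                {
                    "rsID": a.rsid,
                    "CHR": a.chrom,
                    "BP": a.bp,
                    "EA": a.ea,
                    "OA": a.oa,
                    "BETA": a.beta,
                    "SE": a.se,
                    "P": a.p,
                    "EAF": a.eaf,
                    "N": a.n,
                }
                for a in records
            ],
            columns=SUMSTATS_COLUMNS,
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def associations_from_frame(df: pd.DataFrame) -> list[VariantAssociation]:
    return [
        VariantAssociation(
            rsid=r["rsID"],
            chrom=int(r["CHR"]),
            bp=int(r["BP"]),
            ea=r["EA"],
            oa=r["OA"],
            beta=float(r["BETA"]),
            se=float(r["SE"]),
            p=float(r["P"]),
            eaf=float(r["EAF"]),
            n=int(r["N"]),
        )
        for _, r in df.iterrows()
    ]


def save_volume(array: np.ndarray, affine, path) -> None:
    """Write a volume as NIfTI-1; float data stored as float64."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), np.asarray(affine))
    nib.save(img, str(path))


def load_volume(path):
    """Read a NIfTI volume; returns (array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine
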