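"""Kinetic-trapping mass-spectrometry quantitation of disulfide redox state.

Starting from extracted precursor-ion peak areas, the % reduction of a
cysteine-containing peptide in a sample is the ratio of its control-peptide-
normalised area to the same quantity in the fully reduced reference, averaged
over the control peptides:

    % reduction = mean_i [ (A_cys,sample / A_ctrl_i,sample)
                           / (A_cys,100% / A_ctrl_i,100%) ] x 100

Replicates (biological x technical, pooled) yield a mean +/- sample SD per
cysteine.  Values above 100% are reported as-is with a warning — area noise
can exceed the fully-reduced reference — never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("peptide_id", "cysteine_label", "is_control", "sample",
                    "replicate_id", "precursor_area")
SAMPLES = ("control", "treated", "fully_reduced")
FULLY_REDUCED = "fully_reduced"


@dataclass
class ReductionEstimate:
    cysteine_label: str
    sample: str
    percent_mean: float
    percent_sd: float
    n_values: int


class PeakAreaTable:
    """Validated table of extracted precursor areas."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"peak table is missing columns {missing}")
        df = df.copy()
        df["is_control"] = df["is_control"].astype(bool)
        bad = df.index[df["precursor_area"] < 0].tolist()
        if bad:
            raise ValueError(f"negative precursor areas at rows {bad}")
        unknown = sorted(set(df["sample"]) - set(SAMPLES))
        if unknown:
            raise ValueError(f"unknown sample labels {unknown}; expected {SAMPLES}")
        dup = df.duplicated(subset=["peptide_id", "sample", "replicate_id"])
        if dup.any():
            raise ValueError(
                f"duplicate (peptide, sample, replicate) keys at rows {df.index[dup].tolist()}")
        if not df["is_control"].any():
            raise ValueError("peak table needs at least one control peptide")
        if FULLY_REDUCED not in set(df["sample"]):
            raise ValueError("peak table needs a fully_reduced sample")
        self.df = df

    @property
    def control_peptides(self) -> list[str]:
        return sorted(self.df.loc[self.df["is_control"], "peptide_id"].unique())

    def cysteine_peptides(self) -> list[str]:
        return sorted(self.df.loc[~self.df["is_control"], "peptide_id"].unique())

    def _area(self, peptide: str, sample: str, replicate) -> float:
        rows = self.df[(self.df["peptide_id"] == peptide)
                       & (self.df["sample"] == sample)
                       & (self.df["replicate_id"] == replicate)]
        if rows.empty:
            raise KeyError(
                f"missing area for peptide {peptide!r}, sample {sample!r}, "
                f"replicate {replicate!r}")
        return float(rows["precursor_area"].iloc[0])

    def replicates(self, peptide: str, sample: str) -> list:
        return sorted(self.df[(self.df["peptide_id"] == peptide)
                              & (self.df["sample"] == sample)]["replicate_id"].unique())


def read_peak_table(path: str, format: Optional[str] = None) -> PeakAreaTable:
    """Load a CSV/TSV peak-area table (header must carry the required columns)."""
    sep = "\t" if (format or "").upper() == "TSV" or str(path).endswith(".tsv") else ","
    return PeakAreaTable(pd.read_csv(path, sep=sep))


def read_cysteine_map(path: str) -> pd.DataFrame:
    """Companion peptide -> cysteine/disulfide map.  Columns: peptide_id,
    cysteine_label, bond_label, optional numbering_offset (e.g. +19 when MS
    numbering includes a signal peptide)."""
    df = pd.read_csv(path)
    for col in ("peptide_id", "cysteine_label", "bond_label"):
        if col not in df.columns:
            raise ValueError(f"cysteine map is missing column {col!r}")
    if "numbering_offset" not in df.columns:
        df["numbering_offset"] = 0
    return df


def percent_reduction(t: PeakAreaTable, cys_peptide: str, sample: str,
                      replicate) -> float:
    """Ratio-of-ratios % reduction for one peptide/sample/replicate."""
    a_cys = t._area(cys_peptide, sample, replicate)
    a_cys_full = t._area(cys_peptide, FULLY_REDUCED, replicate)
    values = []
    for ctrl in t.control_peptides:
        a_ctrl = t._area(ctrl, sample, replicate)
        a_ctrl_full = t._area(ctrl, FULLY_REDUCED, replicate)
        if a_ctrl == 0 or a_ctrl_full == 0:
            raise ZeroDivisionError(f"zero control area for peptide {ctrl!r}")
        if a_cys_full == 0:
            raise ZeroDivisionError(
                f"zero fully-reduced area for peptide {cys_peptide!r}")
        values.append((a_cys / a_ctrl) / (a_cys_full / a_ctrl_full) * 100.0)
    result = float(np.mean(values))
    if result > 100.0:
        warnings.warn(f"{cys_peptide} in {sample!r} replicate {replicate!r}: "
                      f"{result:.1f}% exceeds the fully reduced reference",
                      stacklevel=2)
    return result


def summarize_replicates(t: PeakAreaTable, cys_peptide: str, sample: str,
                         cysteine_label: Optional[str] = None) -> ReductionEstimate:
    """Mean and sample SD of % reduction across all pooled replicates."""
    reps = t.replicates(cys_peptide, sample)
    if not reps:
        raise KeyError(f"no replicates for peptide {cys_peptide!r} in {sample!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = [percent_reduction(t, cys_peptide, sample, r) for r in reps]
    arr = np.asarray(values)
    label = cysteine_label
    if label is None:
        labels = t.df.loc[t.df["peptide_id"] == cys_peptide, "cysteine_label"]
        label = str(labels.iloc[0]) if not labels.empty else cys_peptide
    return ReductionEstimate(
        cysteine_label=label, sample=sample,
        percent_mean=float(arr.mean()),
        percent_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n_values=len(arr))


def summarize_table(t: PeakAreaTable, samples: Sequence[str] = ("control", "treated")
                    ) -> pd.DataFrame:
    """Per-cysteine mean +/- SD for every requested sample, as a tidy frame."""
    rows = []
    for pep in t.cysteine_peptides():
        for sample in samples:
            if not t.replicates(pep, sample):
                continue
            est = summarize_replicates(t, pep, sample)
            rows.append({"peptide_id": pep, "cysteine_label": est.cysteine_label,
                         "sample": sample, "percent_mean": est.percent_mean,
                         "percent_sd": est.percent_sd, "n_values": est.n_values})
    return pd.DataFrame(rows)
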