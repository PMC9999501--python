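"""GC/MS metabolite tables and the extractable-aromatic trait.

Extracts are profiled by GC/MS against a spiked internal standard
(sorbitol), giving per-metabolite abundances in internal-standard
equivalents (ug or ng per g dry weight). Each metabolite carries a
boolean "aromatic" classification supplied as input data — in the
source workflow that classification was manual curation, so it is never
inferred from names here.

Two trait variants are exposed:

* ``aromatic_fraction`` — aromatic sum divided by the total metabolite
  sum per sample (scale-invariant, in [0, 1]);
* ``aromatic_sum`` — the raw summed aromatic abundance, the variant used
  for correlation against spectral ion sums.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundance matrix with aromatic flags."""

    sample_ids: list[str]
    metabolite_names: list[str]
    abundances: np.ndarray
    aromatic_flags: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.aromatic_flags = np.asarray(self.aromatic_flags, dtype=bool)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample id in metabolite table")
        if len(set(self.metabolite_names)) != len(self.metabolite_names):
            dup = next(n for n in self.metabolite_names
                       if self.metabolite_names.count(n) > 1)
            raise InputError(f"duplicate metabolite name {dup!r}")
        if self.abundances.shape != (len(self.sample_ids), len(self.metabolite_names)):
            raise InputError("abundance matrix shape mismatch")
        if self.aromatic_flags.shape != (len(self.metabolite_names),):
            raise InputError("aromatic flag vector length must equal metabolite count")
        if np.any(self.abundances < 0):
            r, c = np.argwhere(self.abundances < 0)[0]
            raise InputError(
                f"negative abundance at sample {self.sample_ids[r]!r}, "
                f"metabolite {self.metabolite_names[c]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.abundances, columns=self.metabolite_names)
        df.insert(0, "sample", self.sample_ids)
        return df


def read_metabolite_table(path, flags_path=None) -> MetaboliteTable:
    """Read a metabolite TSV.

    Layout: header ``sample\\tmet1\\tmet2...``; if ``flags_path`` is not
    given, the first data line must be the flag row, first cell
    ``aromatic`` and one ``1``/``0`` per metabolite. A sidecar flags file
    is a two-column TSV ``metabolite\\taromatic``.

    Missing values are treated as zero abundance (metabolite not
    detected); the count of imputed cells is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise InputError("missing 'sample' column")
    names = [c for c in df.columns if c != "sample"]

    if flags_path is None:
        if df.empty or str(df["sample"].iloc[0]) != "aromatic":
            raise InputError(
                "expected an 'aromatic' flag row or a sidecar flags file"
            )
        flag_row = df.iloc[0][names]
        df = df.iloc[1:].reset_index(drop=True)
        flags = np.array([_parse_flag(v, n) for n, v in zip(names, flag_row)])
    else:
        fdf = pd.read_csv(flags_path, sep="\t", dtype=str)
        if not {"metabolite", "aromatic"}.issubset(fdf.columns):
            raise InputError("flags file requires columns 'metabolite' and 'aromatic'")
        fmap = dict(zip(fdf["metabolite"], fdf["aromatic"]))
        missing = [n for n in names if n not in fmap]
        if missing:
            raise InputError(f"metabolites missing from flags file: {missing}")
        flags = np.array([_parse_flag(fmap[n], n) for n in names])

    abund = df[names].apply(pd.to_numeric, errors="raise")
    n_missing = int(abund.isna().sum().sum())
    if n_missing:
        log.info("imputed %d missing abundances as zero (not detected)", n_missing)
        abund = abund.fillna(0.0)
    table = MetaboliteTable(
        sample_ids=df["sample"].astype(str).tolist(),
        metabolite_names=names,
        abundances=abund.to_numpy(dtype=float),
        aromatic_flags=flags,
    )
    zero = np.flatnonzero(table.abundances.sum(axis=1) <= 0)
    for i in zero:
        log.warning("sample %r has zero total abundance; flagged for exclusion",
                    table.sample_ids[i])
    return table


def _parse_flag(value, name: str) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "yes"}:
        return True
    if s in {"0", "false", "no"}:
        return False
    raise InputError(f"unknown aromatic flag {value!r} for metabolite {name!r}")


def write_metabolite_table(t: MetaboliteTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["sample"] + t.metabolite_names) + "\n")
        fh.write("\t".join(["aromatic"] + [str(int(f)) for f in t.aromatic_flags]) + "\n")
        for i, s in enumerate(t.sample_ids):
            fh.write("\t".join([s] + [repr(v) for v in t.abundances[i].tolist()]) + "\n")


def aromatic_sum(t: MetaboliteTable) -> pd.Series:
    """Per-sample summed abundance of aromatic-flagged metabolites."""
    vals = t.abundances[:, t.aromatic_flags].sum(axis=1)
    return pd.Series(vals, index=t.sample_ids, name="aromatic_sum")


def aromatic_fraction(t: MetaboliteTable) -> pd.Series:
    """Aromatic sum over total metabolite sum, per sample, in [0, 1].

    Samples with zero total are excluded (NaN) with a warning rather than
    silently reported as 0.
    """
    totals = t.abundances.sum(axis=1)
    arom = t.abundances[:, t.aromatic_flags].sum(axis=1)
    frac = np.full(t.n_samples, np.nan)
    ok = totals > 0
    frac[ok] = arom[ok] / totals[ok]
    for i in np.flatnonzero(~ok):
        warnings.warn(
            f"sample {t.sample_ids[i]!r} has zero total metabolite abundance; "
            "aromatic fraction undefined (excluded)",
            stacklevel=2,
        )
    return pd.Series(frac, index=t.sample_ids, name="aromatic_fraction")
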