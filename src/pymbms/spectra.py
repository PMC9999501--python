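"""Binned pyrolysis mass-spectral matrices.

A py-MBMS run yields, per biomass sample, a unit-mass-binned spectrum of
fragment-ion intensities over integer m/z (here 30-450 by convention).
This module holds the in-memory container plus the standard preprocessing
steps: total-ion-current (TIC) normalization, mean normalization,
replicate averaging and m/z windowing.

Normalization state is tracked explicitly (``raw`` / ``tic`` / ``mean``)
and downstream scoring operations assert the state they require, so a
spectrum can never be silently double-normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InputError

NORM_STATES = ("raw", "tic", "mean")


@dataclass
class SpectraMatrix:
    """Samples x integer-m/z intensity matrix with normalization state.

    Rows are individual spectra (one per instrument replicate when
    ``replicate_ids`` is set); columns follow ``mz``, a strictly
    increasing integer axis in Th.
    """

    sample_ids: list[str]
    mz: np.ndarray
    intensities: np.ndarray
    replicate_ids: list[str] | None = None
    norm_state: str = "raw"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.norm_state not in NORM_STATES:
            raise InputError(f"unknown norm_state {self.norm_state!r}")
        if not np.issubdtype(self.mz.dtype, np.integer):
            raise InputError("m/z axis must be integer (unit-mass binned)")
        if self.mz.ndim != 1 or np.any(np.diff(self.mz) <= 0):
            raise InputError("m/z axis must be strictly increasing")
        if self.intensities.shape != (len(self.sample_ids), len(self.mz)):
            raise InputError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.mz)} m/z bins"
            )
        if np.any(self.intensities < 0):
            r, c = np.argwhere(self.intensities < 0)[0]
            raise InputError(
                f"negative intensity at sample {self.sample_ids[r]!r}, m/z {self.mz[c]}"
            )
        if self.replicate_ids is not None:
            if len(self.replicate_ids) != len(self.sample_ids):
                raise InputError("replicate_ids length must match sample_ids")
            pairs = list(zip(self.sample_ids, self.replicate_ids))
            if len(set(pairs)) != len(pairs):
                dup = next(p for p in pairs if pairs.count(p) > 1)
                raise InputError(f"duplicate (sample, replicate) pair {dup}")
        else:
            if len(set(self.sample_ids)) != len(self.sample_ids):
                raise InputError("duplicate sample_id without replicate_ids")
        if self.norm_state == "tic":
            if not np.allclose(self.intensities.sum(axis=1), 1.0, atol=1e-9):
                raise InputError("tic-normalized rows must each sum to 1")
        elif self.norm_state == "mean":
            if not np.allclose(self.intensities.mean(axis=1), 1.0, atol=1e-9):
                raise InputError("mean-normalized rows must each average to 1")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame view (columns = m/z bins)."""
        df = pd.DataFrame(self.intensities, columns=self.mz)
        df.insert(0, "sample", self.sample_ids)
        if self.replicate_ids is not None:
            df.insert(1, "replicate", self.replicate_ids)
        return df

    def ion_sum(self, ions) -> np.ndarray:
        """Per-row summed intensity over the given integer m/z set.

        Ions absent from the axis contribute zero (with a warning): a bin
        missing from a binned export means no counts were recorded there.
        """
        ions = sorted(int(i) for i in ions)
        present = [i for i in ions if i in set(self.mz.tolist())]
        missing = sorted(set(ions) - set(present))
        if missing:
            warnings.warn(
                f"ions {missing} absent from the m/z axis; treated as zero intensity",
                stacklevel=2,
            )
        if not present:
            return np.zeros(self.n_spectra)
        cols = np.searchsorted(self.mz, present)
        return self.intensities[:, cols].sum(axis=1)


# ---------------------------------------------------------------------------
# IO

def read_spectra(path, dialect: str = "wide_tsv") -> SpectraMatrix:
    """Read a binned spectral matrix from tab-delimited text.

    ``wide_tsv``: header ``sample[\\treplicate]\\t30\\t31...``, one row per
    spectrum. ``long_tsv``: columns ``sample[, replicate], mz, intensity``.
    """
    if dialect == "wide_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    elif dialect == "long_tsv":
        long = pd.read_csv(path, sep="\t", dtype={"sample": str})
        required = {"sample", "mz", "intensity"}
        if not required.issubset(long.columns):
            raise InputError(f"long_tsv requires columns {sorted(required)}")
        index = ["sample"] + (["replicate"] if "replicate" in long.columns else [])
        wide = long.pivot_table(
            index=index, columns="mz", values="intensity", fill_value=0.0, sort=False
        )
        df = wide.reset_index()
        df.columns = [str(c) for c in df.columns]
    else:
        raise InputError(f"unknown dialect {dialect!r}")

    if "sample" not in df.columns:
        raise InputError("missing 'sample' column")
    meta_cols = ["sample"] + (["replicate"] if "replicate" in df.columns else [])
    mz_cols = [c for c in df.columns if c not in meta_cols]
    mz = []
    for c in mz_cols:
        try:
            v = float(c)
        except ValueError:
            raise InputError(f"non-numeric m/z column {c!r}") from None
        if v != int(v):
            raise InputError(f"non-integer m/z column {c!r}: spectra must be unit-mass binned")
        mz.append(int(v))
    if len(set(mz)) != len(mz):
        dup = next(m for m in mz if mz.count(m) > 1)
        raise InputError(f"duplicate m/z column {dup}")

    order = np.argsort(mz)
    inten = df[mz_cols].to_numpy(dtype=float)[:, order]
    mz_arr = np.asarray(mz)[order]
    bad = np.argwhere(inten < 0)
    if bad.size:
        r, c = bad[0]
        raise InputError(
            f"negative intensity {inten[r, c]} at sample "
            f"{df['sample'].iloc[r]!r}, m/z {mz_arr[c]}"
        )
    reps = df["replicate"].astype(str).tolist() if "replicate" in df.columns else None
    return SpectraMatrix(
        sample_ids=df["sample"].astype(str).tolist(),
        mz=mz_arr,
        intensities=inten,
        replicate_ids=reps,
        norm_state="raw",
    )


def write_spectra(m: SpectraMatrix, path, dialect: str = "wide_tsv") -> None:
    """Write to TSV. Floats use shortest round-trip repr so that
    ``read_spectra(write_spectra(m))`` is bit-identical for wide_tsv."""
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "wide_tsv":
            head = ["sample"] + (["replicate"] if m.replicate_ids is not None else [])
            fh.write("\t".join(head + [str(z) for z in m.mz]) + "\n")
            for i in range(m.n_spectra):
                row = [m.sample_ids[i]]
                if m.replicate_ids is not None:
                    row.append(m.replicate_ids[i])
                row += [repr(v) for v in m.intensities[i].tolist()]
                fh.write("\t".join(row) + "\n")
        elif dialect == "long_tsv":
            head = ["sample"] + (["replicate"] if m.replicate_ids is not None else [])
            fh.write("\t".join(head + ["mz", "intensity"]) + "\n")
            for i in range(m.n_spectra):
                for j, z in enumerate(m.mz.tolist()):
                    row = [m.sample_ids[i]]
                    if m.replicate_ids is not None:
                        row.append(m.replicate_ids[i])
                    row += [str(z), repr(m.intensities[i, j].item())]
                    fh.write("\t".join(row) + "\n")
        else:
            raise InputError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# preprocessing

def _check_positive_totals(m: SpectraMatrix) -> np.ndarray:
    totals = m.intensities.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise InputError(
            f"all-zero spectrum for sample {m.sample_ids[zero[0]]!r}: "
            "an empty spectrum cannot be normalized"
        )
    return totals


def tic_normalize(m: SpectraMatrix) -> SpectraMatrix:
    """Divide each spectrum by its total ion current; rows then sum to 1."""
    totals = _check_positive_totals(m)
    return replace(m, intensities=m.intensities / totals[:, None], norm_state="tic")


def mean_normalize(m: SpectraMatrix) -> SpectraMatrix:
    """Divide each spectrum by its own mean intensity over the retained bins.

    Equals ``tic_normalize(m)`` scaled by the number of bins.
    """
    _check_positive_totals(m)
    means = m.intensities.mean(axis=1)
    return replace(m, intensities=m.intensities / means[:, None], norm_state="mean")


def average_replicates(m: SpectraMatrix) -> SpectraMatrix:
    """Collapse instrument replicates to one row per sample (arithmetic mean).

    Normalization state is preserved: the mean of TIC rows still sums to 1.
    Sample order follows first occurrence.
    """
    if m.replicate_ids is None:
        return replace(m)
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(m.sample_ids):
        if s not in groups:
            groups[s] = []
            order.append(s)
        groups[s].append(i)
    out = np.vstack([m.intensities[groups[s]].mean(axis=0) for s in order])
    return SpectraMatrix(
        sample_ids=order, mz=m.mz, intensities=out,
        replicate_ids=None, norm_state=m.norm_state,
    )


def restrict_mz(m: SpectraMatrix, lo: int, hi: int) -> SpectraMatrix:
    """Keep only bins with lo <= m/z <= hi.

    The result is demoted to ``raw``: dropping columns breaks the row-sum /
    row-mean invariants of a normalized matrix.
    """
    if lo > hi:
        raise InputError(f"empty window: lo {lo} > hi {hi}")
    keep = (m.mz >= lo) & (m.mz <= hi)
    if not keep.any():
        raise InputError(f"no m/z bins inside [{lo}, {hi}]")
    return SpectraMatrix(
        sample_ids=list(m.sample_ids), mz=m.mz[keep],
        intensities=m.intensities[:, keep],
        replicate_ids=list(m.replicate_ids) if m.replicate_ids is not None else None,
        norm_state="raw",
    )


def align_mz(m: SpectraMatrix, axis) -> SpectraMatrix:
    """Re-index onto a common integer m/z axis; missing bins become zero."""
    axis = np.asarray(sorted(int(a) for a in axis))
    out = np.zeros((m.n_spectra, len(axis)))
    pos = {int(z): j for j, z in enumerate(axis)}
    for j, z in enumerate(m.mz.tolist()):
        if z in pos:
            out[:, pos[z]] = m.intensities[:, j]
    return SpectraMatrix(
        sample_ids=list(m.sample_ids), mz=axis, intensities=out,
        replicate_ids=list(m.replicate_ids) if m.replicate_ids is not None else None,
        norm_state="raw",
    )
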