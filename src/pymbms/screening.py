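"""Per-sample screening phenotypes from binned py-MBMS spectra.

The rapid screen assigns each sample four numbers:

* **aromatic ion-summation score** — the sum of TIC-normalized
  intensities at the aromatic-metabolite marker ions
  (m/z 68, 71, 77, 91, 94, 105, 107, 108, 122), a dimensionless proxy
  in [0, 1] for the relative abundance of extractable aromatic
  secondary metabolites;
* **aromatic rank** — 1 = most aromatic, average ranks on ties;
* **lignin content (% DW)** — the summed mean-normalized lignin marker
  ions scaled by a single-point response factor calibrated on a
  reference standard of known Klason lignin content;
* **S/G ratio** — summed syringyl-derived ions over summed
  guaiacyl-derived ions (scale-invariant).

m/z 71 appears in both the sugar and the aromatic marker sets; it is
retained in the score as published and flagged as a known confounder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .spectra import SpectraMatrix

DEFAULT_AROMATIC_IONS = frozenset({68, 71, 77, 91, 94, 105, 107, 108, 122})
DEFAULT_LIGNIN_IONS = frozenset(
    {120, 124, 137, 138, 150, 152, 154, 164, 167, 168, 178, 180, 181, 182, 194, 208, 210}
)
DEFAULT_S_IONS = frozenset({154, 167, 168, 182, 194, 208, 210})
DEFAULT_G_IONS = frozenset({124, 137, 138, 150, 164, 178})
DEFAULT_SUGAR_IONS = frozenset({43, 57, 71, 85, 95, 97})


@dataclass(frozen=True)
class IonRoleMap:
    """Registry assigning integer m/z bins to compositional roles.

    Defaults are the published poplar-leaf marker sets. S and G ions are
    subsets of the lignin set; the lignin ions outside both (120, 152,
    180, 181) derive from other monomers or multiple sources and enter
    lignin content but not S/G.
    """

    aromatic_ions: frozenset[int] = DEFAULT_AROMATIC_IONS
    lignin_ions: frozenset[int] = DEFAULT_LIGNIN_IONS
    s_ions: frozenset[int] = DEFAULT_S_IONS
    g_ions: frozenset[int] = DEFAULT_G_IONS
    sugar_ions: frozenset[int] = DEFAULT_SUGAR_IONS
    provenance: str = "published poplar-leaf defaults"

    def __post_init__(self) -> None:
        for name in ("aromatic_ions", "lignin_ions", "s_ions", "g_ions", "sugar_ions"):
            ions = frozenset(int(i) for i in getattr(self, name))
            object.__setattr__(self, name, ions)
            out = [i for i in ions if not (30 <= i <= 450)]
            if out:
                raise InputError(f"{name} outside m/z 30-450: {sorted(out)}")
        if not (self.s_ions | self.g_ions) <= self.lignin_ions:
            extra = sorted((self.s_ions | self.g_ions) - self.lignin_ions)
            raise InputError(f"S/G ions not contained in lignin set: {extra}")

    @property
    def confounded_ions(self) -> frozenset[int]:
        """Ions shared between the sugar and aromatic marker sets."""
        return self.aromatic_ions & self.sugar_ions

    def to_dict(self) -> dict:
        return {
            "aromatic_ions": sorted(self.aromatic_ions),
            "lignin_ions": sorted(self.lignin_ions),
            "s_ions": sorted(self.s_ions),
            "g_ions": sorted(self.g_ions),
            "sugar_ions": sorted(self.sugar_ions),
            "provenance": self.provenance,
        }

    @classmethod
    def from_yaml(cls, path) -> "IonRoleMap":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for name in ("aromatic_ions", "lignin_ions", "s_ions", "g_ions", "sugar_ions"):
            if name in raw:
                kwargs[name] = frozenset(int(i) for i in raw[name])
        kwargs["provenance"] = raw.get("provenance", f"loaded from {path}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class LigninCalibration:
    """Single-point lignin response factor from a reference standard.

    ``response_factor = known_klason_pct / reference_lignin_ion_sum``,
    where the reference sum is over the lignin marker ions of the
    reference spectrum in the stored normalization state. Estimation
    refuses spectra whose normalization state differs from the one the
    calibration was built with.
    """

    reference_lignin_ion_sum: float
    known_klason_pct: float
    norm_state: str = "mean"

    def __post_init__(self) -> None:
        if self.reference_lignin_ion_sum <= 0:
            raise InputError("reference lignin-ion sum must be positive")
        if self.known_klason_pct < 0:
            raise InputError("Klason lignin % cannot be negative")
        if self.known_klason_pct == 0:
            warnings.warn("known Klason lignin is 0%: response factor degenerates to 0",
                          stacklevel=2)

    @property
    def response_factor(self) -> float:
        return self.known_klason_pct / self.reference_lignin_ion_sum

    def to_dict(self) -> dict:
        return {
            "reference_lignin_ion_sum": float(self.reference_lignin_ion_sum),
            "known_klason_pct": float(self.known_klason_pct),
            "norm_state": self.norm_state,
        }

    @classmethod
    def from_yaml(cls, path) -> "LigninCalibration":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**{k: raw[k] for k in
                      ("reference_lignin_ion_sum", "known_klason_pct", "norm_state")})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# operations

def aromatic_ion_score(m: SpectraMatrix, ions: IonRoleMap | None = None) -> pd.Series:
    """Sum of TIC-normalized intensities over the aromatic marker ions.

    Requires ``norm_state == 'tic'`` so the score is a fraction of total
    ion current, bounded in [0, 1].
    """
    ions = ions or IonRoleMap()
    if m.norm_state != "tic":
        raise InputError(
            f"aromatic_ion_score requires TIC-normalized spectra, got {m.norm_state!r}; "
            "apply tic_normalize first"
        )
    vals = m.ion_sum(ions.aromatic_ions)
    return pd.Series(vals, index=m.sample_ids, name="aromatic_score")


def rank_samples(scores, descending: bool = True) -> pd.Series:
    """Average-tie ranking; rank 1 = largest score when descending.

    Ties receive the arithmetic mean of the positions they occupy, so the
    rank sum is always n(n+1)/2.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise InputError("ranking requires at least 2 samples")
    vals = s.to_numpy()
    key = -vals if descending else vals
    order = np.argsort(key, kind="stable")
    ranks = np.empty(len(vals))
    pos = 1.0
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and key[order[j + 1]] == key[order[i]]:
            j += 1
        avg = (pos + pos + (j - i)) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        pos += j - i + 1
        i = j + 1
    return pd.Series(ranks, index=s.index, name="aromatic_rank")


def calibrate_response_factor(
    reference: SpectraMatrix, known_klason_pct: float, ions: IonRoleMap | None = None
) -> LigninCalibration:
    """Build the single-point lignin calibration from a mean-normalized
    reference spectrum of known Klason lignin content."""
    ions = ions or IonRoleMap()
    if reference.norm_state != "mean":
        raise InputError(
            f"calibration expects a mean-normalized reference, got {reference.norm_state!r}"
        )
    if reference.n_spectra != 1:
        raise InputError("calibration reference must be a single spectrum")
    ref_sum = float(reference.ion_sum(ions.lignin_ions)[0])
    if ref_sum <= 0:
        raise InputError("reference spectrum has zero lignin-ion intensity")
    return LigninCalibration(
        reference_lignin_ion_sum=ref_sum,
        known_klason_pct=float(known_klason_pct),
        norm_state="mean",
    )


def estimate_lignin(
    m: SpectraMatrix, cal: LigninCalibration, ions: IonRoleMap | None = None
) -> pd.Series:
    """Per-sample lignin content (% DW) = response factor x lignin-ion sum."""
    ions = ions or IonRoleMap()
    if m.norm_state != cal.norm_state:
        raise InputError(
            f"calibration was built on {cal.norm_state!r}-normalized intensities "
            f"but spectra are {m.norm_state!r}; refusing mismatched normalization"
        )
    vals = cal.response_factor * m.ion_sum(ions.lignin_ions)
    return pd.Series(vals, index=m.sample_ids, name="lignin_pct")


def sg_ratio(m: SpectraMatrix, ions: IonRoleMap | None = None) -> pd.Series:
    """Syringyl-to-guaiacyl ratio: S-ion sum over G-ion sum per sample.

    A ratio of sums is invariant to rescaling a spectrum, so mean- and
    TIC-normalized inputs give identical ratios; raw input is refused to
    keep the normalization contract explicit. Samples with zero G-ion
    sum are reported as NaN with a warning.
    """
    ions = ions or IonRoleMap()
    if m.norm_state not in ("mean", "tic"):
        raise InputError(
            f"sg_ratio requires normalized spectra (mean or tic), got {m.norm_state!r}"
        )
    s = m.ion_sum(ions.s_ions)
    g = m.ion_sum(ions.g_ions)
    out = np.full(m.n_spectra, np.nan)
    ok = g > 0
    out[ok] = s[ok] / g[ok]
    for i in np.flatnonzero(~ok):
        warnings.warn(
            f"sample {m.sample_ids[i]!r} has zero guaiacyl-ion intensity; "
            "S/G undefined (reported as missing)",
            stacklevel=2,
        )
    return pd.Series(out, index=m.sample_ids, name="sg_ratio")
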