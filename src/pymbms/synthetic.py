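"""Synthetic paired py-MBMS / GC-MS data with known ground truth.

No raw leaf spectra are publicly deposited for the study system this
package targets, so every pipeline stage is exercised against a latent
mixture model that reproduces the *statistical* structure the analysis
assumes, with ground truth returned for recovery tests:

* each leaf spectrum is a convex mixture of phenomenological component
  signatures — sugar-derived ions (m/z 43, 57, 71, 85, 95, 97),
  aromatic-metabolite ions (68, 71, 77, 91, 94, 105, 107, 108, 122),
  syringyl- and guaiacyl-lignin ions, and a broad baseline;
* sugar and aromatic latent fractions are negatively coupled by exact
  compositional substitution (sugar absorbs what aromatic releases),
  the mechanism implied by closure-normalized TIC data;
* m/z 71 is deliberately planted in BOTH the sugar and aromatic
  signatures, mirroring the published confounded ion;
* duplicate instrument replicates receive independent multiplicative
  (lognormal, mean-1) noise and a random loading factor;
* the GC/MS aromatic metabolite total is linearly coupled to the latent
  aromatic fraction with multiplicative noise, then split across
  individual metabolites; non-aromatic metabolites track the sugar
  fraction the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import InputError
from .metabolites import MetaboliteTable
from .screening import IonRoleMap
from .spectra import SpectraMatrix

MZ_LO, MZ_HI = 30, 450


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a ~200-genotype leaf screening set analyzed in
    duplicate: aromatic latent fraction uniform on [0.02, 0.20], lignin
    fraction uniform on [0.06, 0.14] (leaf-level lignin, well below
    woody stems), true S/G uniform on [0.4, 0.9], 5% multiplicative
    spectral noise per bin, and a GC/MS aromatic total proportional to
    the aromatic fraction with 25% multiplicative noise — a noise level
    chosen once to place score-vs-GC/MS correlations in the
    high-but-imperfect regime typical of this screen.
    """

    n_samples: int = 200
    n_replicates: int = 2
    aromatic_low: float = 0.02
    aromatic_high: float = 0.20
    sugar_base: float = 0.55          # sugar_i = sugar_base - aromatic_i
    lignin_low: float = 0.06
    lignin_high: float = 0.14
    sg_low: float = 0.4
    sg_high: float = 0.9
    spectral_noise_sd: float = 0.05   # per-bin multiplicative, lognormal mean-1
    loading_sd: float = 0.10          # per-replicate total-intensity factor
    gcms_slope: float = 400.0         # ug/g DW aromatic total per unit fraction
    gcms_noise_sd: float = 0.25
    other_slope: float = 100.0
    other_noise_sd: float = 0.25
    n_aromatic_metabolites: int = 8
    n_other_metabolites: int = 12
    metabolite_dispersion: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("spectral_noise_sd", "loading_sd", "gcms_noise_sd",
                     "other_noise_sd", "metabolite_dispersion"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be nonnegative")
        if not 0 <= self.aromatic_low <= self.aromatic_high < 1:
            raise InputError("aromatic fraction bounds must satisfy 0 <= lo <= hi < 1")
        if self.sugar_base - self.aromatic_high <= 0:
            raise InputError("sugar_base too small: sugar fraction would go negative")
        if 1.0 - self.sugar_base - self.lignin_high <= 0:
            raise InputError("infeasible fractions: baseline would go negative")
        if not 0 < self.lignin_low <= self.lignin_high:
            raise InputError("lignin fraction bounds must be positive and ordered")
        if not 0 < self.sg_low <= self.sg_high:
            raise InputError("S/G bounds must be positive and ordered")
        if self.n_samples < 2 or self.n_replicates < 1:
            raise InputError("need n_samples >= 2 and n_replicates >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LatentComposition:
    """Ground-truth per-sample latent fractions (sum to 1) and true S/G."""

    sample_ids: list[str]
    sugar: np.ndarray
    aromatic: np.ndarray
    lignin: np.ndarray
    baseline: np.ndarray
    sg_true: np.ndarray

    def __post_init__(self) -> None:
        total = self.sugar + self.aromatic + self.lignin + self.baseline
        if not np.allclose(total, 1.0, atol=1e-12):
            raise InputError("latent fractions must sum to 1")
        for name in ("sugar", "aromatic", "lignin", "baseline"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise InputError(f"latent {name} fraction outside [0, 1]")
        if np.any(self.sg_true <= 0):
            raise InputError("sg_true must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "sugar": self.sugar,
                "aromatic": self.aromatic,
                "lignin": self.lignin,
                "baseline": self.baseline,
                "sg_true": self.sg_true,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# component signatures

def _uniform_profile(mz: np.ndarray, support) -> np.ndarray:
    prof = np.zeros(len(mz))
    idx = np.searchsorted(mz, sorted(support))
    prof[idx] = 1.0 / len(support)
    return prof


def build_signatures(ions: IonRoleMap | None = None) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Phenomenological component signatures on the m/z 30-450 axis.

    Each profile is nonnegative and sums to 1. The baseline spreads over
    every bin not claimed by a marker role, so marker-ion sums isolate
    single components exactly in the noiseless case.
    """
    ions = ions or IonRoleMap()
    mz = np.arange(MZ_LO, MZ_HI + 1)
    role_ions = (ions.sugar_ions | ions.aromatic_ions | ions.lignin_ions)
    baseline_support = [z for z in mz.tolist() if z not in role_ions]
    profiles = {
        "sugar": _uniform_profile(mz, ions.sugar_ions),
        "aromatic": _uniform_profile(mz, ions.aromatic_ions),
        "lignin_S": _uniform_profile(mz, ions.s_ions),
        "lignin_G": _uniform_profile(mz, ions.g_ions),
        "baseline": _uniform_profile(mz, baseline_support),
    }
    return mz, profiles


def _lognormal_factor(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Multiplicative noise factor with mean 1 and sd ~ `sd` (lognormal)."""
    if sd == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(sd * sd))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# generation

def sample_composition(cfg: SyntheticConfig, rng: np.random.Generator) -> LatentComposition:
    cfg.validate()
    n = cfg.n_samples
    aromatic = rng.uniform(cfg.aromatic_low, cfg.aromatic_high, n)
    lignin = rng.uniform(cfg.lignin_low, cfg.lignin_high, n)
    sg_true = rng.uniform(cfg.sg_low, cfg.sg_high, n)
    sugar = cfg.sugar_base - aromatic          # exact -1 substitution
    baseline = 1.0 - cfg.sugar_base - lignin   # baseline absorbs lignin variation
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return LatentComposition(
        sample_ids=ids, sugar=sugar, aromatic=aromatic,
        lignin=lignin, baseline=baseline, sg_true=sg_true,
    )


def _mixture_rows(comp: LatentComposition, profiles: dict[str, np.ndarray]) -> np.ndarray:
    ls = comp.lignin * comp.sg_true / (1.0 + comp.sg_true)
    lg = comp.lignin / (1.0 + comp.sg_true)
    F = np.column_stack([comp.sugar, comp.aromatic, ls, lg, comp.baseline])
    P = np.vstack([profiles[k] for k in ("sugar", "aromatic", "lignin_S", "lignin_G", "baseline")])
    return F @ P


def generate_dataset(
    cfg: SyntheticConfig, ions: IonRoleMap | None = None
) -> tuple[SpectraMatrix, MetaboliteTable, LatentComposition]:
    """Generate a paired spectra matrix, metabolite table and truth record.

    Spectra are raw (unnormalized): each replicate row is the latent
    mixture times independent per-bin multiplicative noise and a random
    loading factor, so TIC normalization has real work to do.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ions = ions or IonRoleMap()
    mz, profiles = build_signatures(ions)
    comp = sample_composition(cfg, rng)
    base = _mixture_rows(comp, profiles)

    rows, sample_ids, replicate_ids = [], [], []
    for i, sid in enumerate(comp.sample_ids):
        for r in range(cfg.n_replicates):
            noise = _lognormal_factor(rng, cfg.spectral_noise_sd, len(mz))
            loading = _lognormal_factor(rng, cfg.loading_sd, 1)[0]
            rows.append(base[i] * noise * loading)
            sample_ids.append(sid)
            replicate_ids.append(f"r{r + 1}")
    spectra = SpectraMatrix(
        sample_ids=sample_ids, mz=mz, intensities=np.vstack(rows),
        replicate_ids=replicate_ids, norm_state="raw",
    )

    table = _metabolite_table(cfg, comp, rng)
    return spectra, table, comp


def _split_total(
    totals: np.ndarray, weights: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Split per-sample totals across metabolites with dispersion, keeping
    row sums exactly equal to the totals."""
    n, k = len(totals), len(weights)
    raw = weights[None, :] * _lognormal_factor(rng, dispersion, (n, k))
    raw /= raw.sum(axis=1, keepdims=True)
    return totals[:, None] * raw


def _metabolite_table(
    cfg: SyntheticConfig, comp: LatentComposition, rng: np.random.Generator
) -> MetaboliteTable:
    arom_total = cfg.gcms_slope * comp.aromatic * _lognormal_factor(
        rng, cfg.gcms_noise_sd, cfg.n_samples
    )
    other_total = cfg.other_slope * comp.sugar * _lognormal_factor(
        rng, cfg.other_noise_sd, cfg.n_samples
    )
    w_arom = rng.dirichlet(np.full(cfg.n_aromatic_metabolites, 2.0))
    w_other = rng.dirichlet(np.full(cfg.n_other_metabolites, 2.0))
    arom = _split_total(arom_total, w_arom, cfg.metabolite_dispersion, rng)
    other = _split_total(other_total, w_other, cfg.metabolite_dispersion, rng)
    names = [f"aromatic_met_{j + 1:02d}" for j in range(cfg.n_aromatic_metabolites)]
    names += [f"other_met_{j + 1:02d}" for j in range(cfg.n_other_metabolites)]
    flags = np.array([True] * cfg.n_aromatic_metabolites + [False] * cfg.n_other_metabolites)
    return MetaboliteTable(
        sample_ids=list(comp.sample_ids),
        metabolite_names=names,
        abundances=np.hstack([arom, other]),
        aromatic_flags=flags,
    )


def make_reference_spectrum(
    lignin_fraction: float,
    known_klason_pct: float,
    ions: IonRoleMap | None = None,
    sg: float = 0.65,
    aromatic_fraction: float = 0.05,
    sugar_fraction: float = 0.45,
) -> tuple[SpectraMatrix, float]:
    """Noiseless single-spectrum calibration standard of known lignin %.

    Returns the raw reference spectrum and the Klason percentage; run it
    through ``mean_normalize`` + ``calibrate_response_factor`` to obtain
    the calibration. Because the reference is noiseless, estimating any
    noiseless sample against it returns exactly
    ``known_klason_pct * (lignin ion sum_i / lignin ion sum_ref)``.
    """
    if not 0 < lignin_fraction <= 1:
        raise InputError("lignin_fraction must lie in (0, 1]")
    if sg <= 0:
        raise InputError("reference S/G must be positive")
    baseline = 1.0 - lignin_fraction - aromatic_fraction - sugar_fraction
    if baseline < 0:
        raise InputError("reference fractions exceed 1")
    ions = ions or IonRoleMap()
    _, profiles = build_signatures(ions)
    comp = LatentComposition(
        sample_ids=["reference"],
        sugar=np.array([sugar_fraction]),
        aromatic=np.array([aromatic_fraction]),
        lignin=np.array([lignin_fraction]),
        baseline=np.array([baseline]),
        sg_true=np.array([sg]),
    )
    mz = np.arange(MZ_LO, MZ_HI + 1)
    row = _mixture_rows(comp, profiles)
    spec = SpectraMatrix(
        sample_ids=["reference"], mz=mz, intensities=row,
        replicate_ids=None, norm_state="raw",
    )
    return spec, float(known_klason_pct)
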