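"""End-to-end orchestration of the rapid screening analysis.

``run_screen`` takes raw replicate spectra to a per-sample phenotype
table (aromatic score, rank, lignin % DW, S/G); ``run_validation``
compares the spectral score against a GC/MS trait by Pearson, Spearman
(the published "correlation based on ranking") and R^2.

Pipeline order is fixed: each replicate spectrum is normalized first
(removing shot-to-shot loading differences), then replicates are
averaged. Every run emits a machine-readable manifest carrying the
seed, the ion sets and a hash of the configuration, so any numeric
output is reproducible bit-for-bit from (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import CorrelationReport, correlation_report
from .errors import InputError
from .metabolites import MetaboliteTable, aromatic_fraction, aromatic_sum
from .screening import (
    IonRoleMap,
    LigninCalibration,
    aromatic_ion_score,
    estimate_lignin,
    rank_samples,
    sg_ratio,
)
from .spectra import SpectraMatrix, average_replicates, mean_normalize, tic_normalize

log = logging.getLogger(__name__)

try:
    __version__ = metadata.version("pymbms")
except metadata.PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


@dataclass
class RunConfig:
    """Configuration for a screening run."""

    spectra_path: str | None = None
    metabolites_path: str | None = None
    calibration_path: str | None = None
    ions_path: str | None = None
    trait: str = "fraction"          # "fraction" | "sum"
    rank_descending: bool = True     # rank 1 = most aromatic
    cv_mode: str = "single"          # "single" | "repeated"
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "spectra_path", "metabolites_path", "calibration_path", "ions_path",
            "trait", "rank_descending", "cv_mode", "seed", "outdir",
        )}

    def config_hash(self) -> str:
        # outdir is excluded: the output location does not affect any number
        fields = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        canon = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def config_manifest(cfg: RunConfig, ions: IonRoleMap, extra: dict | None = None) -> dict:
    manifest = {
        "tool": "pymbms",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "ion_sets": ions.to_dict(),
    }
    if extra:
        manifest.update(extra)
    return manifest


def screen_spectra(
    raw: SpectraMatrix,
    calibration: LigninCalibration | None = None,
    ions: IonRoleMap | None = None,
    rank_descending: bool = True,
) -> pd.DataFrame:
    """Raw replicate spectra -> per-sample screening phenotypes.

    Each replicate is normalized (TIC for the score, mean for lignin and
    S/G), then replicates are averaged. Without a calibration the lignin
    column is reported missing (partial-input runs still succeed).
    """
    ions = ions or IonRoleMap()
    if ions.confounded_ions:
        log.info(
            "confounded ions shared by sugar and aromatic sets: %s",
            sorted(ions.confounded_ions),
        )
    tic = average_replicates(tic_normalize(raw))
    mean = average_replicates(mean_normalize(raw))

    score = aromatic_ion_score(tic, ions)
    rank = rank_samples(score, descending=rank_descending)
    sg = sg_ratio(mean, ions)
    if calibration is not None:
        lignin = estimate_lignin(mean, calibration, ions)
    else:
        log.info("no lignin calibration supplied; lignin_pct reported as missing")
        lignin = pd.Series(np.nan, index=mean.sample_ids, name="lignin_pct")
    return pd.DataFrame(
        {
            "sample": tic.sample_ids,
            "aromatic_score": score.to_numpy(),
            "aromatic_rank": rank.to_numpy(),
            "lignin_pct": lignin.to_numpy(),
            "sg_ratio": sg.to_numpy(),
        }
    )


def run_screen(
    cfg: RunConfig,
    spectra: SpectraMatrix | None = None,
    calibration: LigninCalibration | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full screening run from a config; returns (result table, manifest).

    Inputs may be passed in memory or read from the configured paths.
    When ``cfg.outdir`` is set, the result TSV (with a commented
    provenance header) and the manifest JSON are written there.
    """
    from .spectra import read_spectra  # local import keeps module load light

    ions = IonRoleMap.from_yaml(cfg.ions_path) if cfg.ions_path else IonRoleMap()
    if spectra is None:
        if cfg.spectra_path is None:
            raise InputError("no spectra supplied (neither in memory nor by path)")
        spectra = read_spectra(cfg.spectra_path)
    if calibration is None and cfg.calibration_path:
        calibration = LigninCalibration.from_yaml(cfg.calibration_path)

    results = screen_spectra(
        spectra, calibration=calibration, ions=ions,
        rank_descending=cfg.rank_descending,
    )
    manifest = config_manifest(cfg, ions, extra={"n_samples": len(results)})
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_result_table(results, outdir / "screen_results.tsv", manifest)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return results, manifest


def write_result_table(df: pd.DataFrame, path, manifest: dict) -> None:
    """TSV with a commented provenance header block."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pymbms {manifest.get('version')}\n")
        fh.write(f"# seed: {manifest.get('seed')}\n")
        fh.write(f"# config_hash: {manifest.get('config_hash')}\n")
        for name, ionset in manifest.get("ion_sets", {}).items():
            if isinstance(ionset, list):
                fh.write(f"# {name}: {','.join(str(i) for i in ionset)}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_validation(
    results: pd.DataFrame,
    metabolites: MetaboliteTable,
    trait: str = "fraction",
) -> tuple[CorrelationReport, pd.DataFrame]:
    """Validate the spectral screen against the GC/MS trait.

    The trait is either the aromatic *fraction* (default) or the raw
    aromatic *sum*. Returns the correlation report plus a rank-vs-rank
    comparison table.
    """
    if trait == "fraction":
        t = aromatic_fraction(metabolites)
    elif trait == "sum":
        t = aromatic_sum(metabolites)
    else:
        raise InputError(f"unknown trait variant {trait!r}; use 'fraction' or 'sum'")

    scores = pd.Series(
        results["aromatic_score"].to_numpy(), index=results["sample"].tolist()
    )
    t = t.dropna()
    common = [s for s in scores.index if s in t.index]
    if len(common) < 3:
        unmatched_spec = sorted(set(scores.index) - set(t.index))
        unmatched_met = sorted(set(t.index) - set(scores.index))
        raise InputError(
            f"need >= 3 overlapping samples, found {len(common)}; "
            f"spectra-only samples {unmatched_spec}; metabolite-only {unmatched_met}"
        )
    x = scores.loc[common].to_numpy()
    y = t.loc[common].to_numpy()
    report = correlation_report(x, y)
    ranks = pd.DataFrame(
        {
            "sample": common,
            "rank_py_mbms": rank_samples(pd.Series(x, index=common)).to_numpy(),
            "rank_gcms": rank_samples(pd.Series(y, index=common)).to_numpy(),
        }
    )
    return report, ranks
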