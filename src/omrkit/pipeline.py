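"""End-to-end orchestration: simulate -> quantify -> stats -> threshold.

Every stage reads and writes plain CSV/JSON so each is independently
runnable and auditable; the thin :mod:`omrkit.cli` wraps these functions for
the shell.  All randomness flows from explicit integer seeds, and manifests
contain content checksums, so a rerun with the same seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .arena import SessionConfig, light_conditions, session_config_from_dict
from .errors import OMRKitError
from .metrics import FollowingCriterion, quantify_session, results_to_frame
from .stats import PARAMETERS, WavelengthSeries, run_cascade
from .synthetic import CohortRecord, SimFishConfig, generate_cohort, phenotype_template
from .threshold import (
    ThresholdEstimate,
    boundary_from_grid,
    classify_wavelength,
    psychometric_fit,
    two_round_plan,
)
from .trajectory import read_track, write_track

logger = logging.getLogger("omrkit")

__all__ = [
    "parse_grid",
    "simulate_dataset",
    "quantify_dataset",
    "quantify_records",
    "stats_report",
    "threshold_report",
    "two_round_experiment",
]


def parse_grid(spec: str) -> list[float]:
    """Parse ``start:stop:step`` (inclusive) or a comma list into wavelengths."""
    if ":" in spec:
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(f"grid spec {spec!r} must be start:stop:step")
        start, stop, step = (float(p) for p in parts)
        return [float(w) for w in np.arange(start, stop + 0.5 * step, step)]
    return [float(p) for p in spec.split(",")]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_dataset(
    template: str | SimFishConfig,
    n_fish: int,
    grid: Sequence[float],
    seed: int,
    out_dir: str | Path,
    species: str | None = None,
    session: SessionConfig | None = None,
    **template_overrides,
) -> dict:
    """Generate a cohort, write canonical track CSVs and a manifest JSON."""
    if isinstance(template, str):
        template = phenotype_template(template, **template_overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(
        template, n_fish, grid, base_seed=seed, session=session,
        species=species, photon_flux=light_conditions(),
    )
    entries = []
    for rec in records:
        name = f"{rec.session.fish_id}_{int(round(rec.session.wavelength_nm))}nm.csv"
        path = out / name
        write_track(rec.trajectory, path)
        entries.append(
            {
                "path": name,
                "fish_id": rec.session.fish_id,
                "wavelength_nm": rec.session.wavelength_nm,
                "seed": list(rec.seed),
                "sha256": _sha256(path),
                "session": rec.session.to_dict(),
            }
        )
    manifest = {
        "run_id": f"sim-seed{seed}",
        "omrkit_version": __version__,
        "template": asdict(template),
        "species": species or template.phenotype,
        "n_fish": n_fish,
        "grid": [float(w) for w in grid],
        "seed": seed,
        "files": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("%s: wrote %d tracks to %s", manifest["run_id"], len(entries), out)
    return manifest


def quantify_records(
    records: Sequence[CohortRecord],
    criterion: FollowingCriterion | None = None,
) -> pd.DataFrame:
    """Quantify in-memory cohort records into the tidy per-fish parameter frame."""
    results = [quantify_session(r.trajectory, r.session, criterion) for r in records]
    return results_to_frame(results)


def quantify_dataset(
    in_dir: str | Path,
    out_csv: str | Path | None = None,
    strict: bool = False,
    criterion: FollowingCriterion | None = None,
) -> pd.DataFrame:
    """Quantify every track listed in a dataset manifest.

    Per-file failures are logged and skipped unless ``strict``; the run
    raises only if nothing could be quantified.
    """
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    rows = []
    failures = []
    for entry in manifest["files"]:
        path = in_dir / entry["path"]
        try:
            cfg = session_config_from_dict(entry["session"])
            traj = read_track(path, cfg)
            rows.append(quantify_session(traj, cfg, criterion).to_dict())
        except (OMRKitError, OSError) as exc:
            failures.append((str(path), str(exc)))
            logger.warning("skipping %s: %s", path, exc)
            if strict:
                raise
    if not rows:
        raise OMRKitError("no track could be quantified")
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    df.attrs["failures"] = failures
    return df


def stats_report(
    params: pd.DataFrame,
    parameters: Sequence[str] = PARAMETERS,
    alpha: float = 0.05,
    control_level: float | None = None,
) -> dict:
    """Run the statistics cascade for each requested parameter."""
    report: dict = {"alpha": alpha, "control_level": control_level, "parameters": {}}
    for p in parameters:
        series = WavelengthSeries.from_frame(params, p)
        result = run_cascade(series, alpha=alpha, control_level=control_level)
        report["parameters"][p] = result.to_dict()
    return report


def threshold_report(
    params: pd.DataFrame,
    zero_band: float = 1.0,
    alpha: float = 0.05,
    fit: bool = True,
    species: str | None = None,
) -> dict:
    """Classify each wavelength and estimate the visible-invisible boundary."""
    if species is None and "species" in params and params["species"].notna().any():
        species = str(params["species"].dropna().iloc[0])
    classifications = []
    for w, grp in params.groupby("wavelength_nm"):
        classifications.append(
            classify_wavelength(grp["distance_rounds"].to_numpy(), zero_band=zero_band,
                                alpha=alpha, wavelength_nm=float(w))
        )
    estimate = boundary_from_grid(classifications, species=species)
    report = {
        "species": species,
        "classifications": [
            {
                "wavelength_nm": c.wavelength_nm,
                "n": c.n,
                "mean_distance_rounds": c.mean_distance,
                "sign_flip_p": c.sign_flip_p,
                "positive": c.positive,
            }
            for c in sorted(classifications, key=lambda c: c.wavelength_nm)
        ],
        "boundary": {
            "last_positive_nm": estimate.last_positive_nm,
            "first_negative_nm": estimate.first_negative_nm,
            "flags": estimate.flags,
        },
    }
    if fit:
        means = params.groupby("wavelength_nm")["distance_rounds"].mean()
        psf = psychometric_fit(means.index.to_numpy(), means.to_numpy())
        report["psychometric"] = {
            "status": psf.status,
            "lambda50_nm": psf.lambda50_nm,
            "slope_nm": psf.slope_nm,
            "reason": psf.reason,
        }
    return report


def two_round_experiment(
    template: SimFishConfig,
    base_seed: int,
    n_fish: int = 6,
    round1_grid: Sequence[float] = tuple(range(700, 1001, 50)),
    round2_step: float = 20.0,
    session: SessionConfig | None = None,
    zero_band: float = 1.0,
    species: str | None = None,
) -> dict:
    """The full two-round narrowing protocol on simulated cohorts.

    Round 1 scans a coarse grid; its boundary plans a finer round-2 grid;
    round 2 uses fresh fish (different seeds, as in the real protocol) and
    yields the final boundary interval plus a psychometric fit over the
    cohort means of both rounds.
    """
    rec1 = generate_cohort(template, n_fish, round1_grid, base_seed=base_seed,
                           session=session, species=species)
    df1 = quantify_records(rec1)
    rep1 = threshold_report(df1, zero_band=zero_band, fit=False, species=species)
    est1 = ThresholdEstimate(
        species=species,
        last_positive_nm=rep1["boundary"]["last_positive_nm"],
        first_negative_nm=rep1["boundary"]["first_negative_nm"],
        flags=rep1["boundary"]["flags"],
    )
    grid2 = two_round_plan(est1, round1_grid, round2_step)
    rec2 = generate_cohort(template, n_fish, grid2, base_seed=base_seed + 1_000_003,
                           session=session, species=species)
    df2 = quantify_records(rec2)
    rep2 = threshold_report(df2, zero_band=zero_band, fit=False, species=species)

    # psychometric fit over the union of both rounds' cohort means
    both = pd.concat([df1, df2], ignore_index=True)
    means = both.groupby("wavelength_nm")["distance_rounds"].mean()
    psf = psychometric_fit(means.index.to_numpy(), means.to_numpy())
    return {
        "round1": rep1,
        "round2_grid": [float(w) for w in grid2],
        "round2": rep2,
        "boundary": rep2["boundary"],
        "psychometric": {"status": psf.status, "lambda50_nm": psf.lambda50_nm, "slope_nm": psf.slope_nm},
    }
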