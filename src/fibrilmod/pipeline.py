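"""Manifest-driven pipeline: QC -> contact maps -> deltas -> modulation ->
binding -> chain metrics (-> ThT fits when kinetics are provided).

The manifest is a TSV with columns condition_label, ratio, topology,
trajectory, skip_frames — one row per simulated condition.  All inputs are
validated before any computation; every numeric output embeds the resolved
configuration, and a machine-readable run manifest records input hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .binding import (
    ligand_count_profile,
    mediated_contact_map,
    residence_analysis,
    write_binding_profile_tsv,
    write_residence_tsv,
)
from .config import RunConfig
from .contacts import compute_contact_map, contact_delta, write_contact_map_tsv
from .errors import ValidationError
from .fibrils import NativeContactSet, read_contacts_tsv
from .kinetics import dose_response_summary, fit_logistic, read_kinetics_csv
from .metrics import flory_fit, radius_of_gyration, write_rg_tsv
from .modulation import RatioSeries, modulation_coefficients, write_modulation_tsv
from .trajectory import LigandCondition, apply_qc_filter, load_ensemble

log = logging.getLogger("fibrilmod")

_MANIFEST_COLS = ["condition_label", "ratio", "topology", "trajectory", "skip_frames"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_MANIFEST_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if df.empty:
        raise ValidationError("manifest lists no conditions")
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    manifest: str | Path,
    native_contacts: str | Path | None = None,
    kinetics_csv: str | Path | None = None,
    frame_dt: float | None = None,
) -> Path:
    """Execute the full analysis over a per-condition manifest.

    Returns the output directory.  ``native_contacts`` is a contacts TSV
    (one fibril structure or a cluster consensus) enabling the modulation
    stage; ``kinetics_csv`` a long-format plate table enabling ThT fits.
    """
    config.validate()
    manifest = Path(manifest)
    df = read_manifest(manifest)

    # fail before any computation if anything is missing
    absent = []
    for _, row in df.iterrows():
        for col in ("topology", "trajectory"):
            p = manifest.parent / str(row[col])
            if not p.exists():
                absent.append(str(p))
    if native_contacts is not None and not Path(native_contacts).exists():
        absent.append(str(native_contacts))
    if kinetics_csv is not None and not Path(kinetics_csv).exists():
        absent.append(str(kinetics_csv))
    if absent:
        raise ValidationError(f"missing input files: {absent}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    hashes = {}

    conditions, maps = [], []
    for _, row in df.iterrows():
        label = str(row["condition_label"])
        cond = LigandCondition(ratio=float(row["ratio"]), label=label)
        topo = manifest.parent / str(row["topology"])
        traj = manifest.parent / str(row["trajectory"])
        hashes[str(traj)] = _sha256(traj)
        ens = load_ensemble(topo, traj, cond, skip_frames=int(row["skip_frames"]),
                            frame_dt=frame_dt)
        qc_report = None
        if ens.boxes is not None:
            if config.qc_filter:
                ens, qc_report = apply_qc_filter(ens, config.qc_threshold)
            (out / f"qc_{label}.json").write_text(json.dumps(qc_report or {}))
        log.info("condition %s: %d frames after QC", label, ens.n_frames)

        cmap = compute_contact_map(ens, config.contact_cutoff, config.min_separation)
        write_contact_map_tsv(cmap, out / f"contacts_{label}.tsv")
        conditions.append(cond)
        maps.append(cmap)

        rg = radius_of_gyration(ens, weighting="uniform", n_blocks=config.n_blocks)
        write_rg_tsv(rg, out / f"rg_{label}.tsv")
        if ens.topology.n_residues >= 8:
            ff = flory_fit(ens, config.flory_prefactor, config.flory_fit_range)
            (out / f"flory_{label}.json").write_text(
                json.dumps({"nu": ff.nu, "prefactor_nm": ff.prefactor,
                            "fit_range": ff.fit_range, "residual": ff.residual})
            )

        if ens.topology.n_ligands:
            profile = ligand_count_profile(ens, config.contact_cutoff)
            write_binding_profile_tsv(profile, out / f"nligand_{label}.tsv")
            med = mediated_contact_map(ens, config.mediated_cutoff,
                                       config.min_separation)
            pd.DataFrame(
                [(i, j, p) for (i, j), p in sorted(med.pairs.items())],
                columns=["i", "j", "P_isj"],
            ).to_csv(out / f"mediated_{label}.tsv", sep="\t", index=False)
            try:
                stats = residence_analysis(ens, config.r_on, config.r_off)
                write_residence_tsv(stats, out / f"residence_{label}.tsv")
            except ValueError:
                log.warning("non-uniform frame spacing: residence analysis skipped")

    # contact deltas against the lowest-ratio condition
    ref_idx = min(range(len(conditions)), key=lambda k: conditions[k].ratio)
    for k, (cond, cmap) in enumerate(zip(conditions, maps)):
        if k == ref_idx:
            continue
        delta = contact_delta(cmap, maps[ref_idx])
        pd.DataFrame(
            [(i, j, v) for (i, j), v in sorted(delta.pairs.items())],
            columns=["i", "j", "dP"],
        ).to_csv(out / f"delta_{cond.label}.tsv", sep="\t", index=False)

    if native_contacts is not None and len(maps) >= 2:
        native: NativeContactSet = read_contacts_tsv(native_contacts)
        series = RatioSeries(conditions=conditions, maps=maps)
        mod = modulation_coefficients(series, native)
        write_modulation_tsv(mod, out / "modulation.tsv",
                             config.sign_threshold, config.regions or None)
        log.info("modulation: %d native pairs, %d out of range",
                 len(mod.entries), mod.n_skipped_out_of_range)

    if kinetics_csv is not None:
        datasets = read_kinetics_csv(kinetics_csv)
        results = [fit_logistic(ds, n_boot=500, seed=config.seed) for ds in datasets]
        summary = dose_response_summary(results)
        with open(out / "tht_summary.tsv", "w") as fh:
            fh.write("\n".join(config.header_lines()) + "\n")
            summary.to_csv(fh, sep="\t", index=False)

    (out / "run_manifest.json").write_text(json.dumps({
        "inputs": hashes,
        "conditions": [{"label": c.label, "ratio": c.ratio} for c in conditions],
        "config": json.loads((out / "config.json").read_text()),
    }, indent=1))
    return out
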