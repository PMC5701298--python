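"""End-to-end orchestration: simulate -> profiles -> mutations -> cells ->
subclones, with a deterministic run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cells as cells_mod
from . import mutations as mut
from . import profiles as prof
from . import subclones as sub
from .grid import BinGrid
from .simulate import (
    CNEvent,
    MutationSpec,
    SimConfig,
    simulate_cell_depths,
    simulate_mutation_calls,
    simulate_region_depths,
    simulate_truth,
)

log = logging.getLogger("scith")

STAGES = ("simulate", "scna", "mutations", "cells", "subclones")


def demo_config(seed: int = 0, n_cells_per_region: int = 10) -> SimConfig:
    """A small synthetic design: four regions, a founder clone with clonal
    SCNAs, one subclone with an extra 5 Mb gain, one region-private clone,
    diploid contamination, and a trunk/branch/leaf mutation set."""
    genome = [("chr1", 50_000_000), ("chr2", 50_000_000), ("chr3", 50_000_000)]
    tree = {"founder": None, "sub": "founder", "privC": "founder"}
    events = [
        CNEvent("founder", "chr1", 0, 20_000_000, 3),
        CNEvent("founder", "chr2", 10_000_000, 30_000_000, 1),
        CNEvent("sub", "chr3", 10_000_000, 15_000_000, 4),
        CNEvent("privC", "chr1", 40_000_000, 46_000_000, 4),
    ]
    fractions = {
        "A": {"founder": 1.0},
        "B": {"founder": 0.6, "sub": 0.4},
        "C": {"founder": 0.5, "sub": 0.3, "privC": 0.2},
        "D": {"founder": 0.7, "sub": 0.3},
    }
    trunk = ("founder", "sub", "privC")
    muts = []
    pos = 1000
    for i in range(16):
        muts.append(
            MutationSpec(f"trunk{i}", "chr1", pos, "C", "T", trunk, gene=f"TG{i}")
        )
        pos += 1000
    for i in range(4):
        muts.append(
            MutationSpec(f"branch{i}", "chr2", pos, "G", "A", ("sub",), gene=f"BG{i}")
        )
        pos += 1000
    for i in range(3):
        muts.append(
            MutationSpec(f"leaf{i}", "chr3", pos, "T", "A", ("privC",), gene=f"LG{i}")
        )
        pos += 1000
    muts.append(MutationSpec("germ0", "chr1", pos, "A", "G", (), germline=True))
    pos += 1000
    muts.append(
        MutationSpec(
            "indel0", "chr2", pos, "AT", "A", trunk, gene="IG0", is_indel=True, effect="indel"
        )
    )
    return SimConfig(
        genome_spec=genome,
        clone_tree=tree,
        event_list=events,
        clone_fractions_per_region=fractions,
        diploid_contamination=0.25,
        depth_mean=100.0,
        target_mapd=0.20,
        n_cells_per_region=n_cells_per_region,
        mutation_spec=muts,
        ado_rate=0.05,
        seed=seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(config: SimConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    depths, control = simulate_cell_depths(truth, config)
    regions = simulate_region_depths(truth, config)
    caller_a, caller_b, assays, regional = simulate_mutation_calls(truth, config)
    truth.grid.to_bed(outdir / "bins.bed")
    depths.to_csv(outdir / "cell_depths.tsv", sep="\t")
    pd.Series(control, name="control").to_csv(outdir / "control.tsv", sep="\t")
    regions.to_csv(outdir / "region_depths.tsv", sep="\t")
    caller_a.to_csv(outdir / "caller_a.tsv", sep="\t", index=False)
    caller_b.to_csv(outdir / "caller_b.tsv", sep="\t", index=False)
    assays.to_csv(outdir / "assays.tsv", sep="\t", index=False)
    regional.to_csv(outdir / "regional_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "cell": truth.cells,
            "clone": [truth.cell_assignments[c] for c in truth.cells],
            "region": [truth.cell_regions[c] for c in truth.cells],
        }
    ).to_csv(outdir / "cell_truth.tsv", sep="\t", index=False)
    pd.DataFrame(truth.clone_profiles).to_csv(outdir / "clone_profiles.tsv", sep="\t")
    config.to_yaml(outdir / "sim_config.yaml")
    return {"truth": truth}


def stage_scna(
    outdir: Path, params: prof.PipelineParams | None = None
) -> tuple[dict, pd.DataFrame]:
    """Normalize + HMM every cell; returns profiles keyed by cell and QC table."""
    params = params or prof.PipelineParams()
    grid = BinGrid.from_bed(outdir / "bins.bed")
    depths = pd.read_csv(outdir / "cell_depths.tsv", sep="\t", index_col=0)
    control = pd.read_csv(outdir / "control.tsv", sep="\t", index_col=0)["control"].to_numpy()
    profiles = {}
    qc_rows = []
    for cell in depths.columns:
        p = prof.normalize_depth(depths[cell].to_numpy(), control, grid, params, cell)
        prof.infer_copy_number(p, params)
        value = prof.mapd(p)
        profiles[cell] = p
        qc_rows.append({"cell": cell, "mapd": value, "pass": value < params.mapd_threshold})
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    long = pd.concat(
        [p.to_frame().assign(cell=c) for c, p in profiles.items()], ignore_index=True
    )
    long.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    return profiles, qc


def stage_mutations(outdir: Path) -> mut.MutationMatrix:
    caller_a = mut.read_caller_table(outdir / "caller_a.tsv")
    caller_b = mut.read_caller_table(outdir / "caller_b.tsv")
    calls = mut.consensus_calls(caller_a, caller_b)
    calls = mut.apply_quality_filters(calls)
    calls = mut.rescue_low_vaf(calls)
    calls = mut.merge_indels(calls, caller_a)
    matrix = mut.build_matrix(calls)
    matrix.to_frame().to_csv(outdir / "catalog.tsv", sep="\t")
    spectrum = mut.mutation_spectrum(matrix)
    spectrum.to_csv(outdir / "spectrum.tsv", sep="\t")
    if (spectrum.sum(axis=1) > 0).all() and len(spectrum) > 1:
        import warnings

        with warnings.catch_warnings():
            # empty substitution classes are expected for small synthetic sets
            warnings.simplefilter("ignore", UserWarning)
            stat, p = mut.spectrum_test(spectrum, "chi2")
        (outdir / "spectrum_test.json").write_text(
            json.dumps({"mode": "chi2", "statistic": stat, "p": p}, indent=2)
        )
    return matrix


def build_panel(matrix: mut.MutationMatrix, patient: str, assays: pd.DataFrame):
    """Derive validation panels from the catalog: 5 ubiquitous nonsynonymous
    candidates, 14 nonsynonymous tumor-panel variants (preferring ubiquitous)."""
    nonsyn = matrix.meta[
        (matrix.meta["EFFECT"] == "nonsynonymous") & (~matrix.meta["IS_INDEL"].astype(bool))
    ].index
    ubiq = [v for v in nonsyn if matrix.category[v] == "ubiquitous"]
    if len(ubiq) < 5:
        raise ValueError("need >= 5 ubiquitous nonsynonymous variants for the candidate panel")
    candidates = ubiq[:5]
    pool = ubiq + [v for v in nonsyn if v not in ubiq]
    if len(pool) < 14:
        raise ValueError("need >= 14 nonsynonymous variants for the tumor panel")
    tumor_panel = pool[:14]
    keep = set(candidates) | set(tumor_panel)
    outcomes = assays[assays["variant"].isin(keep)].copy()
    return cells_mod.ValidationPanel(patient, candidates, tumor_panel, outcomes)


def stage_cells(
    outdir: Path,
    profiles: dict,
    matrix: mut.MutationMatrix,
    patient: str = "P1",
) -> list:
    """Classify every cell; assay variant names are mapped to catalog keys."""
    assays = pd.read_csv(outdir / "assays.tsv", sep="\t")
    caller_a = mut.read_caller_table(outdir / "caller_a.tsv")
    name_to_key = {
        row["VARIANT"]: mut.variant_key(row["CHROM"], row["POS"], row["REF"], row["ALT"])
        for _, row in caller_a.iterrows()
    }
    assays["variant"] = assays["variant"].map(name_to_key)
    assays = assays.dropna(subset=["variant"])
    panel = build_panel(matrix, patient, assays)
    cell_truth = pd.read_csv(outdir / "cell_truth.tsv", sep="\t").set_index("cell")
    records = []
    for cell, p in profiles.items():
        rec = cells_mod.CellRecord(
            cell_id=cell,
            patient=patient,
            region=str(cell_truth.loc[cell, "region"]),
            has_scna=cells_mod.ploidy_flag(p),
        )
        cells_mod.classify_cell(rec, panel)
        records.append(rec)
    pd.DataFrame(
        [
            {
                "cell": r.cell_id,
                "patient": r.patient,
                "region": r.region,
                "has_scna": r.has_scna,
                "n_present": r.n_present,
                "identity": r.identity,
            }
            for r in records
        ]
    ).to_csv(outdir / "cell_identity.tsv", sep="\t", index=False)
    cells_mod.cohort_summary(records).to_csv(outdir / "cohort_summary.tsv", sep="\t")
    return records


def stage_subclones(
    outdir: Path,
    profiles: dict,
    records: list,
    params: sub.SubcloneParams | None = None,
) -> sub.SubcloneResult:
    tumor = [r.cell_id for r in records if r.identity == "tumor"]
    if len(tumor) < 3:
        raise ValueError(f"only {len(tumor)} tumor cells: cannot run subclone analysis")
    grid = profiles[tumor[0]].grid
    matrix = pd.DataFrame(
        {c: profiles[c].cn_state for c in tumor}, index=pd.RangeIndex(len(grid))
    ).T
    _, large_scale = sub.hierarchical_cluster(matrix, k=2)
    result = sub.assign_subclones(matrix, grid, params, reference_labels=large_scale)
    result.labels.rename("cluster").to_frame().to_csv(outdir / "subclone_labels.tsv", sep="\t")
    result.events.to_csv(outdir / "subclone_events.bed", sep="\t", index=False, header=False)
    report = {
        "k": result.k,
        "frequencies": {str(k): v for k, v in result.frequencies.items()},
        "percent": {str(k): v for k, v in result.percent.items()},
        "silhouette": {str(k): v for k, v in result.silhouette.items()},
        "n_candidate_bins": int(result.candidate_bins.size),
        "n_selected_bins": int(result.selected_bins.size),
        "low_confidence": result.low_confidence,
    }
    (outdir / "subclone_report.json").write_text(json.dumps(report, indent=2))
    if result.agreement is not None:
        result.agreement.to_csv(outdir / "subclone_agreement.tsv", sep="\t")
    return result


def run_pipeline(
    config: SimConfig,
    outdir,
    stages=STAGES,
    params: prof.PipelineParams | None = None,
    subclone_params: sub.SubcloneParams | None = None,
) -> dict:
    """Execute the requested stages in dependency order; write manifest.json.

    Re-running with the same config and seed reproduces the output checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    for i, s in enumerate(stages):
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        need = STAGES[: STAGES.index(s)]
        for dep in need:
            if dep not in stages[:i] and not (outdir / _stage_marker(dep)).exists():
                raise FileNotFoundError(
                    f"stage {s!r} needs {dep!r} output ({_stage_marker(dep)}) in {outdir}"
                )
    profiles = matrix = records = None
    if "simulate" in stages:
        log.info("stage simulate")
        stage_simulate(config, outdir)
    if "scna" in stages:
        log.info("stage scna")
        profiles, _ = stage_scna(outdir, params)
    if "mutations" in stages:
        log.info("stage mutations")
        matrix = stage_mutations(outdir)
    if "cells" in stages:
        log.info("stage cells")
        if profiles is None:
            profiles, _ = stage_scna(outdir, params)
        if matrix is None:
            matrix = stage_mutations(outdir)
        records = stage_cells(outdir, profiles, matrix)
    if "subclones" in stages:
        log.info("stage subclones")
        stage_subclones(outdir, profiles, records, subclone_params)
    manifest = {
        "stages": stages,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_digest(config), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_marker(stage: str) -> str:
    return {
        "simulate": "bins.bed",
        "scna": "profiles.tsv",
        "mutations": "catalog.tsv",
        "cells": "cell_identity.tsv",
        "subclones": "subclone_report.json",
    }[stage]


def _config_digest(config: SimConfig):
    def enc(v):
        if isinstance(v, (CNEvent, MutationSpec)):
            return {k: enc(x) for k, x in v.__dict__.items()}
        if isinstance(v, (list, tuple)):
            return [enc(x) for x in v]
        if isinstance(v, dict):
            return {str(k): enc(x) for k, x in v.items()}
        if isinstance(v, np.generic):
            return v.item()
        return v

    return enc(config.__dict__)
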