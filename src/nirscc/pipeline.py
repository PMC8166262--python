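"""End-to-end orchestration: phantom -> mesh -> solve -> PMDF -> channel metrics.

`run_scc` evaluates every configured (age, fiducial, orientation, SD-distance)
channel on its age's head phantom and returns one record per channel plus the
cross-age consistency of the MLCBR per scalp point.  Forward solves are
factored once per age and cached per optode node, and absorption-perturbed
re-solves reuse the factorization as a preconditioner, so a full 61-point run
remains a desk-scale computation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .forward import (
    OpticalProperties,
    SourceSpec,
    assemble_diffusion_system,
    default_properties,
)
from .meshing import mesh_statistics, voxel_to_tetmesh
from .metrics import (
    SCCConfig,
    SCCRecord,
    consistency,
    mlcbr,
    ncbr,
    records_to_frame,
    zone_classify,
)
from .phantom import (
    FIDUCIAL_1010_LABELS,
    PhantomSpec,
    build_sphere_phantom,
    load_voxel_model_nifti,
    place_fiducials_1010,
    place_landmarks,
)
from .sensitivity import (
    ORIENTATIONS,
    SD_DISTANCES_MM,
    _region_increment_mass,
    compute_pmdf,
    place_sd_pair,
    region_pathlengths,
)

__all__ = ["RunConfig", "SCCRunResult", "run_scc", "compare_optical_properties", "region_name"]

log = logging.getLogger("nirscc")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one SCC run."""

    phantom_specs: dict = None  # age label -> PhantomSpec
    distances: tuple = SD_DISTANCES_MM
    orientations: tuple = ORIENTATIONS
    fiducial_labels: tuple = None  # None -> all 61
    properties: OpticalProperties = field(default_factory=default_properties)
    scc: SCCConfig = field(default_factory=SCCConfig)
    output_dir: str | None = None
    seed: int = 0
    delta_frac: float = 0.001
    direct_node_limit: int = 300_000
    nifti_inputs: dict = None  # age label -> (labels_path, regions_path), bypasses phantom

    def __post_init__(self):
        if self.phantom_specs is None:
            object.__setattr__(
                self,
                "phantom_specs",
                {a: PhantomSpec.for_age(a, voxel_size=2.0) for a in ("0yo", "1yo", "2yo")},
            )
        if not self.phantom_specs and not self.nifti_inputs:
            raise ValueError("at least one age must be configured")
        if len(self.distances) < 1 or len(self.orientations) < 1:
            raise ValueError("need at least one distance and one orientation")
        labels = self.fiducial_labels
        if labels is None:
            labels = tuple(FIDUCIAL_1010_LABELS)
        else:
            labels = tuple(labels)
            unknown = set(labels) - set(FIDUCIAL_1010_LABELS)
            if unknown:
                raise ValueError(f"unknown fiducial labels: {sorted(unknown)}")
            if not labels:
                raise ValueError("need at least one fiducial")
        object.__setattr__(self, "fiducial_labels", labels)

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, (PhantomSpec, SCCConfig)):
                return o.__dict__
            if isinstance(o, OpticalProperties):
                return {str(k): v.__dict__ for k, v in o.tissues.items()}
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)

        payload = json.dumps(self.__dict__, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SCCRunResult:
    records: list  # SCCRecord
    consistency: pd.DataFrame  # per fiducial x orientation x distance
    mesh_stats: dict  # age -> MeshStatistics
    pathlengths: dict  # (age, fiducial, orientation, distance) -> RegionPathlengths
    manifest: dict

    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def region_name(region_id: int, n_per_hemisphere: int) -> str:
    """Synthetic parcel name, e.g. 'L07' / 'R12' (left/right hemisphere)."""
    rid = int(region_id)
    if rid <= n_per_hemisphere:
        return f"L{rid:02d}"
    return f"R{rid - n_per_hemisphere:02d}"


def _prepare_age(config: RunConfig, age: str):
    t0 = time.perf_counter()
    if config.nifti_inputs and age in config.nifti_inputs:
        labels_path, regions_path = config.nifti_inputs[age]
        model = load_voxel_model_nifti(labels_path, regions_path)
    else:
        model = build_sphere_phantom(config.phantom_specs[age])
    lm = place_landmarks(model)
    fids = place_fiducials_1010(model, lm)
    mesh = voxel_to_tetmesh(model)
    system = assemble_diffusion_system(mesh, config.properties)
    system.direct_node_limit = config.direct_node_limit
    stats = mesh_statistics(mesh)
    log.info("age %s: %s (prep %.1fs)", age, stats, time.perf_counter() - t0)
    return model, fids, mesh, system, stats


def _channel_metrics(config, system, fids, age, label, orientation, distance):
    pair = place_sd_pair(fids, label, orientation, distance)
    pmdf = compute_pmdf(system, pair)
    L = region_pathlengths(pmdf, system.mesh)
    region, selectivity = mlcbr(L)
    n_cbr = ncbr(L, config.scc)

    # direct perturbation sensitivity of the MLCBR, reusing the cached solves
    mask = system.mesh.node_region == region
    bump = config.delta_frac * float(system.node_mu_a[mask].mean())
    dM = _region_increment_mass(system, mask, bump)
    s_nodes, s_w = system.optode_weights(pair.source_position)
    d_nodes, d_w = system.optode_weights(pair.detector_position)
    rhs = np.zeros(system.mesh.n_nodes)
    rhs[s_nodes] = s_w
    phi_base = system.solve_optode(pair.source_position)
    phi_pert = system.solve_perturbed(dM, rhs, x0=phi_base)
    i_pert = float(d_w @ phi_pert[d_nodes])
    labs = float(np.log(pmdf.base_intensity / i_pert) / bump)

    record = SCCRecord(
        fiducial_label=label,
        orientation=orientation,
        distance=float(distance),
        age_label=age,
        ncbr=n_cbr,
        mlcbr=region,
        selectivity=selectivity,
        sensitivity=labs,
        zone=zone_classify(labs, selectivity, config.scc),
        pmdf_extent=pmdf.support_size(),
    )
    return record, L, pmdf


def run_scc(config: RunConfig) -> SCCRunResult:
    """Run the full pipeline and (optionally) write reference tables.

    Returns one :class:`SCCRecord` per (age, fiducial, orientation, distance)
    plus a cross-age consistency label per (fiducial, orientation, distance)
    when all three ages are configured with a shared parcellation.
    """
    t_start = time.perf_counter()
    records: list = []
    pathlengths: dict = {}
    mesh_stats: dict = {}
    stage_times: dict = {}
    n_per_hemi = {}

    ages = list(config.phantom_specs) if not config.nifti_inputs else sorted(
        set(config.phantom_specs) | set(config.nifti_inputs)
    )
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    for age in ages:
        try:
            model, fids, mesh, system, stats = _prepare_age(config, age)
        except Exception as exc:
            raise RuntimeError(f"stage 'prepare' failed for age {age}") from exc
        mesh_stats[age] = stats
        n_per_hemi[age] = (
            config.phantom_specs[age].n_regions_per_hemisphere
            if age in (config.phantom_specs or {})
            else max(1, model.n_regions() // 2)
        )
        t0 = time.perf_counter()
        for label in config.fiducial_labels:
            for orientation in config.orientations:
                for distance in config.distances:
                    try:
                        rec, L, _ = _channel_metrics(
                            config, system, fids, age, label, orientation, distance
                        )
                    except Exception as exc:
                        if outdir and records:
                            _write_tables(outdir, records, None, config, n_per_hemi)
                        raise RuntimeError(
                            f"stage 'channel' failed for age={age} fiducial={label} "
                            f"orientation={orientation} distance={distance}"
                        ) from exc
                    rec.mlcbr_name = region_name(rec.mlcbr, n_per_hemi[age])
                    records.append(rec)
                    pathlengths[(age, label, orientation, float(distance))] = L
        stage_times[f"channels_{age}"] = time.perf_counter() - t0

    cons = _consistency_table(records, ages)
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "ages": ages,
        "n_records": len(records),
        "stage_seconds": {k: round(v, 2) for k, v in stage_times.items()},
        "total_seconds": round(time.perf_counter() - t_start, 2),
        "numpy_version": np.__version__,
    }
    result = SCCRunResult(
        records=records,
        consistency=cons,
        mesh_stats=mesh_stats,
        pathlengths=pathlengths,
        manifest=manifest,
    )
    if outdir:
        _write_tables(outdir, records, cons, config, n_per_hemi)
        _write_reference_tables(outdir, result, config, n_per_hemi)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _consistency_table(records, ages) -> pd.DataFrame:
    """Cross-age MLCBR consistency per (fiducial, orientation, distance)."""
    if set(ages) < {"0yo", "1yo", "2yo"}:
        return pd.DataFrame(
            columns=["fiducial_label", "orientation", "distance", "consistency"]
        )
    df = records_to_frame(records)
    piv = df.pivot_table(
        index=["fiducial_label", "orientation", "distance"],
        columns="age_label",
        values="mlcbr",
        aggfunc="first",
    )
    rows = []
    for (label, orientation, distance), row in piv.iterrows():
        rows.append(
            {
                "fiducial_label": label,
                "orientation": orientation,
                "distance": distance,
                "consistency": consistency(
                    int(row["0yo"]), int(row["1yo"]), int(row["2yo"])
                ),
            }
        )
    return pd.DataFrame(rows)


def _write_tables(outdir: Path, records, cons, config, n_per_hemi) -> None:
    df = records_to_frame(records)
    df.to_csv(outdir / "scc_records.tsv", sep="\t", index=False, float_format="%.4g")
    if cons is not None and len(cons):
        cons.to_csv(outdir / "consistency.tsv", sep="\t", index=False)
        # summary of completely consistent scalp points per orientation
        cc = cons[cons["consistency"] == "completely_consistent"]
        summary = (
            cc.groupby(["fiducial_label", "orientation"])["distance"]
            .apply(lambda s: ", ".join(f"{d:g}" for d in sorted(s)))
            .rename("consistent_distances_mm")
            .reset_index()
        )
        summary.to_csv(outdir / "consistency_summary.tsv", sep="\t", index=False)


def _write_reference_tables(outdir: Path, result: SCCRunResult, config, n_per_hemi) -> None:
    """Per-channel reference tables: Lnorm per parcel (3 decimals) x distance,
    with the MLCBR sensitivity (mm) as the last row, one block per age."""
    rows = []
    df = result.frame()
    for (age, label, orientation), sub in df.groupby(
        ["age_label", "fiducial_label", "orientation"]
    ):
        distances = sorted(sub["distance"].unique())
        region_ids = set()
        for d in distances:
            L = result.pathlengths[(age, label, orientation, d)]
            region_ids |= {r for r, v in L.L_norm.items() if v > 0.01}
        for rid in sorted(region_ids):
            row = {
                "age": age,
                "fiducial": label,
                "orientation": orientation,
                "region": region_name(rid, n_per_hemi[age]),
            }
            for d in distances:
                L = result.pathlengths[(age, label, orientation, d)]
                row[f"{d:g}mm"] = round(L.L_norm.get(rid, 0.0), 3)
            rows.append(row)
        row = {"age": age, "fiducial": label, "orientation": orientation, "region": "Labs_MLCBR_mm"}
        for d in distances:
            labs = float(sub.loc[sub["distance"] == d, "sensitivity"].iloc[0])
            row[f"{d:g}mm"] = round(labs, 1)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "scc_reference.tsv", sep="\t", index=False)


def compare_optical_properties(
    config: RunConfig, alt_properties: OpticalProperties
) -> dict:
    """Run the pipeline under two optical-property tables and compare channels.

    Returns the two record frames, the fraction of channels whose MLCBR agrees
    between the tables, and the mean |delta Lnorm| of the MLCBR.
    """
    from dataclasses import replace

    res_a = run_scc(replace(config, output_dir=None))
    res_b = run_scc(replace(config, output_dir=None, properties=alt_properties))
    a, b = res_a.frame(), res_b.frame()
    keys = ["age_label", "fiducial_label", "orientation", "distance"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    agreement = float((merged["mlcbr_a"] == merged["mlcbr_b"]).mean())
    dsel = float((merged["selectivity_a"] - merged["selectivity_b"]).abs().mean())
    per_fiducial = (
        merged.assign(agree=merged["mlcbr_a"] == merged["mlcbr_b"])
        .groupby("fiducial_label")["agree"]
        .mean()
    )
    return {
        "records_a": a,
        "records_b": b,
        "mlcbr_agreement": agreement,
        "per_fiducial_agreement": per_fiducial,
        "mean_abs_selectivity_difference": dsel,
    }
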