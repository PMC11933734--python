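"""End-to-end orchestration of the metastate / ESIPT analysis chain.

The pipeline mirrors the staged design of enhanced-sampling conformational
studies: descriptors are computed for a flattened ("biased") and an
equilibrium ("unbiased") ensemble; the metastate model (PCA + clustering +
sub-state decomposition) is fitted on the flattened ensemble, which visits
every basin; populations are then reported from the equilibrium ensemble's
assignment to those metastates, because an ideally flattened ensemble
carries no population information of its own.  Representatives are picked
from the equilibrium ensemble, closest to each (biased-fit) metastate's mean
descriptors, plus an "EQ" representative closest to the global equilibrium
means.  If a state-energy table is available its rows are joined to the
representatives by conformation id and converted into emission wavelengths,
Stokes shifts and an ensemble ESIPT summary; otherwise the summary is purely
geometric.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import EsiptkitError, ValidationError
from .geometry import DescriptorMatrix, DescriptorSpec, circular_mean, evaluate_descriptors
from .hbond import HBondCriterion, occupancy
from .metastates import (
    MetastateModel,
    PcaModel,
    assign_frames,
    cluster_metastates,
    decompose_substates,
    export_biplot,
    fit_pca,
    plot_biplot,
    population_report,
)
from .photophysics import classify_table, ensemble_summary, records_frame, reference_energy_records
from .representatives import (
    ESIPT_DISTANCE_THRESHOLD,
    esipt_capable_fraction,
    representatives_table,
    select_representatives,
)
from .synthetic import (
    default_template,
    generate_paired_ensembles,
    preset_landscape,
)
from .traj_io import EnergyRecord, Ensemble, read_energy_table, read_ensemble, write_ensemble

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("esiptkit.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``preset`` (synthetic generation) or the two ensemble paths must
    be given.  All stage parameters carry the documented defaults of their
    modules.
    """

    # input
    preset: Optional[str] = None  # system1 | system2 | system3
    n_frames: int = 10001
    seed: int = 0
    biased_path: Optional[str] = None
    unbiased_path: Optional[str] = None
    input_format: str = "pdb_multimodel"
    energy_table: Optional[str] = None  # path, or "builtin" for the packaged table
    # descriptors: None -> the chromophore template's default set
    descriptors: Optional[list] = None  # list of {name, kind, atoms: [[res, name], ...]}
    # PCA / clustering
    embedding: str = "raw_degrees"
    scaling: str = "auto"
    cluster_method: str = "kmeans"
    k: int = 3
    cluster_components: Optional[int] = 1
    metastate_order: str = "pc1"
    decompose: bool = True
    decompose_axis: int = 1
    population_source: str = "unbiased"  # or "biased"
    # geometry / photophysics
    hbond_distance: float = 3.0
    hbond_angle: float = 30.0
    esipt_threshold: float = ESIPT_DISTANCE_THRESHOLD
    distance_descriptor: str = "d_N_HO"
    representative_ceiling: Optional[float] = None
    # output
    output_dir: str = "esiptkit_out"
    plot: bool = False
    write_ensembles: bool = False

    def __post_init__(self):
        if self.esipt_threshold <= 0:
            raise ValidationError("esipt_threshold must be positive")
        if self.preset is None and (self.biased_path is None or self.unbiased_path is None):
            raise ValidationError("either a preset or both ensemble paths are required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Artifacts of one run; every table is also written to the output dir."""

    config: PipelineConfig
    pca: PcaModel
    metastates: MetastateModel
    substates: Optional[MetastateModel]
    populations: pd.DataFrame
    representatives: pd.DataFrame
    capable_percent: float  # frame-level, from the population-source ensemble
    capable_per_metastate: dict
    hbond_occupancy: Optional[pd.DataFrame]
    photophysics: Optional[pd.DataFrame]
    summary: dict


class _Stage:
    """Context manager that prefixes any stage failure with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise EsiptkitError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def _build_specs(config: PipelineConfig) -> list[DescriptorSpec]:
    if config.descriptors is None:
        return default_template().descriptor_specs()
    return [
        DescriptorSpec(
            name=d["name"],
            kind=d["kind"],
            atom_selectors=tuple((int(r), str(a)) for r, a in d["atoms"]),
        )
        for d in config.descriptors
    ]


def _pca_matrix(matrix: DescriptorMatrix, distance_descriptor: str) -> DescriptorMatrix:
    """Descriptor matrix restricted to the torsional descriptors used for PCA.

    The N···HO contact distance is a derived coordinate of the hydroxyl
    torsion; keeping it out of the PCA avoids double-counting that motion.
    """
    keep = [
        (j, n, k)
        for j, (n, k) in enumerate(zip(matrix.descriptor_names, matrix.kinds))
        if n != distance_descriptor
    ]
    return DescriptorMatrix(
        frame_indices=matrix.frame_indices,
        descriptor_names=[n for _, n, _ in keep],
        kinds=[k for _, _, k in keep],
        values=matrix.values[:, [j for j, _, _ in keep]],
    )


def _global_means(matrix: DescriptorMatrix) -> dict:
    means = {}
    for name, kind in zip(matrix.descriptor_names, matrix.kinds):
        col = matrix.column(name)
        means[name] = circular_mean(col) if kind == "torsion" else float(np.mean(col))
    return means


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute descriptors → PCA → clustering → decomposition → populations →
    representatives → geometry flags → (optional) photophysics → summary.

    Every stage's table is written under ``config.output_dir``; re-running
    with the same config and seed reproduces all numeric outputs exactly.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    template = default_template()
    try:
        logger.info("esiptkit %s | numpy %s | config %s",
                    __version__, np.__version__, json.dumps(config.to_dict()))

        with _Stage("input"):
            if config.preset is not None:
                landscape = preset_landscape(
                    config.preset, n_frames=config.n_frames, seed=config.seed
                )
                pair = generate_paired_ensembles(landscape, template)
                biased, unbiased = pair.biased, pair.unbiased
                pair.truth_biased.to_csv(out / "truth_biased.csv", index=False)
                pair.truth_unbiased.to_csv(out / "truth_unbiased.csv", index=False)
                if config.write_ensembles:
                    write_ensemble(biased, out / "biased.pdb")
                    write_ensemble(unbiased, out / "unbiased.pdb")
            else:
                biased = read_ensemble(config.biased_path, config.input_format)
                unbiased = read_ensemble(config.unbiased_path, config.input_format)

        with _Stage("descriptors"):
            specs = _build_specs(config)
            dm_biased = evaluate_descriptors(biased, specs)
            dm_unbiased = evaluate_descriptors(unbiased, specs)
            dm_biased.to_csv(out / "descriptors_biased.csv")
            dm_unbiased.to_csv(out / "descriptors_unbiased.csv")

        with _Stage("pca"):
            pca = fit_pca(
                _pca_matrix(dm_biased, config.distance_descriptor),
                embedding=config.embedding,
                scaling=config.scaling,
            )
            (out / "pca.json").write_text(json.dumps(export_biplot(pca), indent=1))

        with _Stage("clustering"):
            model = cluster_metastates(
                pca,
                method=config.cluster_method,
                k=config.k,
                seed=config.seed,
                components=config.cluster_components,
                order=config.metastate_order,
            )
            if config.plot:
                plot_biplot(pca, model, out / "biplot.png")

        substates = None
        if config.decompose:
            with _Stage("decomposition"):
                substates = decompose_substates(model, pca, axis=config.decompose_axis)

        with _Stage("populations"):
            unbiased_pca_matrix = _pca_matrix(dm_unbiased, config.distance_descriptor)
            if config.population_source == "unbiased":
                assigned = assign_frames(model, pca, unbiased_pca_matrix)
                n = len(assigned)
                fractions = {
                    mid: 100.0 * float(np.sum(assigned == mid)) / n
                    for mid in model.metastate_ids
                }
                pop_model = MetastateModel(
                    labels=assigned,
                    populations={
                        mid: int(np.sum(assigned == mid)) for mid in model.metastate_ids
                    },
                    population_fractions=fractions,
                    descriptor_means=model.descriptor_means,
                    centroids=model.centroids,
                    seed=model.seed,
                )
            else:
                assigned = model.labels
                pop_model = model
            populations = population_report(pop_model)
            populations.to_csv(out / "populations.csv", index=False)
            if substates is not None:
                population_report(substates).to_csv(out / "subpopulations.csv", index=False)

        with _Stage("representatives"):
            source_model = substates if substates is not None else model
            means = dict(source_model.descriptor_means)
            # the equilibrium conformation: closest to the global unbiased means
            means["EQ"] = _global_means(dm_unbiased)
            reps = select_representatives(
                means,
                dm_unbiased,
                biased=dm_biased,
                distance_ceiling=config.representative_ceiling,
                distance_descriptor=config.distance_descriptor,
                threshold=config.esipt_threshold,
            )
            rep_table = representatives_table(reps)
            rep_table.to_csv(out / "representatives.csv", index=False)
            for rep in reps:
                source = unbiased if rep.from_reference else biased
                frame = source.frame(rep.frame_index)
                single = Ensemble(
                    atom_names=source.atom_names,
                    elements=source.elements,
                    residue_names=source.residue_names,
                    residue_indices=source.residue_indices,
                    coordinates=frame.coordinates[None, :, :],
                    provenance=f"representative {rep.metastate_id}",
                )
                write_ensemble(single, out / f"representative_{rep.metastate_id}.pdb")

        with _Stage("geometry_flags"):
            if config.distance_descriptor in dm_unbiased.descriptor_names:
                pop_matrix = dm_unbiased if config.population_source == "unbiased" else dm_biased
                distances = pop_matrix.column(config.distance_descriptor)
                capable_percent, capable_per_meta = esipt_capable_fraction(
                    distances, config.esipt_threshold, labels=assigned
                )
            else:
                capable_percent, capable_per_meta = float("nan"), {}

        hb = None
        with _Stage("hbond"):
            if config.preset is not None:
                donors, acceptors = template.hbond_selection()
                criterion = HBondCriterion(config.hbond_distance, config.hbond_angle)
                hb = occupancy(unbiased, donors, acceptors, criterion)
                hb.to_csv(out / "hbond_occupancy.csv", index=False)
            else:
                logger.info("hbond stage skipped: no donor/acceptor selection for file input")

        photo_df = None
        summary: dict = {
            "esipt_capable_percent": capable_percent,
            "esipt_capable_display": int(round(capable_percent))
            if np.isfinite(capable_percent)
            else None,
            "esipt_capable_per_metastate": capable_per_meta,
            "population_fractions": {
                m: float(f) for m, f in pop_model.population_fractions.items()
            },
            "representatives": {
                r.metastate_id: {
                    "frame": r.frame_index,
                    "d_N_HO": r.d_n_ho,
                    "esipt_geometry_ok": r.esipt_geometry_ok,
                }
                for r in reps
            },
        }
        if config.energy_table is not None:
            with _Stage("photophysics"):
                if config.energy_table == "builtin":
                    records = reference_energy_records()
                else:
                    records = read_energy_table(config.energy_table)
                photo = classify_table(records, threshold=config.esipt_threshold)
                photo_df = records_frame(photo)
                photo_df.to_csv(out / "photophysics.csv", index=False)
                assignment = _assignment_for_records(photo, reps, assigned)
                fractions = {
                    m: float(f) for m, f in pop_model.population_fractions.items()
                }
                try:
                    es = ensemble_summary(photo, fractions, assignment)
                    summary["photophysics"] = {
                        "esipt_capable_percent": es.esipt_capable_percent,
                        "esipt_capable_display": es.esipt_capable_display,
                        "capable_metastates": es.capable_metastates,
                        "n_esipt_capable_records": int(
                            sum(r.esipt_occurs for r in photo)
                        ),
                    }
                except ValidationError as exc:
                    logger.info("photophysics summary skipped: %s", exc)
        else:
            logger.info("photophysics stage skipped: no energy table configured")

        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=1, default=float))
        return PipelineResult(
            config=config,
            pca=pca,
            metastates=model,
            substates=substates,
            populations=populations,
            representatives=rep_table,
            capable_percent=capable_percent,
            capable_per_metastate=capable_per_meta,
            hbond_occupancy=hb,
            photophysics=photo_df,
            summary=summary,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def _assignment_for_records(photo, reps, assigned_labels) -> dict:
    """Map each photophysics record to a long-lived metastate.

    Sub-state ids like "2A" map to their parent "2"; the "EQ" record maps to
    the metastate of the EQ representative's frame (it is the equilibrium
    conformation, which lives in the dominant basin).
    """
    rep_ids = {r.metastate_id for r in reps}
    eq_rep = next((r for r in reps if r.metastate_id == "EQ"), None)
    assignment = {}
    for rec in photo:
        cid = rec.conformation_id
        if cid == "EQ" and eq_rep is not None:
            assignment[cid] = str(assigned_labels[eq_rep.frame_index])
        elif cid in rep_ids or cid[:-1].isdigit():
            assignment[cid] = cid.rstrip("AB") if cid[-1] in "AB" else cid
        else:
            assignment[cid] = cid
    return assignment
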