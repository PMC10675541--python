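"""End-to-end orchestration: partition -> align -> describe -> train -> evaluate.

Two built-in profiles:

* ``full`` — the production grid resolution (0.106 Å alignment spacing,
  0.212 Å descriptor spacing, 2000 rotamers). Intended for real datasets
  on serious hardware.
* ``desk`` — a scaled-down profile (0.4 Å / 0.8 Å, 128 rotamers) whose
  results are qualitatively, not quantitatively, comparable to ``full``;
  it exists so the whole pipeline runs on a laptop and in CI-sized tests.

Each stage writes its artifact into the working directory and is skipped
on re-runs when the artifact already exists, so a pipeline can be resumed
stage by stage. Stage numbers map to distinct CLI exit codes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemio
from .align import RotationSet, align_subset, hopf_rotations
from .chemio import Molecule, SubsetTable
from .descriptors import (
    DescriptorMatrix,
    descriptor_matrix,
    load_descriptors,
    pca_fit,
    pca_project,
    save_descriptors,
)
from .fields import GridSpec, PromoleculeBackend, build_common_box
from .qsarnet import ANNModel, train
from .validate import MetricsReport, evaluate

logger = logging.getLogger("espqsar")

__all__ = ["PipelineConfig", "PROFILES", "run_pipeline", "StageError"]

PROFILES = {
    "full": {"spacing_align": 0.106, "rotamers": 2000},
    "desk": {"spacing_align": 0.4, "rotamers": 128},
}


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` indexes partition=1 .. evaluate=6."""

    def __init__(self, stage: int, message: str):
        super().__init__(message)
        self.stage = stage


@dataclass
class PipelineConfig:
    workdir: str = "espqsar_run"
    structures: str | None = None
    activities: str | None = None
    profile: str = "desk"
    spacing_align: float | None = None   # Å; None -> profile default
    margin: float = 2.7
    rotamers: int | None = None          # None -> profile default
    width_scale: float = 0.5
    n_hidden: int = 35
    n_comp: int | None = None            # None -> training-set size
    tol: float = 1e-4
    max_iter: int = 50_000
    score_rms: float = 0.25   # target RMS of the largest PCA score column
    split_ratio: tuple[int, int] = (4, 1)
    seed: int = 0
    subsets: tuple[int, ...] | None = None  # None -> all seven

    def resolved(self) -> "PipelineConfig":
        prof = PROFILES[self.profile]
        cfg = dataclasses.replace(
            self,
            spacing_align=self.spacing_align or prof["spacing_align"],
            rotamers=self.rotamers or prof["rotamers"],
        )
        return cfg

    @property
    def spacing_desc(self) -> float:
        # descriptor grid is the alignment grid subsampled by stride 2
        return (self.spacing_align or PROFILES[self.profile]["spacing_align"]) * 2


def _log_params(cfg: PipelineConfig) -> None:
    logger.info("pipeline parameters: %s", json.dumps(dataclasses.asdict(cfg)))


def run_pipeline(
    config: PipelineConfig,
    molecules: list[Molecule] | None = None,
) -> list[MetricsReport]:
    """Run every stage for every requested subset and return the reports.

    ``molecules`` may be passed directly (already joined with activities);
    otherwise ``config.structures``/``config.activities`` are read.
    """
    cfg = config.resolved()
    work = Path(cfg.workdir)
    work.mkdir(parents=True, exist_ok=True)
    _log_params(cfg)

    # stage 1: load + partition + split
    try:
        if molecules is None:
            if not cfg.structures or not cfg.activities:
                raise FileNotFoundError(
                    "no molecules given and structures/activities paths unset"
                )
            molecules = chemio.read_dataset(cfg.structures, cfg.activities)
        subsets = chemio.partition_by_mw(molecules)
        subsets = [
            chemio.split_train_test(s, cfg.split_ratio, seed=cfg.seed + s.subset_index)
            for s in subsets
            if s.members
        ]
        chemio.subsets_to_frame(subsets).to_csv(work / "subsets.csv", index=False)
    except Exception as exc:
        raise StageError(1, f"partition stage failed: {exc}") from exc

    wanted = cfg.subsets or tuple(s.subset_index for s in subsets)
    by_id = {m.id: m for m in molecules}
    reports: list[MetricsReport] = []
    for subset in subsets:
        if subset.subset_index not in wanted:
            continue
        reports.append(_run_subset(cfg, work, subset, by_id))
    with open(work / "reports.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1)
    return reports


def _run_subset(cfg, work: Path, subset: SubsetTable, by_id) -> MetricsReport:
    k = subset.subset_index
    members = [by_id[mid] for mid in subset.members]
    backend = PromoleculeBackend(cfg.width_scale)
    template = chemio.select_template(subset, members)
    grid = build_common_box(members, cfg.spacing_align, cfg.margin)

    # stage 2: alignment (cached as XYZ of aligned coordinates)
    aligned_path = work / f"aligned_{k}.xyz"
    log_path = work / f"alignment_{k}.csv"
    try:
        if aligned_path.exists():
            aligned = chemio.read_xyz_charges(aligned_path)
            act = {m.id: m.pic50 for m in members}
            aligned = [
                Molecule(id=m.id, atoms=m.atoms, pic50=act.get(m.id))
                for m in aligned
            ]
            logger.info("subset %d: alignment cache hit", k)
        else:
            rotations = hopf_rotations(cfg.rotamers)
            results, aligned = align_subset(
                subset, members, grid, rotations, backend, template=template
            )
            pd.DataFrame(
                [
                    {
                        "target_id": r.target_id,
                        "rotamer_index": r.rotamer_index,
                        "tx": r.translation[0],
                        "ty": r.translation[1],
                        "tz": r.translation[2],
                        "score": r.score,
                    }
                    for r in results
                ]
            ).to_csv(log_path, index=False)
            chemio.write_xyz_charges(aligned, aligned_path)
            aligned = chemio.read_xyz_charges(aligned_path)  # canonical precision
            act = {m.id: m.pic50 for m in members}
            aligned = [
                Molecule(id=m.id, atoms=m.atoms, pic50=act.get(m.id))
                for m in aligned
            ]
    except Exception as exc:
        raise StageError(2, f"alignment stage failed on subset {k}: {exc}") from exc

    # stage 3: descriptors on the coarsened grid
    desc_path = work / f"descriptors_{k}.h5"
    try:
        if desc_path.exists():
            desc = load_descriptors(desc_path)
        else:
            desc = descriptor_matrix(aligned, grid.coarsen(2), backend)
            save_descriptors(desc, desc_path)
    except Exception as exc:
        raise StageError(3, f"descriptor stage failed on subset {k}: {exc}") from exc

    # stage 4: PCA on the training rows only
    train_ids = subset.train_ids()
    test_ids = subset.test_ids()
    try:
        n_comp = cfg.n_comp or len(train_ids)
        pca = pca_fit(desc.subset(train_ids), n_comp=n_comp)
        X_train = pca_project(pca, desc.subset(train_ids).rows)
        X_test = pca_project(pca, desc.subset(test_ids).rows)
    except Exception as exc:
        raise StageError(4, f"PCA stage failed on subset {k}: {exc}") from exc

    # stage 5: network training. A single global scale brings the largest
    # PCA score column to RMS ``score_rms`` (default 0.25): one scale
    # preserves the variance ordering of the components, and the small
    # magnitude starts the sigmoids in their linear range, so gradient
    # descent builds the fit from high-variance components before it can
    # chase low-variance noise directions. The scale is folded back into
    # the input weights, so the saved model consumes raw PCA scores.
    act = {m.id: m.pic50 for m in aligned}
    y_train = np.array([act[i] for i in train_ids], dtype=float)
    try:
        top_rms = float(np.sqrt(np.mean(X_train**2, axis=0)).max())
        scale = top_rms / cfg.score_rms if top_rms > 1e-12 else 1.0
        model, record = train(
            X_train / scale,
            y_train,
            n_hidden=cfg.n_hidden,
            seed=cfg.seed + 100 + k,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            adaptive_lr=True,
            record_history=False,
        )
        model = ANNModel(
            w_in=model.w_in / scale,
            w_out=model.w_out,
            act_min=model.act_min,
            act_max=model.act_max,
            seed=model.seed,
            final_F=model.final_F,
            iterations=model.iterations,
        )
        from .qsarnet import save_model

        save_model(model, work / f"model_{k}.h5")
        logger.info(
            "subset %d: trained %d iters, F=%.3g (%s)",
            k, record.F_history.size and model.iterations, model.final_F,
            record.stop_reason,
        )
    except Exception as exc:
        raise StageError(5, f"training stage failed on subset {k}: {exc}") from exc

    # stage 6: evaluation on the denormalized pIC50 scale
    try:
        desc_index = {m: i for i, m in enumerate(desc.molecule_ids)}
        train_triples = [
            (i, desc.rows[desc_index[i]], act[i]) for i in train_ids
        ]
        test_triples = [(i, desc.rows[desc_index[i]], act[i]) for i in test_ids]
        report = evaluate(model, pca, train_triples, test_triples, subset_index=k)
        report.residuals.to_csv(work / f"residuals_{k}.csv", index=False)
    except Exception as exc:
        raise StageError(6, f"evaluation stage failed on subset {k}: {exc}") from exc
    return report
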