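"""Fold-space exploration and the end-to-end modelling pipeline.

The confidence-ranked contact list is cut into 40 nested subsets (the top
x·L contacts for x = 0.1, 0.2, ..., 4.0); 20 models are folded against
each subset and the 5 lowest contact-energy models per subset are pooled
(200 models by default).  Selection (satisfaction filter to 50, TM-score
clustering to 5 medoids) then produces the final ranked predictions.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from contactfold.io_formats import (
    Contact,
    Model,
    SecondaryStructure,
    SequenceRecord,
    read_fasta,
    read_rr,
    read_ss,
    write_pdb,
)
from contactfold.folding import FoldConfig, fold, stage2_refine, total_energy
from contactfold.restraints import build_contact_restraints, build_ss_restraints
from contactfold.selection import (
    ClusterResult,
    ScoredModel,
    cluster_models,
    filter_pool,
    satisfaction_score,
    select_top5,
)

logger = logging.getLogger(__name__)

DEFAULT_X_GRID = tuple(round(0.1 * k, 1) for k in range(1, 41))


@dataclass(frozen=True)
class ContactSubset:
    """The top round(x·L) contacts of the confidence-ranked list."""

    x: float
    contacts: tuple[Contact, ...]

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class CandidatePool:
    """All models kept across subsets, with per-model provenance."""

    models: list[ScoredModel]

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class PipelineConfig:
    """Exploration settings wrapping the per-fold configuration.

    Model k of subset s is folded with seed = seed + 1000·s + k, so the
    whole pool is reproducible from one integer.
    """

    fold: FoldConfig = field(default_factory=FoldConfig)
    x_grid: tuple[float, ...] = DEFAULT_X_GRID
    models_per_subset: int = 20
    keep_per_subset: int = 5
    keep_pool: int = 50
    n_clusters: int = 5
    seed: int = 0


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def make_subsets(
    contacts: list[Contact], L: int, x_grid: tuple[float, ...] = DEFAULT_X_GRID
) -> list[ContactSubset]:
    """Nested top-xL subsets of a confidence-sorted contact list.

    Subset size is round-half-up of x·L (never below 1), capped at the
    number of available contacts.
    """
    if not contacts:
        raise ValueError("empty contact list")
    subsets = []
    for x in x_grid:
        size = min(max(1, _round_half_up(x * L)), len(contacts))
        subsets.append(ContactSubset(x=x, contacts=tuple(contacts[:size])))
    return subsets


def generate_candidates(
    sequence: SequenceRecord,
    ss: SecondaryStructure,
    contacts: list[Contact],
    config: PipelineConfig,
) -> CandidatePool:
    """Fold `models_per_subset` models per contact subset and keep the
    `keep_per_subset` lowest contact-energy models of each.

    Contact energy is evaluated against the subset's own restraints; ties
    break by seed index.  With defaults the pool holds 40 × 5 = 200
    models.
    """
    L = len(sequence)
    subsets = make_subsets(contacts, L, config.x_grid)
    ss_restraints = build_ss_restraints(ss)
    pool: list[ScoredModel] = []
    order = 0
    for s_idx, subset in enumerate(subsets):
        if len(subset) == 0:
            logger.warning("subset x=%.1f is empty; skipped", subset.x)
            continue
        contact_restraints = build_contact_restraints(list(subset.contacts), sequence)
        restraints = ss_restraints + contact_restraints
        scored: list[tuple[float, int, Model]] = []
        for k in range(config.models_per_subset):
            cfg = replace(config.fold, seed=config.seed + 1000 * s_idx + k)
            model = fold(L, restraints, cfg, sequence=sequence,
                         label=f"x{subset.x:.1f}_s{k}")
            if cfg.stage2_enabled:
                _, model = stage2_refine(model, restraints, ss, cfg)
            e_contact = total_energy(model, contact_restraints, cfg).e_contact
            scored.append((e_contact, k, model))
        scored.sort(key=lambda t: (t[0], t[1]))
        for e_contact, k, model in scored[: config.keep_per_subset]:
            pool.append(
                ScoredModel(model=model, e_contact=e_contact,
                            subset_x=subset.x, seed=k, order=order)
            )
            order += 1
        logger.info("subset x=%.1f (%d contacts): kept %d of %d models",
                    subset.x, len(subset), min(config.keep_per_subset, len(scored)),
                    len(scored))
    return CandidatePool(models=pool)


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage (read/explore/select/write)."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"[{name}] {exc}") from exc


@dataclass
class PipelineResult:
    top5: list[ScoredModel]
    pool: CandidatePool
    retained: list[ScoredModel]
    clusters: ClusterResult
    report_path: Path | None = None
    model_paths: list[Path] = field(default_factory=list)


def run_pipeline(
    fasta: str | Path,
    rr: str | Path,
    ss: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Read inputs, explore fold space, select and write the top 5 models.

    Writes model1.pdb ... model5.pdb plus report.tsv (one row per pool
    model: subset factor, seed, contact energy, satisfaction, cluster id,
    final rank).  Deterministic for a fixed config seed.
    """
    config = config or PipelineConfig()
    with _stage("read"):
        logger.info("[read] loading inputs")
        sequence = read_fasta(fasta)
        L = len(sequence)
        contacts = read_rr(rr, L)
        ss_states = read_ss(ss, L)
        logger.info("[read] L=%d, %d contacts", L, len(contacts))

    with _stage("explore"):
        logger.info("[explore] generating candidate pool")
        pool = generate_candidates(sequence, ss_states, contacts, config)
        logger.info("[explore] pool of %d models", len(pool))

    with _stage("select"):
        logger.info("[select] satisfaction filter to %d", config.keep_pool)
        retained = filter_pool(pool, contacts, L, keep=config.keep_pool)
        logger.info("[select] clustering into %d clusters", config.n_clusters)
        clusters = cluster_models(retained, k=config.n_clusters)
        top5 = select_top5(clusters, contacts, L)

    report_path = None
    model_paths: list[Path] = []
    if outdir is not None:
        with _stage("write"):
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            for rank, sm in enumerate(top5, start=1):
                p = out / f"model{rank}.pdb"
                write_pdb(sm.model, p)
                model_paths.append(p)
            report_path = out / "report.tsv"
            _write_report(report_path, pool, retained, clusters, top5)
    return PipelineResult(top5=top5, pool=pool, retained=retained,
                          clusters=clusters, report_path=report_path,
                          model_paths=model_paths)


def _write_report(path, pool, retained, clusters, top5) -> None:
    cluster_of = {id(sm): int(clusters.assignments[idx])
                  for idx, sm in enumerate(clusters.models)}
    rank_of = {id(sm): rank for rank, sm in enumerate(top5, start=1)}
    with open(path, "w") as fh:
        fh.write("model\tsubset_x\tseed\te_contact\tsatisfaction\tcluster\trank\n")
        for sm in pool.models:
            cl = cluster_of.get(id(sm), "-")
            rk = rank_of.get(id(sm), "-")
            sat = "" if sm.satisfaction is None else f"{sm.satisfaction:.4f}"
            fh.write(
                f"{sm.model.label}\t{sm.subset_x:.1f}\t{sm.seed}\t"
                f"{sm.e_contact:.6f}\t{sat}\t{cl}\t{rk}\n"
            )
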