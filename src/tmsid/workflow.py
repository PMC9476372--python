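"""End-to-end orchestration: curate -> kernels/fingerprints -> train ->
identify -> evaluate.

The pipeline consumes either an in-memory :class:`SyntheticBundle` or a
bundle directory (training.msp / test.msp / structures.tsv /
candidates.tsv / truth.json as written by
:func:`tmsid.synthetic_data.write_bundle`). Every random choice derives
from the run config's master seed, so a rerun with the same config is
bit-identical (hash-checked in tests).
"""

from __future__ import annotations

import json
import hashlib
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .curation import CompoundRecord, CurationReport, run_curation
from .evaluation import EvaluationSummary, summarize, summary_table
from .fingerprints import (ColumnMask, apply_mask, build_mask,
                           compute_fingerprint)
from .iokr import (DEFAULT_LAMBDA_GRID, IOKR, Candidate, CandidateSet,
                   IOKRResults, RankingResult)
from .kernels import KernelProcessor, PPKParams
from .spectra_io import Spectrum, read_msp
from .synthetic_data import (GeneratorConfig, SyntheticBundle, TestQuery,
                             make_benchmark)

__all__ = [
    "RunConfig",
    "TrainedPipeline",
    "run_train",
    "run_identify",
    "run_evaluate",
    "load_bundle",
]

log = logging.getLogger("tmsid.workflow")


@dataclass
class RunConfig:
    """Declarative run configuration; CLI flags map 1:1 onto fields."""

    synthetic: GeneratorConfig | None = None
    bundle_dir: str | None = None
    ppk: PPKParams = field(default_factory=PPKParams)
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    folds: int = 5
    ks: tuple = (1, 10, 20)
    normalized_scores: bool = False
    mass_mode: str = ">"
    strict_markers: bool = False
    out_dir: str | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_grid:
            raise ValueError("lambda grid must be non-empty")

    def echo(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class TrainedPipeline:
    """Everything the identification step needs, with provenance."""

    curation_report: CurationReport
    mask: ColumnMask
    processor: KernelProcessor
    results: IOKRResults
    train_labels: list[str]
    report: dict

    def model_hash(self) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.results.model.K_train.values).tobytes())
        h.update(np.ascontiguousarray(self.results.model.Y).tobytes())
        h.update(f"{self.results.lambda_:.12g}".encode())
        h.update(self.mask.mask_id.encode())
        return h.hexdigest()


def _resolve_bundle(cfg: RunConfig, bundle: SyntheticBundle | None) -> SyntheticBundle:
    if bundle is not None:
        return bundle
    if cfg.bundle_dir is not None:
        return load_bundle(cfg.bundle_dir)
    if cfg.synthetic is not None:
        return make_benchmark(cfg.synthetic)
    raise ValueError("no data source: provide a bundle, bundle_dir or synthetic config")


def run_train(cfg: RunConfig, bundle: SyntheticBundle | None = None) -> TrainedPipeline:
    """Curate the training library, build mask and kernels, select the
    regularization by internal CV, and fit the IOKR model."""
    bundle = _resolve_bundle(cfg, bundle)
    report: dict = {"seed": cfg.master_seed}

    cur = run_curation(bundle.train_records, mass_mode=cfg.mass_mode,
                       strict_markers=cfg.strict_markers)
    report["curation"] = {"n_input": cur.n_input, "n_output": cur.n_output,
                          "per_step_removed": cur.per_step_removed}
    if not cur.curated:
        raise ValueError("curation removed every training record")
    log.info("curation: %d -> %d records", cur.n_input, cur.n_output)

    fps = [compute_fingerprint(r.structure) for r in cur.curated]
    mask = build_mask(fps)
    Y = np.stack([apply_mask(fp, mask).bits for fp in fps]).astype(float)
    report["fingerprints"] = {
        "n_total_bits": fps[0].bits.size, "n_retained": mask.n_retained,
        "mask_id": mask.mask_id,
    }

    labels = [r.record_id for r in cur.curated]
    proc = KernelProcessor(cfg.ppk).fit([r.spectrum for r in cur.curated],
                                        labels=labels)
    model = IOKR(proc.K_train_, Y, mask_id=mask.mask_id)
    results = model.fit(lambda_grid=cfg.lambda_grid, folds=cfg.folds,
                        seed=cfg.master_seed)
    report["model"] = {"lambda": results.lambda_, "n_train": model.n_train,
                       "p_out": model.p_out,
                       "kernel": asdict(cfg.ppk)}
    pipe = TrainedPipeline(cur, mask, proc, results, labels, report)
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        with open(os.path.join(cfg.out_dir, "train_report.json"), "w") as fh:
            json.dump({**report, "config": _jsonable(cfg.echo()),
                       "model_hash": pipe.model_hash()}, fh, indent=1)
    return pipe


def _masked_candidates(cs: CandidateSet, mask: ColumnMask) -> CandidateSet:
    cands = [
        Candidate(c.identifier, c.structure,
                  apply_mask(compute_fingerprint(c.structure), mask))
        for c in cs.candidates
    ]
    return CandidateSet(cs.query_id, cands, cs.contains_true, cs.true_id)


def run_identify(
    cfg: RunConfig,
    pipeline: TrainedPipeline,
    bundle: SyntheticBundle | None = None,
) -> tuple[list[RankingResult], pd.DataFrame]:
    """Score and rank every test query's candidate set.

    Returns the per-query ranking results and a long-format table with one
    row per (query, candidate); queries with empty candidate sets yield an
    error row and the run continues.
    """
    bundle = _resolve_bundle(cfg, bundle)
    results: list[RankingResult] = []
    rows = []
    for q in bundle.test_queries:
        qid = q.record.record_id
        cs = bundle.candidate_sets.get(qid)
        if cs is None or not cs.candidates:
            rows.append({"query_id": qid, "candidate_id": None, "rank": None,
                         "score": None, "error": "empty candidate set"})
            continue
        k_row = pipeline.processor.transform([q.query_spectrum], labels=[qid])
        ranking = pipeline.results.rank_query(
            k_row.values[0], _masked_candidates(cs, pipeline.mask),
            normalized=cfg.normalized_scores)
        results.append(ranking)
        for rank, (cand_id, score) in enumerate(ranking.ranking, start=1):
            rows.append({
                "query_id": qid, "candidate_id": cand_id, "rank": rank,
                "score": score,
                "is_true": int(cs.contains_true and cand_id == cs.true_id),
                "error": "",
            })
    table = pd.DataFrame(rows)
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        table.to_csv(os.path.join(cfg.out_dir, "ranks.tsv"), sep="\t", index=False)
    return results, table


def run_evaluate(
    cfg: RunConfig,
    results: list[RankingResult],
    groups: dict[str, dict[str, str]] | None = None,
) -> dict[str, list[EvaluationSummary]]:
    """Summaries per grouping (e.g. in-training flag, structural class,
    spectral cluster) plus the merged table; written as TSV + JSON when an
    output directory is configured."""
    out = {"merged": summarize(results, None, ks=cfg.ks)}
    if groups:
        for name, mapping in groups.items():
            out[name] = summarize(results, mapping, ks=cfg.ks)
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        payload = {}
        for name, summaries in out.items():
            df = summary_table(summaries)
            df.to_csv(os.path.join(cfg.out_dir, f"summary_{name}.tsv"),
                      sep="\t", index=False)
            payload[name] = df.to_dict(orient="records")
        with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
            json.dump(payload, fh, indent=1)
    return out


def groups_from_bundle(bundle: SyntheticBundle) -> dict[str, dict[str, str]]:
    """Grouping maps (in-training flag, structural class, designed
    cluster) keyed by query id, as used in grouped evaluation tables."""
    in_train, klass, cluster = {}, {}, {}
    for row in bundle.truth["queries"]:
        qid = row["query_id"]
        in_train[qid] = "Yes" if row["in_training"] else "No"
        klass[qid] = row["class_label"]
        cluster[qid] = row["cluster_label"]
    return {"in_training": in_train, "class": klass, "cluster": cluster}


# ---------------------------------------------------------------------------
# bundle (de)serialization
# ---------------------------------------------------------------------------

def load_bundle(directory) -> SyntheticBundle:
    """Reconstruct a bundle from a directory written by ``write_bundle``."""
    struct_path = os.path.join(directory, "structures.tsv")
    if not os.path.exists(struct_path):
        raise FileNotFoundError(f"structures file not found: {struct_path}")
    structures = pd.read_csv(struct_path, sep="\t", dtype=str)
    rec_by_id: dict[str, CompoundRecord] = {}
    for _, r in structures.iterrows():
        rec_by_id[r["record_id"]] = CompoundRecord(
            record_id=r["record_id"], structure=r["smiles"],
            inchikey=r["inchikey"], formula=r["formula"],
            mw=float(r["mw"]), n_tms=int(r["n_tms"]),
            class_label=r.get("class_label"))

    for s in read_msp(os.path.join(directory, "training.msp")):
        rid = s.library_id or s.name
        if rid in rec_by_id:
            rec_by_id[rid].spectrum = s

    with open(os.path.join(directory, "truth.json")) as fh:
        truth = json.load(fh)
    cfg = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in truth["config"].items()})

    reps: dict[str, list[Spectrum]] = {}
    for s in read_msp(os.path.join(directory, "test.msp")):
        qid = s.name.rsplit("_rep", 1)[0]
        reps.setdefault(qid, []).append(s)

    cands = pd.read_csv(os.path.join(directory, "candidates.tsv"), sep="\t", dtype=str)
    cand_sets: dict[str, CandidateSet] = {}
    for qid, grp in cands.groupby("query_id", sort=False):
        members = [Candidate(r["candidate_id"], r["smiles"],
                             compute_fingerprint(r["smiles"]))
                   for _, r in grp.iterrows()]
        true_rows = grp[grp["is_true"] == "1"]
        contains = not true_rows.empty
        cand_sets[qid] = CandidateSet(
            qid, members, contains,
            true_rows.iloc[0]["candidate_id"] if contains else None)

    train_records = [rec_by_id[rid] for rid in rec_by_id
                     if rec_by_id[rid].spectrum is not None]
    queries = []
    for row in truth["queries"]:
        qid = row["query_id"]
        queries.append(TestQuery(rec_by_id[qid], reps[qid], row["in_training"]))
    return SyntheticBundle(cfg, train_records, queries, cand_sets, truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
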