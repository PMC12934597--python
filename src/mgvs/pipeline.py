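"""End-to-end model-guided virtual screening (MGVS) orchestration.

The pipeline turns a set of generated (possibly hard-to-synthesize)
molecules into purchasable analogs: filter the generated set, dock and
rank it, take the best compounds as queries, search a library for
topological analogs by graph edit distance, dock the analogs, and
evaluate how well the analogs preserve the queries' scores and binding
interactions.

Every stage is deterministic for a fixed configuration: conformer
embedding is seeded, the mock engine is hash-keyed, ranking ties are
broken by compound id, and artifacts are written with fixed float
formatting and sorted JSON keys, so two runs with the same inputs are
byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .chemio import MoleculeRecord, ReceptorStructure
from .dockadapt import (
    ConformerError,
    DockingEngine,
    DockingResult,
    best_result,
    cluster_conformers,
    delta_vina,
    generate_conformers,
    relax,
    score_pose,
    write_poses_sdf,
)
from .filters import FilterConfig, apply_filter_stack, write_filter_report
from .gedsearch import SearchHit, build_index, query_index
from .plinter import (
    InteractionCutoffs,
    detect_interactions,
    match_interactions,
    shared_interaction_stats,
    write_interactions_tsv,
)

__all__ = [
    "MGVSConfig",
    "RunResult",
    "dock_molecules",
    "select_queries",
    "rank_hits",
    "run_mgvs",
    "welch_t",
    "spearman",
    "baseline_compare",
    "pool_size_curve",
    "distance_score_correlation",
]


@dataclass
class MGVSConfig:
    """Tunable parameters of a screening run.

    Defaults are production-scale; tests and fixtures override the size
    parameters downward.  ``ranking`` selects the query-ranking metric:
    ``vina_eff`` (score per heavy atom, the default) or raw ``vina``.
    """

    n_generate: int = 1000
    top_queries: int = 10
    max_ged: int = 12
    max_raw_hits: int = 1000
    top_hits_per_query: int = 100
    n_conformers: int = 5
    rmsd_cutoff: float = 1.0
    ranking: str = "vina_eff"
    seed: int = 0
    match_level: str = "residue"
    match_scope: str = "all"
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    cutoffs: InteractionCutoffs = field(default_factory=InteractionCutoffs)

    def __post_init__(self):
        if self.ranking not in ("vina_eff", "vina"):
            raise ValueError(f"unknown ranking metric {self.ranking!r}")
        for name in ("top_queries", "max_ged", "max_raw_hits", "top_hits_per_query", "n_conformers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "MGVSConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "filters" in kwargs:
            kwargs["filter_config"] = FilterConfig(**kwargs.pop("filters"))
        if "cutoffs" in kwargs:
            kwargs["cutoffs"] = InteractionCutoffs(**kwargs.pop("cutoffs"))
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class RunResult:
    """Everything a screening run produced, in memory."""

    queries: list[MoleculeRecord]
    query_results: dict[str, DockingResult]
    hits_by_query: dict[str, list[SearchHit]]
    hit_results: dict[str, DockingResult]
    best_analog: dict[str, tuple[str, float]]  # query id -> (hit id, delta vina)
    evaluation: dict
    filter_reports: list
    interactions: dict[str, list] = field(default_factory=dict)  # pose id -> [Interaction]


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def dock_molecules(
    records: list[MoleculeRecord],
    receptor: ReceptorStructure,
    engine: DockingEngine,
    config: MGVSConfig,
) -> dict[str, DockingResult]:
    """Embed, cluster, relax and dock each molecule; keep the best-scored
    pose per molecule.  Molecules that fail 3D embedding are skipped
    with a warning rather than aborting the run."""
    out: dict[str, DockingResult] = {}
    for rec in records:
        try:
            cs = generate_conformers(rec, n=config.n_conformers, seed=config.seed)
        except ConformerError as exc:
            warnings.warn(str(exc))
            continue
        cs = cluster_conformers(cs, rmsd_cutoff=config.rmsd_cutoff)
        cs = relax(cs)
        out[rec.id] = best_result(score_pose(cs, receptor, engine))
    return out


def _rank_key(config: MGVSConfig):
    if config.ranking == "vina_eff":
        return lambda item: (item[1].vina_eff, item[1].vina, item[0])
    return lambda item: (item[1].vina, item[1].vina_eff, item[0])


def select_queries(
    records: list[MoleculeRecord],
    results: dict[str, DockingResult],
    config: MGVSConfig,
) -> tuple[list[MoleculeRecord], list]:
    """Filter the generated set, then take the ``top_queries`` best
    survivors by the ranking metric (ascending; more negative = better),
    ties broken by the secondary metric and then compound id."""
    survivors, reports = apply_filter_stack(records, config.filter_config)
    scored = [(rec.id, results[rec.id]) for rec in survivors if rec.id in results]
    scored.sort(key=_rank_key(config))
    chosen_ids = [mol_id for mol_id, _ in scored[: config.top_queries]]
    by_id = {rec.id: rec for rec in records}
    return [by_id[i] for i in chosen_ids], reports


def rank_hits(hits: list[SearchHit], top_n: int) -> list[SearchHit]:
    """Order analogs by (GED, Daylight-like distance, id) and keep the
    best ``top_n``."""
    return sorted(hits, key=SearchHit.sort_key)[:top_n]


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t, two-sided p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t requires at least two observations per group")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation; (NaN, NaN) with a warning when either
    input is constant (correlation undefined)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("spearman requires two equal-length samples of size >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input to spearman: correlation undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def baseline_compare(
    hit_results: list[DockingResult],
    library_results: list[DockingResult],
    n_repeats: int = 20,
    top_k: int = 10,
    seed: int = 0,
) -> dict:
    """Compare search-selected compounds against random library picks.

    For each repeat a random subset of the library of the same size as
    the hit set is drawn and the median of its ``top_k`` best ligand
    efficiencies recorded; the observed hit-set statistic is compared
    against that baseline distribution, plus a Welch t-test on the full
    ligand-efficiency vectors (hits vs library).
    """
    if not hit_results or not library_results:
        raise ValueError("baseline_compare requires non-empty result sets")
    rng = np.random.default_rng(seed)

    def stat(results: list[DockingResult]) -> float:
        effs = sorted(r.vina_eff for r in results)
        return float(np.median(effs[: min(top_k, len(effs))]))

    observed = stat(hit_results)
    k = min(len(hit_results), len(library_results))
    baseline = [
        stat([library_results[i] for i in rng.choice(len(library_results), size=k, replace=False)])
        for _ in range(n_repeats)
    ]
    t, p = welch_t(
        [r.vina_eff for r in hit_results], [r.vina_eff for r in library_results]
    )
    return {
        "observed_median_topk_eff": observed,
        "baseline_mean": float(np.mean(baseline)),
        "baseline_sd": float(np.std(baseline, ddof=1)) if n_repeats > 1 else 0.0,
        "n_repeats": n_repeats,
        "top_k": top_k,
        "welch_t": t,
        "welch_p": p,
    }


def pool_size_curve(per_query_deltas: list[list[float]], sizes: list[int] | None = None) -> list[dict]:
    """Best (minimum) ΔVina achievable within the top-k analog pool, as
    a function of pool size k, averaged over queries with a normal 95%
    confidence interval (mean ± 1.96 SE).

    Each inner list must be in analog rank order.  The per-query best
    is a running minimum, so the mean curve is non-increasing in k by
    construction.
    """
    pools = [d for d in per_query_deltas if d]
    if not pools:
        raise ValueError("pool_size_curve requires at least one non-empty ranked list")
    max_k = max(len(d) for d in pools)
    sizes = sizes or list(range(1, max_k + 1))
    curve = []
    for k in sizes:
        if k < 1:
            raise ValueError("pool sizes must be >= 1")
        best = np.array([min(d[: min(k, len(d))]) for d in pools])
        mean = float(best.mean())
        se = float(best.std(ddof=1) / np.sqrt(len(best))) if len(best) > 1 else 0.0
        curve.append(
            {
                "pool_size": int(k),
                "mean_best_delta": mean,
                "ci_low": mean - 1.96 * se,
                "ci_high": mean + 1.96 * se,
                "n_queries": len(best),
            }
        )
    return curve


def distance_score_correlation(pairs: list[tuple[float, float]]) -> dict:
    """Spearman correlation between a query-hit distance (GED or
    fingerprint) and ΔVina over all (query, hit) pairs."""
    if len(pairs) < 2:
        raise ValueError("need at least two (distance, delta) pairs")
    d = [x for x, _ in pairs]
    dv = [y for _, y in pairs]
    rho, p = spearman(d, dv)
    return {"rho": rho, "p": p, "n": len(pairs)}


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------


def _canon(obj):
    """Canonicalize for byte-stable JSON: round floats, map non-finite
    values to None, recurse into containers."""
    if isinstance(obj, dict):
        return {str(k): _canon(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canon(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(obj: dict, path) -> None:
    text = json.dumps(_canon(obj), sort_keys=True, indent=2) + "\n"
    Path(path).write_text(text)


def run_mgvs(
    generated: list[MoleculeRecord],
    library: list[MoleculeRecord],
    receptor: ReceptorStructure,
    engine: DockingEngine,
    config: MGVSConfig | None = None,
    out_dir=None,
) -> RunResult:
    """Execute the full screen and (optionally) write its artifacts.

    Stages: filter the generated set; dock survivors and take the
    ``top_queries`` best by the ranking metric; search the library for
    analogs of each query by anonymous-graph GED; dock the analogs;
    evaluate score retention (ΔVina, baseline comparison, pool-size
    curve, distance-score correlations) and binding-interaction
    retention (shared-interaction statistics).

    Artifacts under ``out_dir``: queries.tsv, hits.tsv, scores.tsv,
    filters.tsv, interactions.tsv, eval.json, poses.sdf.
    """
    config = config or MGVSConfig()
    generated = generated[: config.n_generate]

    gen_results = dock_molecules(generated, receptor, engine, config)
    queries, reports = select_queries(generated, gen_results, config)
    if not queries:
        raise ValueError("no generated molecules survived filtering and docking")

    index = build_index(library)
    hits_by_query: dict[str, list[SearchHit]] = {}
    for q in queries:
        raw = query_index(index, q, max_ged=config.max_ged, max_hits=config.max_raw_hits)
        hits_by_query[q.id] = rank_hits(raw, config.top_hits_per_query)

    unique_hit_ids = sorted({h.hit_id for hits in hits_by_query.values() for h in hits})
    hit_records = [index.molecules[i] for i in unique_hit_ids]
    hit_results = dock_molecules(hit_records, receptor, engine, config)

    # score retention
    best_analog: dict[str, tuple[str, float]] = {}
    per_query_deltas: list[list[float]] = []
    ged_delta_pairs: list[tuple[float, float]] = []
    fp_delta_pairs: list[tuple[float, float]] = []
    for q in queries:
        q_vina = gen_results[q.id].vina
        deltas = []
        for h in hits_by_query[q.id]:
            if h.hit_id not in hit_results:
                continue
            dv = delta_vina(hit_results[h.hit_id].vina, q_vina)
            deltas.append(dv)
            ged_delta_pairs.append((float(h.ged), dv))
            fp_delta_pairs.append((h.daylight_dist, dv))
        if deltas:
            ranked_hits = [h for h in hits_by_query[q.id] if h.hit_id in hit_results]
            best_i = int(np.argmin(deltas))
            best_analog[q.id] = (ranked_hits[best_i].hit_id, deltas[best_i])
            per_query_deltas.append(deltas)

    evaluation: dict = {
        "n_generated": len(generated),
        "n_filter_survivors": sum(1 for r in reports if r.passed),
        "n_queries": len(queries),
        "n_unique_hits": len(unique_hit_ids),
        "n_hits_docked": len(hit_results),
        "best_delta_vina": {q: {"hit": h, "delta": d} for q, (h, d) in best_analog.items()},
    }
    if per_query_deltas:
        all_deltas = [d for ds in per_query_deltas for d in ds]
        evaluation["delta_vina"] = {
            "mean": float(np.mean(all_deltas)),
            "median": float(np.median(all_deltas)),
            "best": float(np.min(all_deltas)),
            "n": len(all_deltas),
        }
        evaluation["pool_size_curve"] = pool_size_curve(per_query_deltas)
        if len(ged_delta_pairs) >= 2:
            evaluation["correlation"] = {
                "ged_vs_delta": distance_score_correlation(ged_delta_pairs),
                "daylight_vs_delta": distance_score_correlation(fp_delta_pairs),
            }
    if hit_results and len(gen_results) >= 2 and len(hit_results) >= 2:
        evaluation["baseline"] = baseline_compare(
            list(hit_results.values()),
            list(gen_results.values()),
            seed=config.seed,
        )

    # interaction retention
    pose_ints: dict[str, list] = {}
    entries = []
    for q in queries:
        q_ints = detect_interactions(gen_results[q.id], receptor, config.cutoffs)
        pose_ints[q.id] = q_ints
        summaries = []
        for h in hits_by_query[q.id]:
            if h.hit_id not in hit_results:
                continue
            if h.hit_id not in pose_ints:
                pose_ints[h.hit_id] = detect_interactions(
                    hit_results[h.hit_id], receptor, config.cutoffs
                )
            summaries.append(
                match_interactions(
                    q_ints, pose_ints[h.hit_id],
                    level=config.match_level, scope=config.match_scope,
                )
            )
        if q_ints and summaries:
            entries.append((q.id, summaries))
    if entries:
        evaluation["shared_interactions"] = shared_interaction_stats(entries)

    result = RunResult(
        queries=queries,
        query_results={q.id: gen_results[q.id] for q in queries},
        hits_by_query=hits_by_query,
        hit_results=hit_results,
        best_analog=best_analog,
        evaluation=evaluation,
        filter_reports=reports,
        interactions=pose_ints,
    )
    if out_dir is not None:
        _write_artifacts(result, index, out_dir)
    return result


def _write_artifacts(result: RunResult, index, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    q_lines = ["id\tsmiles\tvina\tvina_eff\trank"]
    for rank, q in enumerate(result.queries, start=1):
        r = result.query_results[q.id]
        q_lines.append(f"{q.id}\t{q.smiles}\t{r.vina:.4f}\t{r.vina_eff:.6f}\t{rank}")
    (out / "queries.tsv").write_text("\n".join(q_lines) + "\n")

    h_lines = ["query_id\thit_id\tsmiles\tged\tdaylight_dist\tecfp4_dist\tvina\tdelta_vina\trank"]
    for q in result.queries:
        q_vina = result.query_results[q.id].vina
        for rank, h in enumerate(result.hits_by_query[q.id], start=1):
            smiles = index.molecules[h.hit_id].smiles
            if h.hit_id in result.hit_results:
                vina = result.hit_results[h.hit_id].vina
                vina_s = f"{vina:.4f}"
                delta_s = f"{vina - q_vina:.4f}"
            else:
                vina_s = delta_s = ""
            h_lines.append(
                f"{q.id}\t{h.hit_id}\t{smiles}\t{h.ged}\t{h.daylight_dist:.6f}"
                f"\t{h.ecfp4_dist:.6f}\t{vina_s}\t{delta_s}\t{rank}"
            )
    (out / "hits.tsv").write_text("\n".join(h_lines) + "\n")

    s_lines = ["mol_id\trole\tvina\theavy_atoms\tvina_eff"]
    for mol_id, r in sorted(result.query_results.items()):
        s_lines.append(f"{mol_id}\tquery\t{r.vina:.4f}\t{r.heavy_atoms}\t{r.vina_eff:.6f}")
    for mol_id, r in sorted(result.hit_results.items()):
        s_lines.append(f"{mol_id}\thit\t{r.vina:.4f}\t{r.heavy_atoms}\t{r.vina_eff:.6f}")
    (out / "scores.tsv").write_text("\n".join(s_lines) + "\n")

    write_filter_report(result.filter_reports, out / "filters.tsv")
    write_json(result.evaluation, out / "eval.json")

    poses = [result.query_results[q.id] for q in result.queries]
    poses += [result.hit_results[i] for i in sorted(result.hit_results)]
    write_poses_sdf(poses, out / "poses.sdf")

    if result.interactions:
        ordered = {q.id: result.interactions[q.id] for q in result.queries if q.id in result.interactions}
        for pose_id in sorted(result.interactions):
            ordered.setdefault(pose_id, result.interactions[pose_id])
        write_interactions_tsv(ordered, out / "interactions.tsv")
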