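"""Assembly and validation of the dashboard JSON bundle.

The bundle is the complete, self-contained data contract between the
analysis pipeline and an interactive network dashboard: node records with
2-D embedding coordinates and per-contrast statistics mapped linearly to
pixel node sizes; directed top-K nearest-neighbour edge lists with discrete
similarity bins; cluster membership with medoids and Silhouette
contributions; and a cluster x contrast p-value heatmap.  Every id
referenced anywhere in the bundle resolves within it, and a shipped JSON
schema plus consistency rules (Bonferroni monotonicity, size bounds,
partition structure) are enforced by :func:`validate_bundle`.

Top-K edges are recorded per source node regardless of absolute similarity
(threshold independence); the symmetric union, if wanted, is the renderer's
job.  Numbers are serialised at 6 significant digits and key order is
deterministic, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

import numpy as np

from .clustering import ClusterSolution, silhouette_samples
from .embedding import Embedding2D
from .settest import FeatureStatistics, SetTestResult
from .similarity import SimilarityMatrix, to_distance
from .spectra import Dataset

__all__ = [
    "SCHEMA_VERSION",
    "top_k_edges",
    "bin_similarity",
    "node_size",
    "build_bundle",
    "write_bundle",
    "read_bundle",
    "validate_bundle",
    "load_schema",
]

SCHEMA_VERSION = "msfeast-bundle/1"
DEFAULT_BIN_THRESHOLDS = (0.4, 0.7)
DEFAULT_SIZE_RANGE = (10.0, 50.0)
DEFAULT_FC_CAP = 5.0
DEFAULT_ALPHA = 0.05
DEFAULT_K_EDGES = 30


def load_schema() -> dict:
    with resources.files("msfeast.schema").joinpath("bundle_schema.json").open() as fh:
        return json.load(fh)


def top_k_edges(sim: SimilarityMatrix, K: int) -> list[dict]:
    """Directed top-K neighbour records for every node, no similarity threshold.

    Per source node the K most similar other nodes are ranked 1..K; ties are
    broken by feature order in the matrix.  A record A->B may exist without
    B->A.
    """
    n = len(sim.feature_ids)
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must satisfy 1 <= K <= n-1 (K={K}, n={n})")
    edges: list[dict] = []
    for i, source in enumerate(sim.feature_ids):
        others = [j for j in range(n) if j != i]
        others.sort(key=lambda j: (-sim.scores[i, j], j))
        for rank, j in enumerate(others[:K], start=1):
            edges.append(
                {
                    "source_id": source,
                    "target_id": sim.feature_ids[j],
                    "rank": rank,
                    "similarity": float(sim.scores[i, j]),
                }
            )
    return edges


def bin_similarity(s: float, thresholds: tuple[float, float] = DEFAULT_BIN_THRESHOLDS) -> str:
    """Discrete strength label: s < t1 weak, t1 <= s < t2 moderate, s >= t2 strong."""
    t1, t2 = thresholds
    if not 0 < t1 < t2 < 1:
        raise ValueError(f"thresholds must satisfy 0 < t1 < t2 < 1, got {thresholds}")
    if s < t1:
        return "weak"
    if s < t2:
        return "moderate"
    return "strong"


def node_size(
    stat_value: float,
    mapping: str,
    size_min: float = DEFAULT_SIZE_RANGE[0],
    size_max: float = DEFAULT_SIZE_RANGE[1],
    fc_cap: float = DEFAULT_FC_CAP,
) -> float:
    """Linear statistic-to-pixel-width mapping for node rendering.

    ``mapping='pvalue'``: size = size_min + (1 - p) * (size_max - size_min),
    so p = 1 gives the minimum and p = 0 the maximum size.
    ``mapping='abs_log2fc'``: |lfc| capped at ``fc_cap`` then scaled linearly.
    """
    if size_min >= size_max:
        raise ValueError("size_min must be < size_max")
    if fc_cap <= 0:
        raise ValueError("fc_cap must be positive")
    span = size_max - size_min
    if mapping == "pvalue":
        if not 0 <= stat_value <= 1:
            raise ValueError(f"p-value {stat_value} outside [0, 1]")
        return size_min + (1.0 - stat_value) * span
    if mapping == "abs_log2fc":
        return size_min + min(abs(stat_value), fc_cap) / fc_cap * span
    raise ValueError(f"unknown mapping {mapping!r}")


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def _round_tree(obj: Any) -> Any:
    if isinstance(obj, float):
        return _round_sig(obj)
    if isinstance(obj, dict):
        return {k: _round_tree(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_tree(v) for v in obj]
    return obj


def build_bundle(
    dataset: Dataset,
    sim: SimilarityMatrix,
    clusters: ClusterSolution,
    embedding: Embedding2D,
    set_results: list[SetTestResult],
    feature_stats: list[FeatureStatistics],
    params: dict | None = None,
) -> dict:
    """Assemble the full dashboard bundle from pipeline outputs.

    ``params`` carries the run settings (tolerances, k, perplexity, n_perm,
    seeds, ...) and the rendering parameters ``alpha``, ``k_edges``,
    ``bin_thresholds``, ``size_range``, ``fc_cap``; missing rendering
    parameters fall back to the module defaults.  All inputs must cover the
    identical feature id set; any dangling reference is an error.
    """
    params = dict(params or {})
    alpha = float(params.setdefault("alpha", DEFAULT_ALPHA))
    k_edges = int(params.setdefault("k_edges", min(DEFAULT_K_EDGES, dataset.n_features - 1)))
    thresholds = tuple(params.setdefault("bin_thresholds", list(DEFAULT_BIN_THRESHOLDS)))
    size_range = tuple(params.setdefault("size_range", list(DEFAULT_SIZE_RANGE)))
    fc_cap = float(params.setdefault("fc_cap", DEFAULT_FC_CAP))

    ids = dataset.feature_ids
    for name, other in (("similarity", sim.feature_ids), ("embedding", embedding.feature_ids)):
        if list(other) != ids:
            raise ValueError(f"{name} feature ids do not match dataset order")
    if set(clusters.assignment) != set(ids):
        raise ValueError("cluster assignment does not cover the dataset features")
    for fs in feature_stats:
        if fs.feature_id not in clusters.assignment:
            raise ValueError(f"feature statistics reference unknown feature {fs.feature_id!r}")

    contrasts = sorted({r.contrast_name for r in set_results})
    cluster_indices = sorted({r.cluster_id for r in set_results})
    cid_label = {c: f"C{c}" for c in cluster_indices}
    if set(clusters.assignment.values()) != set(cluster_indices):
        raise ValueError("set-test results do not cover the cluster solution")

    stats_by_feature: dict[str, dict[str, FeatureStatistics]] = {}
    for fs in feature_stats:
        stats_by_feature.setdefault(fs.feature_id, {})[fs.contrast_name] = fs
    for fid in ids:
        missing = [c for c in contrasts if c not in stats_by_feature.get(fid, {})]
        if missing:
            raise ValueError(f"feature {fid!r} lacks statistics for contrasts {missing}")

    smin, smax = float(size_range[0]), float(size_range[1])
    nodes = []
    for fid, (x, y) in zip(ids, embedding.coords):
        per_contrast = {}
        for cname in contrasts:
            fs = stats_by_feature[fid][cname]
            per_contrast[cname] = {
                "p_univariate": fs.p_univariate,
                "log2fc": fs.log2_fold_change,
                "abs_log2fc": fs.abs_log2_fold_change,
                "node_size_p": node_size(fs.p_univariate, "pvalue", smin, smax, fc_cap),
                "node_size_fc": node_size(fs.log2_fold_change, "abs_log2fc", smin, smax, fc_cap),
            }
        nodes.append(
            {
                "feature_id": fid,
                "x": float(x),
                "y": float(y),
                "cluster_id": cid_label[clusters.assignment[fid]],
                "stats": per_contrast,
            }
        )

    edges = top_k_edges(sim, k_edges)
    for e in edges:
        e["bin"] = bin_similarity(e["similarity"], thresholds)  # type: ignore[arg-type]

    sil = silhouette_samples(to_distance(sim), clusters)
    sil_by_feature = dict(zip(ids, sil))
    cluster_records = []
    for c in cluster_indices:
        members = [f for f in ids if clusters.assignment[f] == c]
        cluster_records.append(
            {
                "cluster_id": cid_label[c],
                "members": members,
                "medoid": clusters.medoids[c],
                "silhouette": float(np.mean([sil_by_feature[f] for f in members])),
            }
        )

    by_pair = {(r.cluster_id, r.contrast_name): r for r in set_results}
    heatmap = {
        "cluster_ids": [cid_label[c] for c in cluster_indices],
        "contrasts": contrasts,
        "p_raw": [[by_pair[(c, t)].p_raw for t in contrasts] for c in cluster_indices],
        "p_adjusted": [[by_pair[(c, t)].p_adjusted for t in contrasts] for c in cluster_indices],
        "significant": [
            [bool(by_pair[(c, t)].p_adjusted < alpha) for t in contrasts] for c in cluster_indices
        ],
    }

    groups = {g: sorted(dataset.metadata.samples_of(g)) for g in dataset.metadata.groups}
    bundle = {
        "schema_version": SCHEMA_VERSION,
        "settings": params
        | {
            "family_size": len(cluster_indices) * len(contrasts),
            "n_features": len(ids),
            "k": clusters.k,
            "clustering_seed": clusters.seed,
            "perplexity": embedding.perplexity,
            "embedding_seed": embedding.seed,
        },
        "groups": groups,
        "reference_group": dataset.metadata.reference_group,
        "contrasts": contrasts,
        "nodes": nodes,
        "edges": edges,
        "clusters": cluster_records,
        "heatmap": heatmap,
    }
    return _round_tree(bundle)


def write_bundle(bundle: dict, path: str) -> None:
    """Serialise deterministically (UTF-8, fixed key order, 6 sig digits)."""
    text = json.dumps(_round_tree(bundle), indent=1, ensure_ascii=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
        fh.write("\n")


def read_bundle(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# --- validation -----------------------------------------------------------

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _check_schema(obj: Any, schema: dict, path: str, out: list[str]) -> None:
    """Minimal JSON-schema-subset checker (type/required/properties/items/enum/bounds)."""
    typ = schema.get("type")
    if typ is not None:
        pytype = _TYPES[typ]
        ok = isinstance(obj, pytype) and not (typ in ("number", "integer") and isinstance(obj, bool))
        if typ == "number":
            ok = isinstance(obj, (int, float)) and not isinstance(obj, bool)
        if not ok:
            out.append(f"{path}: expected {typ}, got {type(obj).__name__}")
            return
    if "enum" in schema and obj not in schema["enum"]:
        out.append(f"{path}: value {obj!r} not in {schema['enum']}")
    if isinstance(obj, (int, float)) and not isinstance(obj, bool):
        if "minimum" in schema and obj < schema["minimum"]:
            out.append(f"{path}: {obj} below minimum {schema['minimum']}")
        if "maximum" in schema and obj > schema["maximum"]:
            out.append(f"{path}: {obj} above maximum {schema['maximum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                out.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check_schema(obj[key], sub, f"{path}.{key}", out)
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            _check_schema(item, schema["items"], f"{path}[{i}]", out)


def validate_bundle(
    path_or_bundle: str | dict, sim: SimilarityMatrix | None = None
) -> list[str]:
    """Validate a bundle file (or dict); returns a list of violations (empty = ok).

    Checks the shipped schema, referential integrity (every referenced id
    resolves; cluster members partition the node set), Bonferroni
    monotonicity (p_adjusted = min(1, p_raw * family_size) and >= p_raw),
    significance flags against alpha, node sizes within the configured
    range, and — when the similarity matrix is supplied — that every edge's
    similarity matches the matrix entry to 1e-6.
    """
    bundle = read_bundle(path_or_bundle) if isinstance(path_or_bundle, str) else path_or_bundle
    violations: list[str] = []
    _check_schema(bundle, load_schema(), "$", violations)
    if violations:
        return violations

    node_ids = [n["feature_id"] for n in bundle["nodes"]]
    node_set = set(node_ids)
    if len(node_ids) != len(node_set):
        violations.append("duplicate node feature ids")
    cluster_ids = {c["cluster_id"] for c in bundle["clusters"]}
    contrasts = list(bundle["contrasts"])

    for n in bundle["nodes"]:
        if n["cluster_id"] not in cluster_ids:
            violations.append(f"node {n['feature_id']} references unknown cluster {n['cluster_id']}")
        for cname in contrasts:
            if cname not in n["stats"]:
                violations.append(f"node {n['feature_id']} lacks stats for contrast {cname}")

    seen_members: list[str] = []
    for c in bundle["clusters"]:
        seen_members.extend(c["members"])
        if c["medoid"] not in set(c["members"]):
            violations.append(f"cluster {c['cluster_id']} medoid not among members")
        unknown = set(c["members"]) - node_set
        if unknown:
            violations.append(f"cluster {c['cluster_id']} members not in nodes: {sorted(unknown)}")
    if sorted(seen_members) != sorted(node_ids):
        violations.append("cluster members do not partition the node id set")

    for e in bundle["edges"]:
        for endpoint in (e["source_id"], e["target_id"]):
            if endpoint not in node_set:
                violations.append(f"edge references unknown node {endpoint}")
        if e["source_id"] == e["target_id"]:
            violations.append(f"self edge at {e['source_id']}")
    ranks: dict[str, set[int]] = {}
    for e in bundle["edges"]:
        ranks.setdefault(e["source_id"], set())
        if e["rank"] in ranks[e["source_id"]]:
            violations.append(f"duplicate rank {e['rank']} for source {e['source_id']}")
        ranks[e["source_id"]].add(e["rank"])

    settings = bundle["settings"]
    alpha = settings.get("alpha", DEFAULT_ALPHA)
    family = settings.get("family_size")
    hm = bundle["heatmap"]
    if hm["cluster_ids"] != [c["cluster_id"] for c in bundle["clusters"]]:
        violations.append("heatmap cluster ids disagree with cluster records")
    if hm["contrasts"] != contrasts:
        violations.append("heatmap contrasts disagree with bundle contrasts")
    for i, cid in enumerate(hm["cluster_ids"]):
        for j, cname in enumerate(contrasts):
            p_raw, p_adj = hm["p_raw"][i][j], hm["p_adjusted"][i][j]
            if p_adj < p_raw - 1e-12:
                violations.append(f"heatmap ({cid},{cname}): p_adjusted {p_adj} < p_raw {p_raw}")
            if family is not None:
                expect = min(1.0, p_raw * family)
                if abs(p_adj - expect) > 5e-6 * max(1.0, expect):
                    violations.append(
                        f"heatmap ({cid},{cname}): p_adjusted {p_adj} != min(1, p_raw*{family})"
                    )
            if hm["significant"][i][j] != (p_adj < alpha):
                violations.append(f"heatmap ({cid},{cname}): significance flag inconsistent")

    size_range = settings.get("size_range")
    if size_range:
        smin, smax = size_range
        for n in bundle["nodes"]:
            for cname, st in n["stats"].items():
                for key in ("node_size_p", "node_size_fc"):
                    if not (smin - 1e-9 <= st[key] <= smax + 1e-9):
                        violations.append(
                            f"node {n['feature_id']} {key} {st[key]} outside [{smin}, {smax}]"
                        )

    if sim is not None:
        idx = {f: i for i, f in enumerate(sim.feature_ids)}
        for e in bundle["edges"]:
            i, j = idx.get(e["source_id"]), idx.get(e["target_id"])
            if i is None or j is None:
                continue
            if abs(e["similarity"] - sim.scores[i, j]) > 1e-6 + 1e-5 * abs(sim.scores[i, j]):
                violations.append(
                    f"edge {e['source_id']}->{e['target_id']} similarity {e['similarity']} "
                    f"!= matrix entry {sim.scores[i, j]:.8f}"
                )
    return violations
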